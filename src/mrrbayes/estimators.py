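"""Classical deterministic estimators used as baselines and initializers.

These are the counterpart estimators of the simple Bayesian models — the
Lincoln-Petersen index (counterpart of M0) and a Fisher-Ford-style
survival-adjusted estimator (counterpart of MS).  Neither accounts for
removal of individuals by trapping; they serve as cross-checks and as
sampler starting points, not as an inference surface.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import MRRDataset

__all__ = ["UndefinedEstimateError", "lincoln_petersen", "fisher_ford"]


class UndefinedEstimateError(ValueError):
    """The estimator is undefined on this dataset (e.g. no recaptures)."""


def lincoln_petersen(dataset: MRRDataset) -> float:
    """Lincoln-Petersen abundance index ``u_c * N / m_c``.

    The marked fraction among captures estimates the released fraction of the
    whole population.  Ignores both mortality and removal, so it
    overestimates abundance whenever marked individuals die or are removed
    during the experiment.
    """
    if dataset.m_c == 0:
        raise UndefinedEstimateError(
            "Lincoln-Petersen is undefined: no marked individuals recaptured"
        )
    return dataset.u_c * dataset.N / dataset.m_c


def fisher_ford(dataset: MRRDataset) -> tuple[float, float]:
    """Fisher-Ford-style estimate of (daily survival, abundance).

    Survival is taken from the exponential decay of marked captures: the
    least-squares slope of ``log m_i`` on ``i`` over days with ``m_i > 0``,
    exponentiated.  Abundance adjusts each day's capture ratio for the marked
    individuals expected still alive: day-wise estimates
    ``U_i = u_i * N * phi_hat**i / m_i`` are averaged over days with
    ``m_i > 0``.

    This is a conventional log-linear variant of the classical method (the
    original leaves implementation details open); it is used only as a
    baseline and MCMC initializer.

    Returns
    -------
    (phi_hat, abundance_hat)
        ``phi_hat`` is always positive; a value above 1 (rising captures) is
        reported with a warning rather than clipped.
    """
    m = dataset.m
    u = dataset.u
    days = np.arange(1, dataset.D + 1, dtype=float)
    pos = m > 0
    if pos.sum() < 2:
        raise UndefinedEstimateError(
            "Fisher-Ford needs at least two days with positive recaptures"
        )
    slope = np.polyfit(days[pos], np.log(m[pos]), 1)[0]
    phi_hat = float(np.exp(slope))
    if phi_hat > 1.0:
        warnings.warn(
            f"estimated daily survival {phi_hat:.3f} > 1 (captures rise over time)",
            stacklevel=2,
        )
    u_daywise = u[pos] * dataset.N * phi_hat ** days[pos] / m[pos]
    return phi_hat, float(u_daywise.mean())
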