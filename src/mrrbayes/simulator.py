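"""Forward simulation of a mark-release-recapture experiment.

The simulator is individual-faithful but drawn at the cohort level: the fate
of every individual on a day is an independent Bernoulli trial, so the daily
counts are exact binomial draws over the currently alive cohort.  Within each
day the event order is *survive, then capture*: an individual first survives
the day with its cohort's daily survival probability, and a surviving
individual is then captured (and permanently removed) with the trap-network
efficiency ``beta0``.  This ordering makes the marked day-``i`` capture
probability exactly ``beta0 * (1-beta0)**(i-1) * phi**i`` — survival enters
with exponent ``i`` and escape from previous trapping with exponent ``i-1``
— which is the marginal the inference models assume.

Recruits of the unmarked population arrive as a Poisson(``b``) count each day
*before* that day's survival/capture step, so a day-1 recruit contributes
``phi_u * beta0`` to day-1 expected captures, matching the latent-recruit
construction of the recruitment models.

Captures are simulated at the aggregate trap-network level; the trap count
``J`` is carried as metadata only.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datamodel import MRRDataset, SimulationConfig, validate_dataset

__all__ = [
    "simulate_marked",
    "simulate_unmarked",
    "simulate_pupal_survey",
    "simulate_dataset",
]


def _cohort_removal_counts(
    n0: int,
    beta0: float,
    phi: float,
    D: int,
    rng: np.random.Generator,
    recruit_rate: float = 0.0,
) -> np.ndarray:
    """Daily capture counts of a cohort under survive-then-capture removal.

    ``n0`` individuals are alive at release; if ``recruit_rate > 0`` a
    Poisson number of new individuals joins at the start of each day.
    """
    counts = np.zeros(D, dtype=np.int64)
    alive = int(n0)
    for i in range(D):
        if recruit_rate > 0.0:
            alive += int(rng.poisson(recruit_rate))
        survivors = int(rng.binomial(alive, phi)) if alive > 0 else 0
        captured = int(rng.binomial(survivors, beta0)) if survivors > 0 else 0
        counts[i] = captured
        alive = survivors - captured
    return counts


def simulate_marked(
    N: int, beta0: float, phi: float, D: int, rng: np.random.Generator
) -> np.ndarray:
    """Daily recaptures ``m_i`` of a released cohort of ``N`` marked individuals.

    Each individual each day survives with probability ``phi`` and, if alive,
    is captured with probability ``beta0`` and removed.  Always satisfies
    ``sum(m) <= N``.
    """
    return _cohort_removal_counts(N, beta0, phi, D, rng)


def simulate_unmarked(
    U: int,
    beta0: float,
    phi_u: float,
    b: float,
    D: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Daily captures ``u_i`` of the unmarked population.

    The initial ``U`` unmarked individuals follow the same
    survive-then-capture removal process with survival ``phi_u``; a
    Poisson(``b``) number of newly emerged adults enters each day before that
    day's survival and capture step.
    """
    return _cohort_removal_counts(U, beta0, phi_u, D, rng, recruit_rate=b)


def simulate_pupal_survey(
    U: int,
    phi_u: float,
    tau: float,
    s: float,
    f_a: float,
    mu: float,
    rng: np.random.Generator,
) -> int:
    """Observed pupal count from an imperfect pre-release immature survey.

    For a population at steady state, daily emergence balances adult
    mortality, so the pupae present in the whole area over one maturation
    window number about ``tau * U / s * (1 - phi_u)``; a survey covering a
    fraction ``f_a`` of the area finds each independently.  The collectable
    count is therefore Binomial(round(tau*U/s), f_a*(1-phi_u)); an imperfect
    search then detects each collectable pupa with probability ``mu``.
    """
    size = int(round(tau * U / s))
    p = f_a * (1.0 - phi_u)
    collectable = int(rng.binomial(size, p)) if size > 0 and p > 0 else 0
    if mu <= 0.0 or collectable == 0:
        return 0
    return int(rng.binomial(collectable, mu))


def simulate_dataset(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> MRRDataset:
    """Simulate a complete MRR experiment described by ``cfg``.

    A single seeded generator drives the pupal survey, the marked cohort and
    the unmarked population in that order, so the output is deterministic
    given ``cfg.seed`` (or a caller-supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_pupae = simulate_pupal_survey(
        cfg.U, cfg.phi_u, cfg.tau, cfg.s, cfg.f_a, cfg.mu, rng
    )
    m = simulate_marked(cfg.N, cfg.beta0, cfg.phi, cfg.D, rng)
    u = simulate_unmarked(cfg.U, cfg.beta0, cfg.phi_u, cfg.b, cfg.D, rng)
    return validate_dataset(
        MRRDataset(
            m=m,
            u=u,
            N=cfg.N,
            n_pupae=n_pupae,
            f_a=cfg.f_a,
            tau=cfg.tau,
            s=cfg.s,
            J=cfg.J,
        )
    )
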