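"""Log-density computation for the five MRR inference models.

Marked-cohort likelihood (all models)
    ``m_c ~ Binomial(N, sum_i p_i)`` for the total recaptured, and
    ``m ~ Multinomial(p / sum_i p_i, m_c)`` for the daily split, where ``p``
    is the model's marked capture-probability vector.  The product collapses
    to ``N! / ((N - m_c)! prod_i m_i!) * prod_i p_i^{m_i} * (1 - P)^{N - m_c}``
    with ``P = sum_i p_i``; proposals with ``P > 1`` are invalid and score
    ``-inf``.

Unmarked likelihood
    M0/MS/MB: ``u_i ~ Poisson(U * p_i^{unmarked})``.
    MRSU/MRP: latent daily survivor and recruit counts
    ``U_i ~ Poisson(U (1-beta0)^{i-1} phi_x^i)`` and
    ``V_i ~ Poisson(b * sum_{j<=i} (1-beta0)^{j-1} phi_x^j)`` are observed
    through binomial thinning ``u_i ~ Binomial(U_i + V_i, beta0)``.  A
    binomial thinning of a Poisson sum is Poisson, so the latents are
    marginalized analytically:
    ``u_i ~ Poisson(beta0 * (lambda_Ui + lambda_Vi))``
    with ``phi_x = phi`` under MRSU and ``phi_u`` under MRP.

Pupal-survey likelihood (MRP only)
    ``n_pupae ~ Binomial(round(tau*U/s), f_a*(1 - phi_u))``.

All functions return ``-inf`` (never raise, never NaN) for parameter values
outside the support — the sampler treats that as proposal rejection.
Abundance ``U`` is treated as continuous inside Poisson/binomial means,
consistent with its Gamma prior; the binomial pupal size rounds
``tau*U/s`` to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import betaln, gammaln

from .datamodel import Model, MRRDataset, PriorSet, free_parameters

__all__ = [
    "ParameterVector",
    "capture_probs",
    "unmarked_means",
    "loglik_marked",
    "loglik_unmarked",
    "loglik_pupae",
    "log_prior",
    "log_posterior",
]

_NEG_INF = float("-inf")


@dataclass
class ParameterVector:
    """One point in parameter space.

    Only the entries freed by the model are meaningful; under MRSU the
    unmarked survival aliases the marked one (``phi_u`` is ignored).
    """

    U: float
    beta0: float
    phi: float = 1.0
    phi_u: float = 1.0
    b: float = 0.0

    def in_support(self, model_id: Model) -> bool:
        if not (self.U > 0 and 0.0 < self.beta0 < 1.0):
            return False
        names = free_parameters(model_id)
        if "phi" in names and not (0.0 < self.phi <= 1.0):
            return False
        if "phi_u" in names and not (0.0 < self.phi_u <= 1.0):
            return False
        if "b" in names and not (self.b >= 0.0 and math.isfinite(self.b)):
            return False
        return math.isfinite(self.U)


def _phi_unmarked(model_id: Model, params: ParameterVector) -> float:
    return params.phi if model_id is Model.MRSU else params.phi_u


def capture_probs(
    model_id: Model | str,
    params: ParameterVector,
    D: int,
    cohort: str = "marked",
) -> np.ndarray:
    """Daily capture probabilities ``p_i``, ``i = 1..D``.

    ======  =============================  =========================
    model   marked                         unmarked
    ======  =============================  =========================
    M0      beta0                          beta0
    MS      beta0 * phi**i                 beta0
    MB      beta0*(1-beta0)**(i-1)*phi**i  beta0*(1-beta0)**(i-1)
    MRSU    same as MB marked              (latent; see unmarked_means)
    MRP     same as MB marked              (latent; see unmarked_means)
    ======  =============================  =========================

    Survival decay applies only to the marked cohort, which is released once
    and never replenished.  The unmarked population is assumed stationary
    (recruitment balancing mortality) in M0 and MS, so its capture
    probability carries no survival term; MB additionally depletes both
    cohorts by previous days' trapping, which recruitment does not replace.
    """
    model_id = Model(model_id)
    if cohort not in ("marked", "unmarked"):
        raise ValueError(f"cohort must be 'marked' or 'unmarked', got {cohort!r}")
    i = np.arange(1, D + 1, dtype=float)
    b0, phi = params.beta0, params.phi
    if model_id is Model.M0:
        return np.full(D, b0)
    if model_id is Model.MS:
        if cohort == "marked":
            return b0 * phi**i
        return np.full(D, b0)
    if cohort == "marked":  # MB, MRSU, MRP share the removal form
        return b0 * (1.0 - b0) ** (i - 1.0) * phi**i
    if model_id is Model.MB:
        return b0 * (1.0 - b0) ** (i - 1.0)
    raise ValueError(
        f"{model_id.value} has no unmarked capture-probability vector; "
        "its unmarked process is latent — use unmarked_means()"
    )


def unmarked_means(
    model_id: Model | str, params: ParameterVector, D: int
) -> np.ndarray:
    """Poisson means of the daily unmarked captures ``u_i``.

    For M0/MS/MB this is ``U * p_i^{unmarked}``.  For MRSU/MRP the latent
    survivors and recruits are marginalized:
    ``beta0 * (U*(1-beta0)**(i-1)*phi_x**i + b*cumsum((1-beta0)**(j-1)*phi_x**j))``.
    """
    model_id = Model(model_id)
    if model_id in (Model.M0, Model.MS, Model.MB):
        return params.U * capture_probs(model_id, params, D, cohort="unmarked")
    phi_x = _phi_unmarked(model_id, params)
    i = np.arange(1, D + 1, dtype=float)
    decay = (1.0 - params.beta0) ** (i - 1.0) * phi_x**i
    return params.beta0 * (params.U * decay + params.b * np.cumsum(decay))


def loglik_marked(p: np.ndarray, m: np.ndarray, N: int) -> float:
    """Log binomial-total times multinomial-split likelihood of recaptures.

    Returns ``-inf`` when ``sum(p) > 1`` (invalid proposal) or when a day
    with ``p_i = 0`` has a positive count.
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m)
    if p.shape != m.shape:
        raise ValueError(f"dimension mismatch: p has {p.shape}, m has {m.shape}")
    P = float(p.sum())
    if P > 1.0 or np.any(p < 0.0):
        return _NEG_INF
    mc = int(m.sum())
    pos = m > 0
    if np.any(p[pos] == 0.0):
        return _NEG_INF
    ll = float(gammaln(N + 1) - gammaln(N - mc + 1) - gammaln(m + 1).sum())
    if pos.any():
        ll += float(np.sum(m[pos] * np.log(p[pos])))
    if N > mc:
        if P >= 1.0:
            return _NEG_INF
        ll += (N - mc) * math.log1p(-P)
    return ll


def _poisson_logpmf_sum(u: np.ndarray, lam: np.ndarray) -> float:
    """``sum_i log Poisson(u_i; lam_i)`` with 0*log(0) = 0 handling."""
    u = np.asarray(u, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0.0):
        return _NEG_INF
    pos = u > 0
    if np.any(lam[pos] == 0.0):
        return _NEG_INF
    out = -float(lam.sum()) - float(gammaln(u + 1).sum())
    if pos.any():
        out += float(np.sum(u[pos] * np.log(lam[pos])))
    return out


def loglik_unmarked(
    model_id: Model | str, params: ParameterVector, u: np.ndarray, D: int
) -> float:
    """Log likelihood of the daily unmarked captures under ``model_id``."""
    lam = unmarked_means(model_id, params, D)
    return _poisson_logpmf_sum(u, lam)


def loglik_pupae(
    params: ParameterVector,
    n_pupae: Optional[int],
    f_a: float,
    tau: float,
    s: float,
    poisson_approx: bool = False,
) -> float:
    """Log likelihood of the pre-release pupal count (model MRP).

    ``n_pupae ~ Binomial(round(tau*U/s), f_a*(1-phi_u))``; ``-inf`` when the
    count exceeds the binomial size.  With ``poisson_approx`` the binomial is
    replaced by Poisson(``f_a*(1-phi_u)*tau*U/s``) — a smooth function of U
    suited to gradient-based samplers, and numerically indistinguishable in
    the usual regime where the success probability ``f_a*(1-phi_u)`` is small.
    """
    if n_pupae is None:
        raise ValueError("n_pupae is required to evaluate the pupal likelihood")
    size = int(round(tau * params.U / s))
    prob = f_a * (1.0 - params.phi_u)
    if not (0.0 <= prob <= 1.0):
        return _NEG_INF
    k = int(n_pupae)
    if poisson_approx:
        lam = prob * tau * params.U / s
        return _poisson_logpmf_sum(np.array([k]), np.array([lam]))
    if k < 0 or k > size:
        return _NEG_INF
    if prob == 0.0:
        return 0.0 if k == 0 else _NEG_INF
    if prob == 1.0:
        return 0.0 if k == size else _NEG_INF
    return float(
        gammaln(size + 1)
        - gammaln(k + 1)
        - gammaln(size - k + 1)
        + k * math.log(prob)
        + (size - k) * math.log1p(-prob)
    )


def _log_beta(x: float, a: float, b: float) -> float:
    if not (0.0 < x < 1.0):
        return _NEG_INF
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x) - float(betaln(a, b))


def _log_gamma(x: float, shape: float, rate: float) -> float:
    if x <= 0.0:
        return _NEG_INF
    return (
        shape * math.log(rate)
        - float(gammaln(shape))
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


def _log_lognormal(x: float, meanlog: float, precision: float) -> float:
    if x <= 0.0:
        return _NEG_INF
    lx = math.log(x)
    return (
        0.5 * math.log(precision)
        - 0.5 * math.log(2.0 * math.pi)
        - lx
        - 0.5 * precision * (lx - meanlog) ** 2
    )


def log_prior(
    model_id: Model | str, params: ParameterVector, priors: PriorSet
) -> float:
    """Sum of log prior densities over the model's free parameters only.

    MRSU has no separate ``phi_u`` prior (it aliases ``phi``); the
    recruitment prior applies only to MRSU/MRP.
    """
    model_id = Model(model_id)
    names = free_parameters(model_id)
    lp = _log_gamma(params.U, priors.U_shape, priors.U_rate)
    lp += _log_beta(params.beta0, priors.beta0_a, priors.beta0_b)
    if "phi" in names:
        lp += _log_beta(params.phi, priors.phi_a, priors.phi_b)
    if "phi_u" in names:
        lp += _log_beta(params.phi_u, priors.phiu_a, priors.phiu_b)
    if "b" in names:
        lp += _log_lognormal(params.b, priors.b_meanlog, priors.b_precision)
    return lp


def log_posterior(
    model_id: Model | str,
    params: ParameterVector,
    dataset: MRRDataset,
    priors: PriorSet,
) -> float:
    """Unnormalized log posterior density at ``params``.

    Sum of the marked, unmarked, (for MRP) pupal log likelihoods and the log
    prior; ``-inf`` propagates from any term.
    """
    model_id = Model(model_id)
    if model_id is Model.MRP and dataset.n_pupae is None:
        raise ValueError("model MRP requires a pupal count (dataset.n_pupae)")
    if not params.in_support(model_id):
        return _NEG_INF
    lp = log_prior(model_id, params, priors)
    if lp == _NEG_INF:
        return _NEG_INF
    p_marked = capture_probs(model_id, params, dataset.D, cohort="marked")
    ll = loglik_marked(p_marked, dataset.m, dataset.N)
    if ll == _NEG_INF:
        return _NEG_INF
    ll += loglik_unmarked(model_id, params, dataset.u, dataset.D)
    if model_id is Model.MRP:
        ll += loglik_pupae(
            params, dataset.n_pupae, dataset.f_a, dataset.tau, dataset.s
        )
    total = lp + ll
    return total if not math.isnan(total) else _NEG_INF
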