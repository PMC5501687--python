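"""Domain types shared across the package.

Conventions used throughout:

* Days are indexed ``i = 1..D`` with day 1 the first post-release collection
  day.  Capture-probability formulas of the removal models use the exponent
  ``i - 1`` for escape from previous days' trapping, which vanishes at ``i=1``.
* The Gamma prior on abundance is parameterized by (shape, rate) and the
  Lognormal prior on recruitment by (mean of log, precision of log) — the
  BUGS-dialect conventions.  ``Lognormal(10, 0.25)`` therefore means a very
  diffuse prior with log-scale standard deviation ``1/sqrt(0.25) = 2``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Model",
    "MRRDataset",
    "SimulationConfig",
    "ModelSpec",
    "PriorSet",
    "MCMCConfig",
    "PosteriorSummary",
    "validate_dataset",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violated a structural invariant of the data model."""


class Model(str, enum.Enum):
    """The five inference models.

    * ``M0`` — constant capture probability; Bayesian Lincoln-Petersen
      counterpart.  Frees (U, beta0).
    * ``MS`` — capture probability decays with daily survival; Bayesian
      Fisher-Ford counterpart.  Frees (U, beta0, phi).
    * ``MB`` — survival plus removal of captured individuals (Buonaccorsi-type
      removal design).  Frees (U, beta0, phi).
    * ``MRSU`` — removal model with recruitment, assuming unmarked survival
      equals marked survival.  Frees (U, beta0, phi, b); phi_u is an alias of
      phi.
    * ``MRP`` — removal model with recruitment and a pupal-survey likelihood
      separating unmarked from marked survival.  Frees all five parameters.
    """

    M0 = "M0"
    MS = "MS"
    MB = "MB"
    MRSU = "MRSU"
    MRP = "MRP"


_FREE_PARAMS: dict[Model, tuple[str, ...]] = {
    Model.M0: ("U", "beta0"),
    Model.MS: ("U", "beta0", "phi"),
    Model.MB: ("U", "beta0", "phi"),
    Model.MRSU: ("U", "beta0", "phi", "b"),
    Model.MRP: ("U", "beta0", "phi", "phi_u", "b"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters a model estimates."""

    model_id: Model
    free_parameters: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        model_id = Model(self.model_id)
        object.__setattr__(self, "model_id", model_id)
        expected = _FREE_PARAMS[model_id]
        if not self.free_parameters:
            object.__setattr__(self, "free_parameters", expected)
        elif tuple(self.free_parameters) != expected:
            raise ValidationError(
                f"{model_id.value} frees {expected}, got {tuple(self.free_parameters)}"
            )

    @property
    def uses_pupae(self) -> bool:
        return self.model_id is Model.MRP

    @property
    def has_recruitment(self) -> bool:
        return self.model_id in (Model.MRSU, Model.MRP)


def free_parameters(model_id: Model | str) -> tuple[str, ...]:
    """Names of the parameters estimated by ``model_id``."""
    return _FREE_PARAMS[Model(model_id)]


def _as_count_vector(x: Sequence[int] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-d vector")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.all(np.isfinite(arr)) or np.any(rounded != arr):
            raise ValidationError(f"{name} must contain integers, got {arr.dtype}")
        arr = rounded.astype(np.int64)
    return arr.astype(np.int64)


@dataclass(eq=False)
class MRRDataset:
    """Observed daily trap counts from one mark-release-recapture experiment.

    Parameters
    ----------
    m, u
        Length-``D`` vectors of marked recaptures ``m_i`` and unmarked
        captures ``u_i`` for post-release days ``i = 1..D``, summed over all
        traps.
    N
        Number of marked individuals released.
    n_pupae
        Optional pupal count from the pre-release immature survey (required
        to fit model MRP).
    f_a
        Fraction of the study area (or premises) covered by the pupal search,
        in ``(0, 1]``.
    tau
        Pupal maturation time in days.
    s
        Fraction of the targeted sex in the population (0.5 for females).
    J
        Number of traps; metadata only — counts are aggregated over traps.
    """

    m: np.ndarray
    u: np.ndarray
    N: int
    n_pupae: Optional[int] = None
    f_a: float = 1.0
    tau: float = 2.0
    s: float = 0.5
    J: Optional[int] = None

    def __post_init__(self) -> None:
        self.m = _as_count_vector(self.m, "m")
        self.u = _as_count_vector(self.u, "u")
        self.N = int(self.N)
        if self.n_pupae is not None:
            self.n_pupae = int(self.n_pupae)
        if self.J is not None:
            self.J = int(self.J)

    @property
    def D(self) -> int:
        """Number of post-release collection days."""
        return len(self.m)

    @property
    def m_c(self) -> int:
        """Total marked recaptures, ``sum_i m_i``."""
        return int(self.m.sum())

    @property
    def u_c(self) -> int:
        """Total unmarked captures, ``sum_i u_i``."""
        return int(self.u.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MRRDataset):
            return NotImplemented
        return (
            np.array_equal(self.m, other.m)
            and np.array_equal(self.u, other.u)
            and self.N == other.N
            and self.n_pupae == other.n_pupae
            and math.isclose(self.f_a, other.f_a)
            and math.isclose(self.tau, other.tau)
            and math.isclose(self.s, other.s)
            and self.J == other.J
        )


def validate_dataset(d: MRRDataset) -> MRRDataset:
    """Check all structural invariants of ``d``; return it unchanged if valid.

    Raises
    ------
    ValidationError
        Naming the first violated invariant (negative count, length mismatch,
        ``sum(m) > N`` ...).
    """
    if len(d.m) != len(d.u):
        raise ValidationError(
            f"length mismatch: len(m)={len(d.m)} != len(u)={len(d.u)}"
        )
    if d.D < 1:
        raise ValidationError("need at least one collection day (D >= 1)")
    if np.any(d.m < 0):
        raise ValidationError(f"negative count in m at day {int(np.argmin(d.m)) + 1}")
    if np.any(d.u < 0):
        raise ValidationError(f"negative count in u at day {int(np.argmin(d.u)) + 1}")
    if d.N <= 0:
        raise ValidationError(f"N must be positive, got {d.N}")
    if d.m_c > d.N:
        raise ValidationError(f"sum(m) > N: recaptured {d.m_c} of {d.N} released")
    if d.n_pupae is not None and d.n_pupae < 0:
        raise ValidationError(f"n_pupae must be non-negative, got {d.n_pupae}")
    if not (0.0 < d.f_a <= 1.0):
        raise ValidationError(f"f_a must be in (0, 1], got {d.f_a}")
    if d.tau <= 0:
        raise ValidationError(f"tau must be positive, got {d.tau}")
    if not (0.0 < d.s <= 1.0):
        raise ValidationError(f"s must be in (0, 1], got {d.s}")
    if d.J is not None and d.J <= 0:
        raise ValidationError(f"J must be positive, got {d.J}")
    return d


@dataclass(frozen=True)
class SimulationConfig:
    """Complete generative parameterization of a simulated MRR experiment.

    Defaults are the reference simulation-study conditions: abundance 4,000,
    2,000 released, 5% daily trap capture efficiency, marked/unmarked daily
    survival 0.78/0.85, recruitment 600/day, a 10-day experiment with 64
    traps, and a pupal survey covering 10% of the area at perfect search
    efficiency.
    """

    U: int = 4000
    N: int = 2000
    beta0: float = 0.05
    phi: float = 0.78
    phi_u: float = 0.85
    b: float = 600.0
    mu: float = 1.0
    D: int = 10
    J: int = 64
    f_a: float = 0.1
    tau: float = 2.0
    s: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("U", "N", "D", "J"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name, lo_open, hi in (
            ("beta0", True, 1.0),
            ("phi", True, 1.0),
            ("phi_u", True, 1.0),
            ("f_a", True, 1.0),
            ("s", True, 1.0),
        ):
            v = getattr(self, name)
            if not (0.0 < v <= hi) if lo_open else not (0.0 <= v <= hi):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.beta0 >= 1.0:
            raise ValidationError(f"beta0 must be in (0, 1), got {self.beta0}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValidationError(f"mu must be in [0, 1], got {self.mu}")
        if self.b < 0:
            raise ValidationError(f"b must be non-negative, got {self.b}")
        if self.tau <= 0:
            raise ValidationError(f"tau must be positive, got {self.tau}")

    def with_(self, **changes) -> "SimulationConfig":
        """A copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class PriorSet:
    """Hyperparameters of the prior distributions.

    Defaults: ``U ~ Gamma(shape=0.001, rate=0.001)`` (scale-free diffuse),
    ``beta0 ~ Beta(2, 4)`` (mass near small capture efficiencies),
    ``phi, phi_u ~ Beta(4, 2)`` (mass near high daily survival),
    ``b ~ Lognormal(meanlog=10, precision=0.25)`` i.e. sdlog 2, a diffuse
    prior on the recruitment rate.
    """

    U_shape: float = 0.001
    U_rate: float = 0.001
    beta0_a: float = 2.0
    beta0_b: float = 4.0
    phi_a: float = 4.0
    phi_b: float = 2.0
    phiu_a: float = 4.0
    phiu_b: float = 2.0
    b_meanlog: float = 10.0
    b_precision: float = 0.25

    def __post_init__(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ValidationError(f"prior hyperparameter {f_.name} must be > 0")

    @property
    def b_sdlog(self) -> float:
        return 1.0 / math.sqrt(self.b_precision)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler protocol.

    The reference analysis protocol is 3 chains of 360,000 iterations with a
    320,000 burn-in; the default here is a desk-scale budget of 3 chains of
    20,000 iterations with a 10,000 burn-in, which converges on 10-day
    experiments (check the R-hat column of the summary).
    """

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 1
    seed: Optional[int] = None
    target_accept: float = 0.25
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValidationError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if not (0.0 < self.target_accept < 1.0):
            raise ValidationError("target_accept must be in (0, 1)")


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries.

    ``table`` is indexed by parameter name with columns
    ``mean, median, q2.5, q97.5, rhat, ess``.
    """

    table: "object"  # pandas.DataFrame; avoid import cycle at type-check time

    def __post_init__(self) -> None:
        t = self.table
        bad = t[(t["q2.5"] > t["median"]) | (t["median"] > t["q97.5"])]
        if len(bad):
            raise ValidationError(
                f"quantile ordering violated for {list(bad.index)}"
            )

    @property
    def parameters(self) -> list[str]:
        return list(self.table.index)

    def covers(self, parameter: str, value: float) -> bool:
        """Whether the equal-tailed 95% interval contains ``value``."""
        row = self.table.loc[parameter]
        return bool(row["q2.5"] <= value <= row["q97.5"])

    def __getitem__(self, parameter: str):
        return self.table.loc[parameter]
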