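"""Domain types shared across the package.

The canonical long-format table has one row per rating of one child's
wellbeing at one survey wave by one rater; see :data:`OBS_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Pandemic periods in temporal order.
PERIODS: tuple[str, ...] = ("pre", "early", "late", "post")

#: Canonical long-format columns.
OBS_COLUMNS: list[str] = [
    "family_id",
    "individual_id",
    "zygosity",
    "wave",
    "period",
    "rater",
    "sex",
    "age",
    "pea",
    "wellbeing",
]

#: Default collapsing of survey waves into pandemic periods.  Wave 0 is the
#: pre-pandemic baseline; waves 1-2 fall in the first lockdown year, 3-4 in
#: the second, 5-6 after restrictions ended.
DEFAULT_PERIOD_MAP: dict[int, str] = {
    0: "pre",
    1: "early",
    2: "early",
    3: "late",
    4: "late",
    5: "post",
    6: "post",
}

#: Approximate years elapsed since the baseline survey for each wave
#: (pandemic waves were fielded roughly every six months).
WAVE_YEARS: dict[int, float] = {
    0: 0.0,
    1: 1.0,
    2: 1.5,
    3: 2.0,
    4: 2.5,
    5: 3.0,
    6: 3.5,
    7: 4.0,
}


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol:
        raise ValueError(
            f"{name} is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )


@dataclass
class AceParams:
    """Univariate variance components of the classical twin model.

    ``a2`` additive genetic, ``c2`` shared environmental, ``e2`` non-shared
    environmental (includes measurement error), ``d2`` optional non-additive
    genetic variance.  Fitted models use either C or D, never both.
    """

    a2: float
    c2: float
    e2: float
    d2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2", "d2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.e2 <= 0:
            raise ValueError("e2 must be strictly positive (contains measurement error)")

    @property
    def total(self) -> float:
        return self.a2 + self.c2 + self.e2 + self.d2

    def standardized(self) -> dict[str, float]:
        t = self.total
        return {"a2": self.a2 / t, "c2": self.c2 / t, "e2": self.e2 / t, "d2": self.d2 / t}


@dataclass
class TwinCorrelations:
    """Twin-pair Pearson correlations per zygosity (double-entered)."""

    r_mz: float
    r_dz: float
    n_mz: int
    n_dz: int

    def __post_init__(self) -> None:
        for r in (self.r_mz, self.r_dz):
            if np.isfinite(r) and not (-1.0 - 1e-9 <= r <= 1.0 + 1e-9):
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class CFParams:
    """Correlated-factors model parameters over the four pandemic periods.

    ``sigma_a``, ``sigma_c`` and ``sigma_e`` are 4x4 symmetric PSD component
    matrices; the implied phenotypic covariance is their elementwise sum.
    Mean coefficients (per-period intercepts plus linear age and sex effects)
    are carried alongside so a fitted object is self-contained.
    """

    sigma_a: np.ndarray
    sigma_c: np.ndarray
    sigma_e: np.ndarray
    intercepts: np.ndarray | None = None
    beta_age: float = 0.0
    beta_sex: float = 0.0
    periods: tuple[str, ...] = PERIODS

    def __post_init__(self) -> None:
        self.sigma_a = np.asarray(self.sigma_a, dtype=float)
        self.sigma_c = np.asarray(self.sigma_c, dtype=float)
        self.sigma_e = np.asarray(self.sigma_e, dtype=float)
        k = len(self.periods)
        for name, mat in (("sigma_a", self.sigma_a), ("sigma_c", self.sigma_c),
                          ("sigma_e", self.sigma_e)):
            if mat.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            _check_psd(mat, name)
        if self.intercepts is not None:
            self.intercepts = np.asarray(self.intercepts, dtype=float)
            if self.intercepts.shape != (k,):
                raise ValueError("intercepts must have one entry per period")

    @property
    def phenotypic(self) -> np.ndarray:
        return self.sigma_a + self.sigma_c + self.sigma_e


@dataclass
class MultiRaterParams:
    """Psychometric multi-rater model components for one period.

    The latent child phenotype seen by both parents has the ``common`` ACE
    decomposition; each parent's rating adds rater-specific A/C/E on top.
    The rater-specific shared-environment components (``C_m``, ``C_f``) are
    the rater-bias terms: deviations applied identically to both twins by
    one rater.
    """

    common: AceParams
    mother_specific: AceParams
    father_specific: AceParams

    @property
    def mother_total(self) -> float:
        return self.common.total + self.mother_specific.total

    @property
    def father_total(self) -> float:
        return self.common.total + self.father_specific.total


@dataclass
class MeanModel:
    """Linear mean structure for simulated ratings."""

    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"pre": 8.2, "early": 7.6, "late": 7.5, "post": 7.9}
    )
    beta_age: float = -0.02
    beta_sex: float = 0.05  # female vs male
    father_offset: float = -0.05  # father rating vs mother rating


@dataclass
class MissingnessConfig:
    """MCAR observation model.

    ``period_obs_prob``: probability that a child is observed at all in a
    period (baseline availability is drawn once per family so both twins
    share the baseline flag); ``rater_prob``: probability that a given rater
    responds for a family in a period, conditional on observation.
    """

    period_obs_prob: Mapping[str, float] = field(
        default_factory=lambda: {p: 1.0 for p in PERIODS}
    )
    rater_prob: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "mother": {p: 1.0 for p in PERIODS},
            "father": {p: 1.0 for p in PERIODS},
        }
    )

    def __post_init__(self) -> None:
        probs = list(self.period_obs_prob.values())
        for r in self.rater_prob.values():
            probs.extend(r.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Configuration of the synthetic twin-cohort generator.

    Either ``cf_params`` (longitudinal common phenotype) or
    ``multirater_by_period`` (period-wise common + rater-specific structure)
    must be supplied.  When both are given, ``cf_params`` governs the common
    phenotype and only the rater-specific parts of the multi-rater sets are
    used.
    """

    n_mz_pairs: int
    n_dz_pairs: int
    seed: int
    cf_params: CFParams | None = None
    multirater_by_period: Mapping[str, MultiRaterParams] | None = None
    mean_model: MeanModel = field(default_factory=MeanModel)
    missingness: MissingnessConfig | None = None
    cantril_discretize: bool = False
    periods: tuple[str, ...] = PERIODS
    pea_probs: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.111, "middle": 0.372, "high": 0.517}
    )
    age_range: tuple[float, float] = (7.0, 12.0)

    def __post_init__(self) -> None:
        if self.n_mz_pairs <= 0 or self.n_dz_pairs <= 0:
            raise ValueError("pair counts must be positive")
        if self.cf_params is None and self.multirater_by_period is None:
            raise ValueError("provide cf_params and/or multirater_by_period")


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood model fit."""

    params: dict[str, float]
    minus2ll: float
    converged: bool
    n_obs: int
    n_params: int
    se: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None
    message: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.minus2ll):
            raise ValueError("-2lnL must be finite at the reported optimum")


@dataclass
class LmmSpec:
    """Random-intercept linear mixed model for mean wellbeing.

    Fixed effects follow the wellbeing trend model
    ``Y = (b1 + u_i) + b2*wave + b3*sex + b4*age + b5*PEA + b6*rater + e``
    with wave categorical (reference = first wave), female vs male,
    low/middle vs high parental educational attainment, and father vs
    mother rater.
    """

    intercept: float
    wave_effects: Mapping[int, float]  # offset vs the reference wave
    beta_female: float = 0.0
    beta_age: float = 0.0
    beta_pea_low: float = 0.0
    beta_pea_middle: float = 0.0
    beta_father: float = 0.0
    var_family: float = 0.0
    var_individual: float = 0.3
    var_residual: float = 0.4

    def __post_init__(self) -> None:
        for name in ("var_family", "var_individual", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class LmmFit:
    """Fitted random-intercept LMM."""

    beta: dict[str, float]
    se: dict[str, float]
    tstat: dict[str, float]
    pvalue: dict[str, float]
    var_family: float
    var_individual: float
    var_residual: float
    loglik: float
    n_obs: int
    n_individuals: int
    n_families: int
    nesting: str
    ref_wave: int
    design_columns: list[str]
    design_mean: np.ndarray  # sample-average design row, for marginal means
    flags: list[str] = field(default_factory=list)
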