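"""Seeded synthetic twin cohorts with known A/C/E structure.

The generator emulates a population twin register observed at a pre-pandemic
baseline and three pandemic periods: MZ/DZ pairs whose latent wellbeing
phenotype follows a correlated-factors A/C/E structure across periods,
optional dual parental ratings with common plus rater-specific components
(the rater-specific shared-environment part being rater bias), linear
covariate effects, MCAR missingness with a family-shared baseline flag, and
optional 0-10 Cantril-ladder discretization.  All draws are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    OBS_COLUMNS,
    PERIODS,
    WAVE_YEARS,
    LmmSpec,
    MissingnessConfig,
    SimulationConfig,
)

__all__ = [
    "simulate_twin_cohort",
    "apply_missingness",
    "discretize_cantril",
    "simulate_lmm_cohort",
    "LmmCohortDesign",
]

#: Representative survey wave for each collapsed period.
PERIOD_WAVE: dict[str, int] = {"pre": 0, "early": 1, "late": 3, "post": 5}


def discretize_cantril(latent_scores) -> np.ndarray:
    """Round latent scores to the 0-10 integer ladder (monotone, clipped)."""
    return np.clip(np.rint(np.asarray(latent_scores, dtype=float)), 0.0, 10.0)


def _chol(mat: np.ndarray, name: str) -> np.ndarray:
    """Cholesky-like square root of a PSD matrix (eigen fallback at the
    boundary); raises a diagnostic naming the offending matrix otherwise."""
    mat = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(f"component matrix {name!r} is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def _draw_ace_phenotype(
    rng: np.random.Generator,
    n_pairs: int,
    sigma_a: np.ndarray,
    sigma_c: np.ndarray,
    sigma_e: np.ndarray,
    mz: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (twin1, twin2) phenotype deviates, each ``(n_pairs, k)``.

    Cross-twin correlations: A 1 (MZ) / 0.5 (DZ), C 1, E 0.
    """
    la = _chol(sigma_a, "sigma_a")
    lc = _chol(sigma_c, "sigma_c")
    le = _chol(sigma_e, "sigma_e")
    k = sigma_a.shape[0]
    z = lambda: rng.standard_normal((n_pairs, k))  # noqa: E731
    if mz:
        a1 = a2 = z() @ la.T
    else:
        shared = z() @ la.T * np.sqrt(0.5)
        a1 = shared + z() @ la.T * np.sqrt(0.5)
        a2 = shared + z() @ la.T * np.sqrt(0.5)
    c = z() @ lc.T
    e1, e2 = z() @ le.T, z() @ le.T
    return a1 + c + e1, a2 + c + e2


def _draw_specific(
    rng: np.random.Generator,
    n_pairs: int,
    a2: np.ndarray,
    c2: np.ndarray,
    e2: np.ndarray,
    mz: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Rater-specific deviates per period (diagonal structure across periods).

    The A part shares like additive genetic variance across twins, the C part
    (rater bias) is applied identically to both twins, the E part is
    idiosyncratic per twin.
    """
    k = a2.size
    sa, sc, se = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
    z = lambda: rng.standard_normal((n_pairs, k))  # noqa: E731
    if mz:
        g1 = g2 = z() * sa
    else:
        shared = z() * sa * np.sqrt(0.5)
        g1 = shared + z() * sa * np.sqrt(0.5)
        g2 = shared + z() * sa * np.sqrt(0.5)
    bias = z() * sc
    return g1 + bias + z() * se, g2 + bias + z() * se


def simulate_twin_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a complete long-format twin cohort (one row per child x
    period x rater); apply :func:`apply_missingness` afterwards if partial
    observation is wanted."""
    periods = list(config.periods)
    k = len(periods)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    if config.cf_params is not None:
        sigma_a = config.cf_params.sigma_a
        sigma_c = config.cf_params.sigma_c
        sigma_e = config.cf_params.sigma_e
    else:
        mrp = config.multirater_by_period
        sigma_a = np.diag([mrp[p].common.a2 for p in periods])
        sigma_c = np.diag([mrp[p].common.c2 for p in periods])
        sigma_e = np.diag([mrp[p].common.e2 for p in periods])

    raters = ["mother"]
    if config.multirater_by_period is not None:
        raters = ["mother", "father"]
        spec_a = {
            r: np.array(
                [getattr(config.multirater_by_period[p], f"{r}_specific").a2 for p in periods]
            )
            for r in raters
        }
        spec_c = {
            r: np.array(
                [getattr(config.multirater_by_period[p], f"{r}_specific").c2 for p in periods]
            )
            for r in raters
        }
        spec_e = {
            r: np.array(
                [getattr(config.multirater_by_period[p], f"{r}_specific").e2 for p in periods]
            )
            for r in raters
        }

    frames = []
    fam_offset = 0
    for zyg, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        mz = zyg == "MZ"
        p1, p2 = _draw_ace_phenotype(rng, n_pairs, sigma_a, sigma_c, sigma_e, mz)
        family_id = fam_offset + np.arange(n_pairs)
        fam_offset += n_pairs

        age0 = rng.uniform(*config.age_range, size=n_pairs)
        if mz:
            female1 = female2 = rng.random(n_pairs) < 0.5
        else:
            female1 = rng.random(n_pairs) < 0.5
            female2 = rng.random(n_pairs) < 0.5
        pea_levels = np.array(list(config.pea_probs))
        pea = rng.choice(pea_levels, size=n_pairs, p=list(config.pea_probs.values()))

        ratings: dict[tuple[int, str], np.ndarray] = {}
        for r in raters:
            if config.multirater_by_period is not None:
                s1, s2 = _draw_specific(rng, n_pairs, spec_a[r], spec_c[r], spec_e[r], mz)
            else:
                s1 = s2 = 0.0
            ratings[(1, r)] = p1 + s1
            ratings[(2, r)] = p2 + s2

        mm = config.mean_model
        for twin, female in ((1, female1), (2, female2)):
            for j, period in enumerate(periods):
                wave = PERIOD_WAVE.get(period, j)
                age = age0 + WAVE_YEARS.get(wave, float(j))
                for r in raters:
                    mean = (
                        mm.intercepts[period]
                        + mm.beta_age * age
                        + mm.beta_sex * female
                        + (mm.father_offset if r == "father" else 0.0)
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "family_id": family_id,
                                "individual_id": family_id * 10 + twin,
                                "zygosity": zyg,
                                "wave": wave,
                                "period": period,
                                "rater": r,
                                "sex": np.where(female, "F", "M"),
                                "age": age,
                                "pea": pea,
                                "wellbeing": mean + ratings[(twin, r)][:, j],
                            }
                        )
                    )

    df = pd.concat(frames, ignore_index=True)
    if config.cantril_discretize:
        df["wellbeing"] = discretize_cantril(df["wellbeing"].to_numpy())
    df = df.sort_values(["family_id", "individual_id", "period", "rater"], kind="stable")
    df = df[OBS_COLUMNS].reset_index(drop=True)
    if config.missingness is not None:
        df = apply_missingness(df, config.missingness, seed=config.seed)
    return df


def apply_missingness(
    rows: pd.DataFrame, missingness: MissingnessConfig, seed: int
) -> pd.DataFrame:
    """Drop ratings MCAR.

    Baseline ('pre') availability is drawn once per family so both twins
    share the baseline flag (required by the selected-baseline rule); other
    periods are drawn per child; rater response is drawn per family x
    period.  Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    df = rows.copy()

    families = np.sort(df["family_id"].unique())
    children = np.sort(df["individual_id"].unique())
    fam_idx = pd.Series(np.arange(families.size), index=families)
    child_idx = pd.Series(np.arange(children.size), index=children)

    keep = np.ones(len(df), dtype=bool)
    periods_present = [p for p in PERIODS if p in set(df["period"])] or sorted(
        df["period"].unique()
    )
    for period in periods_present:
        p_obs = missingness.period_obs_prob.get(period, 1.0)
        in_period = (df["period"] == period).to_numpy()
        if period == "pre":
            flags = rng.random(families.size) < p_obs
            keep &= ~in_period | flags[fam_idx[df["family_id"]].to_numpy()]
        else:
            flags = rng.random(children.size) < p_obs
            keep &= ~in_period | flags[child_idx[df["individual_id"]].to_numpy()]
        for rater in ("mother", "father"):
            p_rater = missingness.rater_prob.get(rater, {}).get(period, 1.0)
            rflags = rng.random(families.size) < p_rater
            sel = in_period & (df["rater"] == rater).to_numpy()
            keep &= ~sel | rflags[fam_idx[df["family_id"]].to_numpy()]
    return df[keep].reset_index(drop=True)


@dataclass
class LmmCohortDesign:
    """Sampling design for the mixed-model cohorts.

    ``twin-longitudinal`` emulates the population twin register (twin pairs,
    baseline plus repeated pandemic waves, wave-wise participation);
    ``cross-sectional`` emulates the clinical/representative panels where
    each wave is a fresh sample and every child is observed once.
    """

    style: str = "twin-longitudinal"
    n_families: int = 5000
    waves: Sequence[int] = (0, 1, 2, 3, 4, 5, 6)
    participation: Mapping[int, float] = field(default_factory=dict)
    father_prob: float = 0.07
    age_range: tuple[float, float] = (7.0, 12.0)
    pea_probs: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.111, "middle": 0.372, "high": 0.517}
    )

    def __post_init__(self) -> None:
        if self.style not in ("twin-longitudinal", "cross-sectional"):
            raise ValueError(f"unknown design style {self.style!r}")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")


def simulate_lmm_cohort(
    lmm_spec: LmmSpec, design: LmmCohortDesign, seed: int
) -> pd.DataFrame:
    """Simulate a cohort from the random-intercept mean model.

    ``Y = (b1 + u_fam + u_ind) + b2*wave + b3*sex + b4*age + b5*PEA
    + b6*rater + e`` with the twin design nesting individuals within
    families; the cross-sectional design has singleton families and one
    observation per child.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    waves = list(design.waves)
    pea_levels = list(design.pea_probs)
    pea_p = list(design.pea_probs.values())

    if design.style == "twin-longitudinal":
        n_fam = design.n_families
        fam_ids = np.arange(n_fam)
        b_fam = rng.normal(0.0, np.sqrt(lmm_spec.var_family), n_fam)
        zyg_fam = np.where(rng.random(n_fam) < 0.5, "MZ", "DZ")
        age0 = rng.uniform(*design.age_range, n_fam)
        pea_fam = rng.choice(pea_levels, size=n_fam, p=pea_p)
        rows = []
        for twin in (1, 2):
            ind = fam_ids * 10 + twin
            b_ind = rng.normal(0.0, np.sqrt(lmm_spec.var_individual), n_fam)
            female = rng.random(n_fam) < 0.5
            for w in waves:
                part = design.participation.get(w, 1.0)
                obs = rng.random(n_fam) < part
                father = rng.random(n_fam) < design.father_prob
                age = age0 + WAVE_YEARS.get(w, float(w))
                e = rng.normal(0.0, np.sqrt(lmm_spec.var_residual), n_fam)
                y = (
                    lmm_spec.intercept
                    + lmm_spec.wave_effects.get(w, 0.0)
                    + lmm_spec.beta_female * female
                    + lmm_spec.beta_age * age
                    + np.where(
                        pea_fam == "low",
                        lmm_spec.beta_pea_low,
                        np.where(pea_fam == "middle", lmm_spec.beta_pea_middle, 0.0),
                    )
                    + lmm_spec.beta_father * father
                    + b_fam
                    + b_ind
                    + e
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "family_id": fam_ids[obs],
                            "individual_id": ind[obs],
                            "zygosity": zyg_fam[obs],
                            "wave": w,
                            "period": [_wave_period(w)] * int(obs.sum()),
                            "rater": np.where(father[obs], "father", "mother"),
                            "sex": np.where(female[obs], "F", "M"),
                            "age": age[obs],
                            "pea": pea_fam[obs],
                            "wellbeing": y[obs],
                        }
                    )
                )
        df = pd.concat(rows, ignore_index=True)
    else:
        n = design.n_families  # children; singleton families
        ind = np.arange(n)
        weights = np.array([design.participation.get(w, 1.0) for w in waves], dtype=float)
        weights /= weights.sum()
        wave = rng.choice(waves, size=n, p=weights)
        female = rng.random(n) < 0.5
        age = rng.uniform(*design.age_range, n)
        pea = rng.choice(pea_levels, size=n, p=pea_p)
        father = rng.random(n) < design.father_prob
        b_ind = rng.normal(0.0, np.sqrt(lmm_spec.var_individual), n)
        e = rng.normal(0.0, np.sqrt(lmm_spec.var_residual), n)
        wave_eff = np.array([lmm_spec.wave_effects.get(int(w), 0.0) for w in wave])
        y = (
            lmm_spec.intercept
            + wave_eff
            + lmm_spec.beta_female * female
            + lmm_spec.beta_age * age
            + np.where(
                pea == "low",
                lmm_spec.beta_pea_low,
                np.where(pea == "middle", lmm_spec.beta_pea_middle, 0.0),
            )
            + lmm_spec.beta_father * father
            + b_ind
            + e
        )
        df = pd.DataFrame(
            {
                "family_id": ind,
                "individual_id": ind,
                "zygosity": "none",
                "wave": wave,
                "period": [_wave_period(int(w)) for w in wave],
                "rater": np.where(father, "father", "mother"),
                "sex": np.where(female, "F", "M"),
                "age": age,
                "pea": pea,
                "wellbeing": y,
            }
        )
    df = df.sort_values(["family_id", "individual_id", "wave"], kind="stable")
    return df[OBS_COLUMNS].reset_index(drop=True)


def _wave_period(w: int) -> str:
    from .datatypes import DEFAULT_PERIOD_MAP

    return DEFAULT_PERIOD_MAP.get(int(w), "post")
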