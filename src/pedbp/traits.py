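"""Longitudinal trait assembly: covariate model, correlated environmental
components, exam-age filling, and the genotype-independent null trait Q1.

SBP and DBP are observed at three exams.  A person's value at exam *e* is

    trait(e) = mean(sex, age_e) + g + env_e

where ``g`` is the additive genetic value (constant across exams, giving a
within-trait genetic correlation of 1 over time) and ``env_e`` is one
coordinate of a zero-mean six-dimensional Gaussian (DBP exams 1-3, SBP
exams 1-3) with the fixed cross-trait/cross-exam correlation structure
below, independent across individuals.

Q1 is a Gaussian trait with additive genetic covariance ``h2 * sigma2 * A``
(A the additive relationship matrix) and independent residuals; no
genotype enters its construction, so any marker association with Q1 is a
false positive by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import PedigreeSet

__all__ = [
    "CovariateParams",
    "EnvCorrelation",
    "Q1Params",
    "ENV_COMPONENTS",
    "fill_ages",
    "expected_trait_mean",
    "simulate_environment",
    "assemble_traits",
    "simulate_q1",
]

#: Order of the six environmental components.
ENV_COMPONENTS = ("dbp_e1", "dbp_e2", "dbp_e3", "sbp_e1", "sbp_e2", "sbp_e3")

#: Correlations between the simulated environmental components
#: (upper-triangle values as published; order matches ENV_COMPONENTS).
DEFAULT_ENV_CORR = np.array(
    [
        [1.00, 0.41, 0.32, 0.34, 0.14, 0.20],
        [0.41, 1.00, 0.33, 0.23, 0.46, 0.38],
        [0.32, 0.33, 1.00, 0.06, 0.06, 0.48],
        [0.34, 0.23, 0.06, 1.00, 0.57, 0.47],
        [0.14, 0.46, 0.06, 0.57, 1.00, 0.69],
        [0.20, 0.38, 0.48, 0.47, 0.69, 1.00],
    ]
)

EXAM_GAP_12 = 3.9  # years between exams 1 and 2
EXAM_GAP_13 = 6.9  # years between exams 1 and 3


@dataclass(frozen=True)
class CovariateParams:
    """Sex and age effects on mean SBP/DBP (mmHg), centered at the study
    mean age.  DBP rises with age in females only."""

    baseline_mean_sbp: float = 122.0
    baseline_mean_dbp: float = 71.0
    female_offset_sbp: float = -5.565
    female_offset_dbp: float = -3.715
    age_slope_sbp_male: float = 0.266
    age_slope_sbp_female: float = 0.708
    age_slope_dbp_male: float = 0.0
    age_slope_dbp_female: float = 0.158
    age_center: float = 37.74

    def __post_init__(self):
        if self.age_center <= 0:
            raise ValueError("age_center must be positive")


@dataclass
class EnvCorrelation:
    """6x6 correlation of the environmental components plus per-trait
    per-exam variances (stationary across exams)."""

    corr: np.ndarray = field(default_factory=lambda: DEFAULT_ENV_CORR.copy())
    var_sbp: float = 1.0
    var_dbp: float = 1.0

    def __post_init__(self):
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (6, 6):
            raise ValueError("correlation matrix must be 6x6")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        self.repair_delta = 0.0
        if np.linalg.eigvalsh(self.corr).min() <= 1e-10:
            from statsmodels.stats.correlation_tools import corr_clipped

            repaired = corr_clipped(self.corr, threshold=1e-8)
            self.repair_delta = float(np.abs(repaired - self.corr).max())
            import logging

            logging.getLogger("pedbp").warning(
                "environmental correlation matrix repaired to nearest PSD "
                "(max entry change %.4f)",
                self.repair_delta,
            )
            self.corr = repaired

    def covariance(self) -> np.ndarray:
        sd = np.array([np.sqrt(self.var_dbp)] * 3 + [np.sqrt(self.var_sbp)] * 3)
        return self.corr * np.outer(sd, sd)


@dataclass(frozen=True)
class Q1Params:
    """Fixed effects and scale of the null trait Q1 (higher in females,
    declining with age; magnitudes are free choices of the model)."""

    mean: float = 0.0
    variance: float = 1.0
    female_offset: float = 0.3
    age_slope: float = -0.01  # per year, negative: Q1 declines with age
    h2: float = 0.68


# ---------------------------------------------------------------------------
# Exam ages


def fill_ages(schedule: pd.DataFrame) -> pd.DataFrame:
    """Complete missing exam ages using the fixed between-exam gaps of
    3.9 years (exam 1 to 2) and 6.9 years (exam 1 to 3).

    ``schedule`` has columns ``age_exam1..age_exam3`` (NaN = missing),
    indexed by person; at least one age per person is required.
    """
    out = schedule.copy()
    cols = ["age_exam1", "age_exam2", "age_exam3"]
    missing_all = out[cols].isna().all(axis=1)
    if missing_all.any():
        raise ValueError(f"all exam ages missing for {list(out.index[missing_all])[:5]}")
    a1 = out["age_exam1"].to_numpy(dtype=float)
    a2 = out["age_exam2"].to_numpy(dtype=float)
    a3 = out["age_exam3"].to_numpy(dtype=float)
    base = np.where(~np.isnan(a1), a1, np.where(~np.isnan(a2), a2 - EXAM_GAP_12, a3 - EXAM_GAP_13))
    out["age_exam1"] = np.where(np.isnan(a1), base, a1)
    out["age_exam2"] = np.where(np.isnan(a2), base + EXAM_GAP_12, a2)
    out["age_exam3"] = np.where(np.isnan(a3), base + EXAM_GAP_13, a3)
    return out


# ---------------------------------------------------------------------------
# Covariate means


def expected_trait_mean(sex, age, trait: str, params: CovariateParams = CovariateParams()):
    """Mean trait value (mmHg) for given sex and age (vectorized).

    baseline + female offset (females) + sex-specific slope x (age - center).
    """
    female = np.asarray(sex) == "female"
    age_c = np.asarray(age, dtype=float) - params.age_center
    if trait == "sbp":
        base, off = params.baseline_mean_sbp, params.female_offset_sbp
        slope = np.where(female, params.age_slope_sbp_female, params.age_slope_sbp_male)
    elif trait == "dbp":
        base, off = params.baseline_mean_dbp, params.female_offset_dbp
        slope = np.where(female, params.age_slope_dbp_female, params.age_slope_dbp_male)
    else:
        raise ValueError("trait must be 'sbp' or 'dbp'")
    out = base + np.where(female, off, 0.0) + slope * age_c
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Environmental components


def simulate_environment(
    n: int, env: EnvCorrelation, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw ``n`` independent zero-mean 6-vectors of environmental
    components with the configured covariance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = env.covariance()
    draws = rng.multivariate_normal(np.zeros(6), cov, size=n, method="cholesky")
    return pd.DataFrame(draws, columns=list(ENV_COMPONENTS))


# ---------------------------------------------------------------------------
# Trait assembly


def assemble_traits(
    genetic: pd.DataFrame,
    schedule: pd.DataFrame,
    sexes: pd.Series,
    env: pd.DataFrame,
    params: CovariateParams = CovariateParams(),
) -> pd.DataFrame:
    """Pre-treatment SBP/DBP for the three exams.

    ``genetic`` has columns ``g_sbp``/``g_dbp`` (constant across exams);
    ``schedule`` the filled exam ages; ``env`` the per-person environmental
    components (columns :data:`ENV_COMPONENTS`).  No bounds are applied,
    so implausible values (including SBP < DBP) can occur.
    Returns a wide frame with columns like ``sbp_e2`` indexed by person.
    """
    idx = genetic.index
    for other in (schedule, env):
        if not idx.equals(other.index):
            raise ValueError("inputs must share an identical person index")
    if not idx.equals(sexes.index):
        raise ValueError("inputs must share an identical person index")
    out = pd.DataFrame(index=idx)
    for trait in ("dbp", "sbp"):
        for e in (1, 2, 3):
            mean = expected_trait_mean(sexes.to_numpy(), schedule[f"age_exam{e}"], trait, params)
            out[f"{trait}_e{e}"] = mean + genetic[f"g_{trait}"].to_numpy() + env[f"{trait}_e{e}"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Null trait Q1


def simulate_q1(
    pedigrees: PedigreeSet,
    relationship: pd.DataFrame,
    ages: pd.Series,
    params: Q1Params = Q1Params(),
    seed: int | np.random.Generator = 0,
    relationship_sqrt: np.ndarray | None = None,
) -> pd.Series:
    """Simulate the heritable, genotype-independent trait Q1 (exam 1 only).

    value = mean + female offset + age slope x (age - 37.74)
          + additive deviate ~ N(0, h2 sigma2 A) + residual N(0, (1-h2) sigma2).

    ``relationship_sqrt`` may pass a precomputed symmetric square root of
    ``A`` (useful across replicates; ``A`` is constant).
    """
    if not (0.0 <= params.h2 < 1.0):
        raise ValueError("h2 must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(relationship.index)
    n = len(ids)
    if relationship_sqrt is None:
        relationship_sqrt = relationship_matrix_sqrt(relationship)
    sigma = np.sqrt(params.variance)
    g = relationship_sqrt @ rng.standard_normal(n) * sigma * np.sqrt(params.h2)
    e = rng.standard_normal(n) * sigma * np.sqrt(1.0 - params.h2)
    female = np.array([pedigrees[p].sex == "female" for p in ids])
    age_c = ages.reindex(ids).to_numpy(dtype=float) - 37.74
    fixed = params.mean + np.where(female, params.female_offset, 0.0) + params.age_slope * age_c
    return pd.Series(fixed + g + e, index=ids, name="q1")


def relationship_matrix_sqrt(relationship: pd.DataFrame) -> np.ndarray:
    """Symmetric PSD square root of the additive relationship matrix.

    ``A`` is only positive semidefinite when MZ twins are present
    (duplicated rows), so an eigendecomposition with clipped eigenvalues
    is used rather than a Cholesky factor.
    """
    w, U = np.linalg.eigh(np.asarray(relationship, dtype=float))
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("relationship matrix is not positive semidefinite")
    return (U * np.sqrt(np.clip(w, 0.0, None))) @ U.T
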