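"""Parameter recovery from simulated output.

* :func:`estimate_heritability` — single-random-effect REML under
  ``y = Xb + g + e`` with ``Cov(g) = Va A`` (A the additive relationship
  matrix) and ``Cov(e) = Ve I``.  After an eigendecomposition
  ``A = U S U'`` the model is diagonal in the rotated basis, so the
  restricted likelihood is profiled over the total variance and
  maximized over ``h2 = Va / (Va + Ve)`` in one dimension.
* :func:`recover_covariate_effects` — OLS of a trait on sex and
  sex-stratified centered age, matching the generating covariate model.
* :func:`estimate_env_correlations`, :func:`estimate_rates` — empirical
  environmental correlations and treated/smoker fractions.
* :func:`null_scan` — per-variant mixed-model score test of a trait on
  minor-allele dosage with the kinship random effect, for type-I-error
  assessment against the null trait Q1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponentFit",
    "estimate_heritability",
    "reml_loglik",
    "recover_covariate_effects",
    "estimate_env_correlations",
    "estimate_rates",
    "null_scan",
]


@dataclass(frozen=True)
class VarianceComponentFit:
    h2_estimate: float
    additive_variance: float
    residual_variance: float
    standard_error: float
    log_likelihood: float

    def __post_init__(self):
        if self.additive_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be nonnegative")


def _eigen_transform(y, X, relationship):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    A = np.asarray(relationship, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if A.shape != (n, n) or len(X) != n:
        raise ValueError("misaligned inputs")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")
    s, U = np.linalg.eigh(A)
    s = np.clip(s, 0.0, None)
    return U.T @ y, U.T @ X, s, U


def _reml_neg2(h2, yt, Xt, s):
    n, p = Xt.shape
    d = h2 * s + (1.0 - h2)
    Xd = Xt / d[:, None]
    XtX = Xt.T @ Xd
    beta = np.linalg.solve(XtX, Xd.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / d))
    sigma2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(XtX)
    return (n - p) * np.log(sigma2) + np.log(d).sum() + logdet, sigma2


def reml_loglik(h2, y, X, relationship):
    """Profiled restricted log-likelihood at heritability ``h2``
    (up to an additive constant) — exposed for oracle grid searches."""
    yt, Xt, s, _ = _eigen_transform(y, X, relationship)
    neg2, _ = _reml_neg2(h2, yt, Xt, s)
    return -0.5 * neg2


def estimate_heritability(
    trait,
    covariates,
    relationship,
    *,
    _transformed: tuple | None = None,
) -> VarianceComponentFit:
    """REML fit of the narrow-sense heritability of ``trait``.

    ``covariates`` is the fixed-effect design (an intercept column is
    added if absent); ``relationship`` the additive relationship matrix
    aligned with the trait.  Deterministic given inputs; boundary
    estimates are clamped to [0, 1).
    """
    if _transformed is not None:
        yt, Xt, s = _transformed
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.any(np.all(X == X[0, :], axis=0) & (X[0, :] != 0)):
            X = np.column_stack([np.ones(len(X)), X])
        yt, Xt, s, _ = _eigen_transform(trait, X, relationship)
    hi = 1.0 - 1e-6
    obj = lambda h2: _reml_neg2(h2, yt, Xt, s)[0]
    res = optimize.minimize_scalar(obj, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-8})
    h2 = float(res.x)
    # the bounded minimizer can stall away from a boundary optimum
    for cand in (0.0, hi):
        if obj(cand) < res.fun:
            h2 = cand
    neg2, sigma2 = _reml_neg2(h2, yt, Xt, s)
    # SE from the numerical curvature of the restricted log-likelihood
    eps = 1e-4
    lo_, hi_ = max(h2 - eps, 0.0), min(h2 + eps, hi)
    f0, fl, fh = neg2, _reml_neg2(lo_, yt, Xt, s)[0], _reml_neg2(hi_, yt, Xt, s)[0]
    curv = (fl + fh - 2 * f0) / ((hi_ - lo_) / 2) ** 2  # of -2 loglik
    se = float(np.sqrt(2.0 / curv)) if curv > 0 else float("nan")
    h2 = min(max(h2, 0.0), 1.0)
    return VarianceComponentFit(
        h2_estimate=h2,
        additive_variance=h2 * sigma2,
        residual_variance=(1.0 - h2) * sigma2,
        standard_error=se,
        log_likelihood=-0.5 * neg2,
    )


def calibrate_env_variance_reml(
    genetic,
    covariates,
    relationship,
    h2_target: float,
    *,
    _transformed: tuple | None = None,
) -> float:
    """Environmental variance that makes REML recover ``h2_target`` for a
    *realized* genetic vector.

    The simulator's genetic values are a fixed vector ``g`` (the realized
    gene-drop), not a fresh draw from N(0, Va A), so the heritability REML
    attributes to them depends on how ``g`` projects onto the relationship
    structure.  This routine solves, by root-finding over the environmental
    variance ``v``, for the value at which the minimizer of the expected
    restricted likelihood of ``y = Xb + g + e``, ``e ~ N(0, v I)``, sits at
    ``h2_target`` — replacing the data quadratic form ``y'Py`` by its
    expectation ``g'Pg + v tr(P)``.
    """
    if not (0.0 < h2_target < 1.0):
        raise ValueError("h2_target must be in (0, 1)")
    if _transformed is not None:
        gt, Xt, s = _transformed
    else:
        gt, Xt, s, _ = _eigen_transform(genetic, covariates, relationship)
    n, p = Xt.shape

    def expected_h2(v):
        def q(h2):
            d = h2 * s + (1.0 - h2)
            Xd = Xt / d[:, None]
            XtX = Xt.T @ Xd
            XtX_inv = np.linalg.inv(XtX)
            xg = Xd.T @ gt
            gPg = float(gt @ (gt / d) - xg @ (XtX_inv @ xg))
            trP = float((1.0 / d).sum() - np.trace(XtX_inv @ (Xd.T @ Xd)))
            sigma2 = (gPg + v * trP) / (n - p)
            return (n - p) * np.log(sigma2) + np.log(d).sum() + np.linalg.slogdet(XtX)[1]

        res = optimize.minimize_scalar(q, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                                       options={"xatol": 1e-10})
        return float(res.x)

    scale = float(np.var(gt[p:])) if n > p else 1.0
    lo, hi = 1e-8 * scale, 1e4 * scale
    f = lambda v: expected_h2(v) - h2_target
    if f(lo) < 0 or f(hi) > 0:  # degenerate g; fall back to the closed form
        gv = float(np.var(np.asarray(genetic, dtype=float), ddof=1)) if genetic is not None else scale
        return gv * (1.0 - h2_target) / h2_target
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def estimate_heritability_many(traits, covariates, relationship) -> list[VarianceComponentFit]:
    """REML fits for each column of ``traits`` (n x k) sharing one
    covariate design and relationship matrix; the eigendecomposition is
    done once."""
    Y = np.asarray(traits, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.any(np.all(X == X[0, :], axis=0) & (X[0, :] != 0)):
        X = np.column_stack([np.ones(len(X)), X])
    yt0, Xt, s, U = _eigen_transform(Y[:, 0], X, relationship)
    fits = [estimate_heritability(None, None, None, _transformed=(yt0, Xt, s))]
    for j in range(1, Y.shape[1]):
        fits.append(
            estimate_heritability(None, None, None, _transformed=(U.T @ Y[:, j], Xt, s))
        )
    return fits


# ---------------------------------------------------------------------------
# Covariate recovery


def recover_covariate_effects(
    phenotypes: pd.DataFrame,
    trait_col: str,
    sex_col: str = "sex",
    age_col: str = "age",
    age_center: float = 37.74,
    cluster=None,
) -> pd.DataFrame:
    """OLS of a trait on a female indicator and sex-stratified centered
    age; returns estimates and standard errors for (intercept,
    female_offset, age_slope_male, age_slope_female).

    ``cluster`` (e.g. family labels) switches to cluster-robust standard
    errors — appropriate when pooling relatives or replicates that share
    one realized set of genetic values.
    """
    import statsmodels.api as sm

    female = (phenotypes[sex_col] == "female").to_numpy(dtype=float)
    if female.min() == female.max():
        raise ValueError("both sexes must be present")
    age_c = phenotypes[age_col].to_numpy(dtype=float) - age_center
    X = np.column_stack([np.ones_like(female), female, age_c * (1 - female), age_c * female])
    model = sm.OLS(phenotypes[trait_col].to_numpy(dtype=float), X)
    if cluster is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        fit = model.fit()
    names = ["intercept", "female_offset", "age_slope_male", "age_slope_female"]
    return pd.DataFrame({"estimate": fit.params, "se": fit.bse}, index=names)


# ---------------------------------------------------------------------------
# Environmental correlations and rates


def estimate_env_correlations(env_components: pd.DataFrame) -> pd.DataFrame:
    """Empirical correlation matrix of the six environmental components
    (latent debug output pooled over persons/replicates)."""
    from .traits import ENV_COMPONENTS

    cols = [c for c in ENV_COMPONENTS if c in env_components.columns]
    if len(cols) != 6:
        raise ValueError("expected the six environmental component columns")
    return env_components[cols].corr()


def estimate_rates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-exam treated fraction among hypertensives and smoker fraction,
    with binomial standard errors, pooled over replicates.

    Expects long format with columns exam, htn, meds, smoke.
    """
    rows = []
    for exam, grp in phenotypes.groupby("exam"):
        htn = grp["htn"].to_numpy(dtype=bool)
        meds = grp["meds"].to_numpy(dtype=bool)
        smoke = grp["smoke"].to_numpy(dtype=bool)
        n_htn = int(htn.sum())
        tf = float(meds[htn].mean()) if n_htn else float("nan")
        sf = float(smoke.mean())
        rows.append(
            {
                "exam": exam,
                "treated_fraction": tf,
                "treated_se": np.sqrt(tf * (1 - tf) / n_htn) if n_htn else float("nan"),
                "n_hypertensive": n_htn,
                "smoker_fraction": sf,
                "smoker_se": np.sqrt(sf * (1 - sf) / len(grp)),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows).set_index("exam")


# ---------------------------------------------------------------------------
# Null association scan


def null_scan(
    trait: pd.Series,
    dosages: pd.DataFrame,
    covariates,
    relationship: pd.DataFrame,
    alpha: float = 0.05,
    return_pvalues: bool = False,
):
    """Mixed-model score test of ``trait`` against every dosage column.

    The null model (no marker) is fitted once by REML; each variant's
    score statistic ``(g' P y)^2 / (g' P g)`` is chi-square(1) under the
    null.  Returns the fraction of p-values below ``alpha`` (and the
    p-values themselves with ``return_pvalues``); monomorphic variants
    are skipped and counted.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    ids = list(trait.index)
    G = dosages.reindex(ids).to_numpy(dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.any(np.all(X == X[0, :], axis=0) & (X[0, :] != 0)):
        X = np.column_stack([np.ones(len(X)), X])
    y = trait.to_numpy(dtype=float)
    A = relationship.reindex(index=ids, columns=ids).to_numpy(dtype=float)
    yt, Xt, s, U = _eigen_transform(y, X, A)
    fit = estimate_heritability(y, X, A, _transformed=(yt, Xt, s))
    h2 = fit.h2_estimate
    sigma2 = fit.additive_variance + fit.residual_variance
    d = sigma2 * (h2 * s + (1.0 - h2))
    # projection P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 in the rotated basis
    w = 1.0 / d
    WX = Xt * w[:, None]
    XtVX_inv = np.linalg.inv(Xt.T @ WX)

    def P(M):
        WM = M * w[:, None]
        return WM - WX @ (XtVX_inv @ (WX.T @ M))

    Gt = U.T @ G
    Py = P(yt[:, None])[:, 0]
    PG = P(Gt)
    mono = G.std(axis=0) == 0.0
    score = Gt.T @ Py
    var = np.einsum("ij,ij->j", Gt, PG)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = score**2 / var
    pvals = stats.chi2.sf(chi2[~mono], df=1)
    rate = float((pvals < alpha).mean()) if len(pvals) else float("nan")
    if return_pvalues:
        return rate, pvals, int(mono.sum())
    return rate
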