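import numpy as np
import pandas as pd
import pytest

from pedbp import additive_relationship, generate_pedigree_set
from pedbp.estimation import (
    calibrate_env_variance_reml,
    estimate_heritability,
    estimate_heritability_many,
    null_scan,
    recover_covariate_effects,
    reml_loglik,
)
from pedbp.traits import Q1Params, simulate_q1


@pytest.fixture(scope="module")
def ped100():
    """~100-person pedigree set with its relationship matrix."""
    ps = generate_pedigree_set(5, (18, 24), 0, seed=42)
    return ps, additive_relationship(ps)


def _simulate(ps, A, h2, sigma2=1.0, seed=0):
    ages = pd.Series(40.0, index=A.index)
    return simulate_q1(
        ps, A, ages, Q1Params(h2=h2, variance=sigma2, female_offset=0, age_slope=0), seed=seed
    ).to_numpy()


class TestREML:
    def test_matches_grid_search_oracle(self, ped100):
        """REML optimum agrees with a brute-force grid over h2."""
        ps, A = ped100
        n = len(ps)
        X = np.ones((n, 1))
        for seed in (1, 2, 3):
            y = _simulate(ps, A, h2=0.5, seed=seed)
            grid = np.arange(0.0, 1.0, 0.01)
            ll = [reml_loglik(h, y, X, A) for h in grid]
            oracle = grid[int(np.argmax(ll))]
            fit = estimate_heritability(y, X, A)
            assert abs(fit.h2_estimate - oracle) <= 0.01

    def test_affine_invariance(self, ped100):
        ps, A = ped100
        y = _simulate(ps, A, h2=0.4, seed=9)
        X = np.ones((len(y), 1))
        base = estimate_heritability(y, X, A)
        scaled = estimate_heritability(3.2 * y - 7.0, X, A)
        assert scaled.h2_estimate == pytest.approx(base.h2_estimate, abs=1e-5)
        assert scaled.additive_variance == pytest.approx(3.2**2 * base.additive_variance, rel=1e-3)

    def test_null_heritability(self, ped100):
        ps, A = ped100
        rng = np.random.default_rng(7)
        ests = []
        for _ in range(30):
            y = rng.standard_normal(len(ps))
            ests.append(estimate_heritability(y, np.ones((len(y), 1)), A).h2_estimate)
        assert np.mean(ests) < 0.15  # boundary-clamped near zero

    def test_parameter_recovery(self, ped100):
        """Mean REML estimate over 50 draws is within 3 MC-SEs of truth."""
        ps, A = ped100
        truth = 0.6
        Y = np.column_stack([_simulate(ps, A, h2=truth, seed=s) for s in range(50)])
        fits = estimate_heritability_many(Y, np.ones((len(ps), 1)), A)
        est = np.array([f.h2_estimate for f in fits])
        mcse = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - truth) < 3 * mcse

    def test_variance_decomposition_consistent(self, ped100):
        ps, A = ped100
        y = _simulate(ps, A, h2=0.5, seed=5)
        fit = estimate_heritability(y, np.ones((len(y), 1)), A)
        tot = fit.additive_variance + fit.residual_variance
        assert fit.h2_estimate == pytest.approx(fit.additive_variance / tot, abs=1e-8)

    def test_singular_design_rejected(self, ped100):
        ps, A = ped100
        y = _simulate(ps, A, h2=0.5, seed=5)
        X = np.ones((len(y), 2))  # duplicated intercept
        with pytest.raises(ValueError, match="singular"):
            estimate_heritability(y, X, A)


class TestCalibration:
    def test_env_variance_puts_reml_at_target(self, ped100):
        """Calibrated environmental variance centers REML on the target
        for a fixed realized genetic vector (MC check over noise draws)."""
        ps, A = ped100
        n = len(ps)
        rng = np.random.default_rng(11)
        g = (A.to_numpy() @ rng.standard_normal(n)) * 0.3  # an A-structured vector
        X = np.ones((n, 1))
        target = 0.35
        v = calibrate_env_variance_reml(g, X, A, target)
        ests = []
        for _ in range(60):
            y = g + rng.normal(0, np.sqrt(v), n)
            ests.append(estimate_heritability(y, X, A).h2_estimate)
        est = np.array(ests)
        mcse = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - target) < 4 * mcse


class TestCovariateRecovery:
    def test_noise_free_exact(self):
        """Deterministic input built from the covariate model alone is
        recovered exactly."""
        from pedbp.traits import expected_trait_mean

        rng = np.random.default_rng(0)
        sex = np.where(rng.random(500) < 0.5, "female", "male")
        age = rng.uniform(20, 80, 500)
        df = pd.DataFrame(
            {"sex": sex, "age": age, "dbp": expected_trait_mean(sex, age, "dbp")}
        )
        tab = recover_covariate_effects(df, "dbp")
        assert tab.loc["female_offset", "estimate"] == pytest.approx(-3.715, abs=1e-8)
        assert tab.loc["age_slope_male", "estimate"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["age_slope_female", "estimate"] == pytest.approx(0.158, abs=1e-8)

    def test_permuted_ages_flatten_slopes(self):
        from pedbp.traits import expected_trait_mean

        rng = np.random.default_rng(1)
        sex = np.where(rng.random(4000) < 0.5, "female", "male")
        age = rng.uniform(20, 80, 4000)
        y = expected_trait_mean(sex, age, "sbp") + rng.normal(0, 5, 4000)
        df = pd.DataFrame({"sex": sex, "age": rng.permutation(age), "sbp": y})
        tab = recover_covariate_effects(df, "sbp")
        for coef in ("age_slope_male", "age_slope_female"):
            assert abs(tab.loc[coef, "estimate"]) < 3 * tab.loc[coef, "se"] + 0.05

    def test_single_sex_rejected(self):
        df = pd.DataFrame({"sex": ["male"] * 10, "age": range(10), "sbp": range(10)})
        with pytest.raises(ValueError, match="sexes"):
            recover_covariate_effects(df, "sbp")


class TestNullScan:
    def test_alpha_zero(self, ped100):
        ps, A = ped100
        rng = np.random.default_rng(3)
        y = pd.Series(_simulate(ps, A, h2=0.3, seed=2), index=A.index)
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, size=(len(ps), 50)),
            index=A.index,
            columns=[f"1:{i + 1}" for i in range(50)],
        )
        X = np.ones((len(ps), 1))
        assert null_scan(y, dos, X, A, alpha=0.0) == 0.0

    def test_monomorphic_skipped(self, ped100):
        ps, A = ped100
        rng = np.random.default_rng(4)
        y = pd.Series(_simulate(ps, A, h2=0.3, seed=4), index=A.index)
        dos = pd.DataFrame(
            {"1:1": np.zeros(len(ps)), "1:2": rng.binomial(2, 0.4, len(ps))}, index=A.index
        )
        rate, pvals, n_mono = null_scan(y, dos, np.ones((len(ps), 1)), A, 0.05, return_pvalues=True)
        assert n_mono == 1
        assert len(pvals) == 1
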