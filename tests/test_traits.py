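import numpy as np
import pandas as pd
import pytest

from pedbp import additive_relationship
from pedbp.traits import (
    DEFAULT_ENV_CORR,
    ENV_COMPONENTS,
    CovariateParams,
    EnvCorrelation,
    Q1Params,
    assemble_traits,
    expected_trait_mean,
    fill_ages,
    simulate_environment,
    simulate_q1,
)


class TestFillAges:
    def _sched(self, a1, a2, a3):
        return pd.DataFrame(
            {"age_exam1": [a1], "age_exam2": [a2], "age_exam3": [a3]}, index=["p"]
        )

    @pytest.mark.parametrize(
        "given,expected",
        [
            ((40.0, None, None), (40.0, 43.9, 46.9)),
            ((None, 43.9, None), (40.0, 43.9, 46.9)),  # subtracting works too
            ((None, None, 46.9), (40.0, 43.9, 46.9)),
            ((40.0, 43.9, 46.9), (40.0, 43.9, 46.9)),  # complete input unchanged
        ],
    )
    def test_offsets(self, given, expected):
        out = fill_ages(self._sched(*[np.nan if v is None else v for v in given]))
        got = tuple(out.loc["p"])
        assert got == pytest.approx(expected)

    def test_all_missing(self):
        with pytest.raises(ValueError, match="missing"):
            fill_ages(self._sched(np.nan, np.nan, np.nan))


class TestCovariateMeans:
    def test_reference_values(self):
        p = CovariateParams()
        assert expected_trait_mean("male", 37.74, "dbp", p) == pytest.approx(71.0)
        assert expected_trait_mean("female", 37.74, "dbp", p) == pytest.approx(67.285)
        # DBP does not rise with age in males
        assert expected_trait_mean("male", 47.74, "dbp", p) == pytest.approx(71.0)
        assert expected_trait_mean("female", 47.74, "dbp", p) == pytest.approx(67.285 + 1.58)
        assert expected_trait_mean("male", 47.74, "sbp", p) == pytest.approx(122 + 2.66)
        assert expected_trait_mean("female", 37.74, "sbp", p) == pytest.approx(116.435)


class TestEnvironment:
    def test_correlations_converge(self):
        env = EnvCorrelation()
        draws = simulate_environment(100_000, env, seed=5)
        corr = draws.corr().to_numpy()
        assert np.abs(corr - DEFAULT_ENV_CORR).max() < 0.01
        assert np.abs(draws.mean()).max() < 0.02

    def test_individuals_independent(self):
        env = EnvCorrelation()
        draws = simulate_environment(100_000, env, seed=6).to_numpy()
        a, b = draws[::2], draws[1::2]  # consecutive "pairs of individuals"
        r = np.corrcoef(a[:, 0], b[:, 0])[0, 1]
        assert abs(r) < 0.01

    def test_validation(self):
        bad = DEFAULT_ENV_CORR.copy()
        bad[0, 1] = 0.9  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            EnvCorrelation(corr=bad)

    def test_non_pd_repair(self):
        c = np.full((6, 6), 0.9)
        np.fill_diagonal(c, 1.0)
        c[0, 1] = c[1, 0] = -0.9  # impossible jointly with the rest
        env = EnvCorrelation(corr=c)
        assert env.repair_delta > 0
        assert np.linalg.eigvalsh(env.corr).min() > -1e-10


class TestAssembly:
    def _inputs(self, n=4):
        idx = pd.Index([f"p{i}" for i in range(n)], name="person_id")
        g = pd.DataFrame({"g_sbp": np.zeros(n), "g_dbp": np.zeros(n)}, index=idx)
        sched = pd.DataFrame(
            {"age_exam1": [37.74] * n, "age_exam2": [41.64] * n, "age_exam3": [44.64] * n},
            index=idx,
        )
        sexes = pd.Series(["male"] * n, index=idx)
        env = pd.DataFrame(np.zeros((n, 6)), index=idx, columns=list(ENV_COMPONENTS))
        return g, sched, sexes, env

    def test_zero_components_give_baseline(self):
        g, sched, sexes, env = self._inputs()
        out = assemble_traits(g, sched, sexes, env)
        assert out["sbp_e1"].eq(122.0).all()
        assert out["dbp_e1"].eq(71.0).all()
        # exams 2-3 move only through the age effect (male SBP slope 0.266)
        assert out["sbp_e2"].iloc[0] == pytest.approx(122 + 0.266 * 3.9)
        assert out["dbp_e3"].iloc[0] == pytest.approx(71.0)

    def test_genetic_constant_across_exams(self, study_default, reps20):
        """trait - covariate mean - env is one constant per person/trait
        (within-trait genetic correlation of 1 over time)."""
        rep = reps20[0]
        lat = rep.latent
        ids = lat.index
        sched = study_default.schedule.loc[ids]
        sexes = study_default.sexes.reindex(ids)
        for e in (1, 2, 3):
            mean = expected_trait_mean(sexes.to_numpy(), sched[f"age_exam{e}"], "sbp")
            resid = lat[f"raw_sbp_e{e}"] - mean - lat[f"sbp_e{e}"]
            np.testing.assert_allclose(resid.to_numpy(), lat["g_sbp"].to_numpy(), atol=1e-8)

    def test_misaligned_index(self):
        g, sched, sexes, env = self._inputs()
        with pytest.raises(ValueError, match="index"):
            assemble_traits(g, sched.iloc[::-1], sexes, env)

    def test_implausible_values_not_clamped(self):
        """No floors/ceilings and no SBP > DBP constraint: an extreme
        genetic value pushes simulated SBP below simulated DBP."""
        g, sched, sexes, env = self._inputs()
        g["g_sbp"] -= 80.0
        out = assemble_traits(g, sched, sexes, env)
        assert (out["sbp_e1"] < out["dbp_e1"]).all()
        assert (out["sbp_e1"] == 42.0).all()  # exact, nothing floored


class TestQ1:
    def test_h2_zero_unrelated(self, ped11):
        A = additive_relationship(ped11)
        ages = pd.Series(40.0, index=A.index)
        draws = np.array(
            [
                simulate_q1(ped11, A, ages, Q1Params(h2=0.0, female_offset=0, age_slope=0), seed=s)
                for s in range(400)
            ]
        )
        # parent-offspring covariance vanishes when h2 = 0
        i, j = list(A.index).index("gp1"), list(A.index).index("p1")
        r = np.corrcoef(draws[:, i], draws[:, j])[0, 1]
        assert abs(r) < 0.15

    def test_relatives_correlated_at_h2(self, ped11):
        A = additive_relationship(ped11)
        ages = pd.Series(40.0, index=A.index)
        params = Q1Params(h2=0.68, female_offset=0, age_slope=0)
        draws = np.array(
            [simulate_q1(ped11, A, ages, params, seed=s) for s in range(400)]
        )
        i, j = list(A.index).index("t1"), list(A.index).index("t2")
        r_mz = np.corrcoef(draws[:, i], draws[:, j])[0, 1]
        assert r_mz == pytest.approx(0.68, abs=0.08)  # MZ correlation = h2

    def test_h2_domain(self, ped11):
        A = additive_relationship(ped11)
        ages = pd.Series(40.0, index=A.index)
        with pytest.raises(ValueError):
            simulate_q1(ped11, A, ages, Q1Params(h2=1.0), seed=0)
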