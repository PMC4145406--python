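import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedbp import effects
from pedbp.effects import (
    EffectCatalog,
    build_background_set,
    calibrate_environment,
    coding_effect_magnitude,
    effect_direction,
    genetic_value,
    load_functional_catalog,
    load_interaction_catalog,
    make_background_candidates,
    variance_explained,
)
from pedbp.genotypes import VariantDef


class TestEffectFormula:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((0.0, 0.5, 0.5, 1.0, 1.0), 0.0),  # PP2S of zero kills the product
            ((0.5, 0.5, 0.0, 1.0, 1.0), 0.0),  # so does zero genetic correlation
            ((1.0, 1.0, 0.5, 2.0, 1.0), 1.0),  # direct product
            ((0.8, 0.25, -0.5, 1.0, 2.0), 0.25 * 0.64 * 0.5 * 2.0),
        ],
    )
    def test_magnitude(self, args, expected):
        assert coding_effect_magnitude(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (0.5, 1.5, 0.5), (0.5, 0.5, 2.0)])
    def test_magnitude_range_errors(self, bad):
        with pytest.raises(ValueError):
            coding_effect_magnitude(*bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pp2s=st.floats(0, 1),
        delta=st.floats(0, 0.5),
        perc=st.floats(0, 1),
        rho=st.floats(-1, 1),
    )
    def test_magnitude_monotone_in_pp2s(self, pp2s, delta, perc, rho):
        lo = coding_effect_magnitude(pp2s, perc, rho)
        hi = coding_effect_magnitude(min(pp2s + delta, 1.0), perc, rho)
        assert hi >= lo

    def test_direction_rules(self):
        # deleterious coding variants push against the mRNA-trait correlation
        assert effect_direction(+1, "coding") == -1
        assert effect_direction(-1, "coding") == +1
        # regulatory variants follow the observed correlation
        assert effect_direction(+1, "regulatory") == +1
        assert effect_direction(-1, "regulatory") == -1
        with pytest.raises(ValueError):
            effect_direction(0, "coding")


class TestCatalogFixtures:
    def test_functional_catalog(self):
        cat = load_functional_catalog()
        assert len(cat) == 55
        top = {f.variant.key: f for f in cat}["3:48040283"]
        assert top.beta_sbp == -9.91
        assert top.beta_dbp == -6.22
        assert top.variant.maf == 0.0318
        assert top.variant.gene == "MAP4"

    def test_interaction_catalog(self):
        inter = load_interaction_catalog()
        assert len(inter) == 3
        assert {i.polyphen_score for i in inter} == {0.983, 0.99, 0.925}
        assert {i.variant.maf for i in inter} == {0.0068, 0.0016, 0.0501}
        assert all(i.variant.gene == "CYP3A43" and i.variant.chromosome == "7" for i in inter)


class TestBackground:
    def test_half_signs_and_magnitudes(self):
        cands = make_background_candidates(1500, seed=1)
        bg = build_background_set(cands, 1000, seed=2)
        signs = np.array(bg.signs)
        assert (signs > 0).sum() == 500
        assert (signs < 0).sum() == 500
        assert bg.magnitude_sbp == 0.11187
        assert bg.magnitude_dbp == 0.08786
        assert all(v.maf > 0.4 for v in bg.variants)

    def test_varies_by_seed(self):
        cands = make_background_candidates(1500, seed=1)
        a = build_background_set(cands, 1000, seed=2)
        b = build_background_set(cands, 1000, seed=3)
        assert {v.key for v in a.variants} != {v.key for v in b.variants}

    def test_empty_and_insufficient(self):
        cands = make_background_candidates(10, seed=1)
        empty = build_background_set(cands, 0, seed=0)
        assert len(empty.variants) == 0
        with pytest.raises(ValueError, match="candidates"):
            build_background_set(cands, 1000, seed=0)


class TestGeneticValue:
    def _catalog_one(self, beta_sbp=2.0):
        v = VariantDef(chromosome="1", position=10, maf=0.2, category="coding")
        from pedbp.effects import FunctionalVariant

        return EffectCatalog(functional=[FunctionalVariant(variant=v, beta_sbp=beta_sbp)])

    def test_single_variant_dosage_scaling(self):
        cat = self._catalog_one(beta_sbp=2.0)
        dos = pd.DataFrame({"1:10": [0, 1, 2]}, index=["a", "b", "c"])
        g = genetic_value(dos, cat, "sbp")
        # pre-centering values {0, b, 2b}: differences preserved after centering
        assert g["b"] - g["a"] == pytest.approx(2.0)
        assert g["c"] - g["a"] == pytest.approx(4.0)
        assert g.mean() == pytest.approx(0.0)

    def test_all_zero_dosages(self):
        cat = self._catalog_one()
        dos = pd.DataFrame({"1:10": [0, 0, 0]}, index=["a", "b", "c"])
        assert (genetic_value(dos, cat, "sbp") == 0).all()

    def test_missing_column_names_variant(self):
        cat = self._catalog_one()
        dos = pd.DataFrame({"1:99": [0, 1]}, index=["a", "b"])
        with pytest.raises(KeyError, match="1:10"):
            genetic_value(dos, cat, "sbp")

    def test_hwe_variance_matches_closed_form(self, rng):
        """Variance of the top-variant SBP term at HWE, n=50,000, equals
        2 p q beta^2 (~6.05 mmHg^2) within Monte-Carlo tolerance."""
        p, beta = 0.0318, -9.91
        dosages = rng.binomial(2, p, size=50_000).astype(float)
        term = beta * dosages
        expected = 2 * p * (1 - p) * beta**2
        # SE of the sample variance via the fourth central moment
        mu = 2 * p * beta
        m4 = np.mean((term - mu) ** 4)
        se = np.sqrt((m4 - expected**2) / 50_000)
        assert abs(term.var(ddof=1) - expected) < 3 * se


class TestCalibration:
    @pytest.mark.parametrize(
        "vg,h2,expected",
        [(10.0, 0.5, 10.0), (10.0, 0.317, 10.0 * 0.683 / 0.317), (10.0, 0.999999, 1e-5)],
    )
    def test_closed_form(self, vg, h2, expected):
        assert calibrate_environment(vg, h2) == pytest.approx(expected, rel=1e-3, abs=1e-4)

    @pytest.mark.parametrize("h2", [0.0, 1.0, -0.2, 1.5])
    def test_h2_domain(self, h2):
        with pytest.raises(ValueError):
            calibrate_environment(10.0, h2)

    def test_realized_h2_exact(self):
        vg = 7.3
        ve = calibrate_environment(vg, 0.279)
        assert vg / (vg + ve) == pytest.approx(0.279)


class TestVarianceExplained:
    def test_direct_substitution(self):
        assert variance_explained(0.0, 0.5, 100.0) == 0.0
        assert variance_explained(1.0, 0.5, 100.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.5, 0.0)

    def test_gene_level_additivity_unlinked(self, rng):
        """With unlinked variants, gene-level variance explained is the sum
        of per-variant contributions (covariances vanish)."""
        cat = load_functional_catalog()
        map4 = [f for f in cat if f.variant.gene == "MAP4"]
        n = 50_000
        total = np.zeros(n)
        per_variant_ve = 0.0
        sigma2 = 217.5
        for f in map4:
            d = rng.binomial(2, f.variant.maf, size=n).astype(float)
            total += f.beta_sbp * d
            per_variant_ve += variance_explained(f.beta_sbp, d.var(ddof=1), sigma2)
        gene_ve = 100 * total.var(ddof=1) / sigma2
        assert gene_ve == pytest.approx(per_variant_ve, rel=0.02)
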