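"""Phenotype statistics: descriptives, variance components, heritability,
BLUP shrinkage, STI identities and trait correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magicscan import (blup_line_effects, descriptive_stats,
                       fit_variance_components, heritability,
                       lsmeans_and_correlations, stress_tolerance_index,
                       sti_table)
from magicscan.phenostats import VarianceComponents, treatment_effect_test


def _long(records):
    return pd.DataFrame(records,
                        columns=["line", "trait", "treatment", "year", "value"])


class TestDescriptives:
    def test_constant_vector_has_zero_sd_and_cv(self):
        d = descriptive_stats([3.0, 3.0, 3.0])
        assert d.sd == 0 and d.cv == 0 and d.se == 0

    def test_known_vector(self):
        d = descriptive_stats([2.0, 4.0, 6.0, 8.0])
        assert d.mean == 5.0 and d.min == 2.0 and d.max == 8.0
        assert d.sd == pytest.approx(np.std([2, 4, 6, 8], ddof=1))
        assert d.cv == pytest.approx(100 * d.sd / 5.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            descriptive_stats([1.0, np.nan])

    def test_zero_mean_flags_cv_undefined(self):
        assert descriptive_stats([-1.0, 1.0]).cv is None


class TestVarianceComponents:
    # 3 lines x 2 years, one record per cell; hand-worked two-way ANOVA:
    # MS_line = 42, MS_residual = 2  ->  VG = (42-2)/2 = 20, VE = 2.
    TOY = _long([("A", "t", "WW", 1, 10.0), ("A", "t", "WW", 2, 12.0),
                 ("B", "t", "WW", 1, 14.0), ("B", "t", "WW", 2, 14.0),
                 ("C", "t", "WW", 1, 18.0), ("C", "t", "WW", 2, 22.0)])

    def test_toy_matches_hand_computed_ems(self):
        vc = fit_variance_components(self.TOY, "t", "WW")
        assert vc.VG == pytest.approx(20.0)
        assert vc.VE == pytest.approx(2.0)
        assert vc.VGY == 0.0 and vc.confounded

    def test_noise_free_lines_give_pure_genetic_variance(self):
        tab = _long([(l, "t", "WW", yr, v) for l, v in
                     zip("ABC", [5.0, 7.0, 9.0]) for yr in (1, 2)])
        vc = fit_variance_components(tab, "t", "WW")
        assert vc.VE == pytest.approx(0.0, abs=1e-12)
        assert vc.VG == pytest.approx(np.var([5, 7, 9], ddof=1))

    def test_replicated_recovery_within_3se(self):
        # VG=4, VGY=1, VE=1; 120 lines x 2 years x 2 reps, 50 replicates
        rng = np.random.default_rng(42)
        l, yn, r, reps = 120, 2, 2, 50
        est = []
        for _ in range(reps):
            g = rng.normal(0, 2, l)
            gy = rng.normal(0, 1, (l, yn))
            ye = rng.normal(0, 0.7, yn)
            rows = [(f"L{i}", "t", "WW", j, 10 + g[i] + ye[j] + gy[i, j]
                     + rng.normal())
                    for i in range(l) for j in range(yn) for _k in range(r)]
            vc = fit_variance_components(_long(rows), "t", "WW")
            est.append((vc.VG, vc.VGY, vc.VE))
        est = np.array(est)
        for k, truth in enumerate([4.0, 1.0, 1.0]):
            se = est[:, k].std(ddof=1) / np.sqrt(reps)
            assert abs(est[:, k].mean() - truth) < 3 * se + 1e-9

    def test_single_year_rejected(self):
        tab = _long([("A", "t", "WW", 1, 1.0), ("B", "t", "WW", 1, 2.0)])
        with pytest.raises(ValueError, match="2 years"):
            fit_variance_components(tab, "t", "WW")

    def test_unbalanced_em_reml_close_to_balanced_answer(self):
        vc_bal = fit_variance_components(self.TOY, "t", "WW")
        # duplicate one cell to unbalance the layout slightly
        extra = self.TOY.iloc[[0]].assign(value=10.0)
        vc_unb = fit_variance_components(
            pd.concat([self.TOY, extra], ignore_index=True), "t", "WW")
        assert vc_unb.method == "em-reml" and vc_unb.converged
        assert vc_unb.VG == pytest.approx(vc_bal.VG, rel=0.5)


class TestHeritability:
    def test_pure_genetic_gives_one(self):
        assert heritability(VarianceComponents(1, 0, 0, y=2)) == 1.0

    def test_direct_substitution(self):
        assert heritability(VarianceComponents(1, 0, 2, y=2)) == pytest.approx(0.5)

    def test_undefined_when_all_zero(self):
        assert np.isnan(heritability(VarianceComponents(0, 0, 0, y=2)))

    def test_bounded_and_monotone_in_vg(self):
        h = [heritability(VarianceComponents(vg, 0.5, 1.0, y=2))
             for vg in np.linspace(0, 10, 25)]
        assert all(0 <= x <= 1 for x in h)
        assert np.all(np.diff(h) >= 0)


class TestBlup:
    def test_single_record_per_line_returns_raw_deviations(self):
        tab = _long([(l, "t", "WW", 1, v) for l, v in zip("ABCD", [1., 2., 3., 6.])])
        res = blup_line_effects(tab, "t", "WW", 1)
        assert not res.identified
        assert res.effects["D"] == pytest.approx(6.0 - 3.0)

    def test_balanced_closed_form_shrinkage(self):
        # 40 lines x 4 reps with known components; BLUP_i must equal
        # (s2g/(s2g+s2e/n))(ybar_i - mu) with the fitted components
        rng = np.random.default_rng(3)
        l, n = 40, 4
        g = rng.normal(0, 1.0, l)
        rows = [(f"L{i:02d}", "t", "WW", 1, 5 + g[i] + rng.normal(0, 1.0))
                for i in range(l) for _ in range(n)]
        tab = _long(rows)
        res = blup_line_effects(tab, "t", "WW", 1)
        means = tab.groupby("line")["value"].mean()
        lam = res.sigma2_g / (res.sigma2_g + res.sigma2_e / n)
        expected = lam * (means - tab["value"].mean())
        assert np.allclose(res.effects, expected.loc[res.effects.index])
        # shrinkage inequality: same sign, no larger magnitude
        dev = means - tab["value"].mean()
        assert np.all(np.abs(res.effects) <= np.abs(dev.loc[res.effects.index]) + 1e-12)
        assert np.all(res.effects * dev.loc[res.effects.index] >= 0)

    def test_blups_rank_correlate_with_true_effects(self):
        # reliability of a 4-rep mean at s2g=1, s2e=0.5 is 1/(1+0.125)=0.889,
        # so corr(BLUP, truth) ~ sqrt(0.889) ~ 0.94
        rng = np.random.default_rng(4)
        l, n = 534, 4
        g = rng.normal(0, 1.0, l)
        rows = [(f"L{i:03d}", "t", "WW", 1, g[i] + rng.normal(0, np.sqrt(0.5)))
                for i in range(l) for _ in range(n)]
        res = blup_line_effects(_long(rows), "t", "WW", 1)
        truth = pd.Series(g, index=[f"L{i:03d}" for i in range(l)])
        rho = res.effects.corr(truth.loc[res.effects.index], method="spearman")
        assert rho > 0.9


class TestSTI:
    def test_identity_cases(self):
        assert stress_tolerance_index(10, 10, 10) == pytest.approx(1.0)
        assert stress_tolerance_index(10, 5, 10) == pytest.approx(0.5)
        assert stress_tolerance_index(10, 0, 10) == 0.0

    @given(st.floats(0.1, 1e3), st.floats(0.0, 1e3), st.floats(0.1, 1e3),
           st.floats(0.1, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, yp, ys, ypm, c):
        a = stress_tolerance_index(yp, ys, ypm)
        b = stress_tolerance_index(c * yp, c * ys, c * ypm)
        assert np.isclose(a, b, rtol=1e-9)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            stress_tolerance_index(1.0, 1.0, 0.0)

    def test_table_uses_per_year_control_mean(self):
        tab = _long([("A", "t", "WW", 1, 10.0), ("A", "t", "TD", 1, 5.0),
                     ("B", "t", "WW", 1, 10.0), ("B", "t", "TD", 1, 10.0),
                     ("A", "t", "WW", 2, 20.0), ("A", "t", "TD", 2, 20.0),
                     ("B", "t", "WW", 2, 20.0), ("B", "t", "TD", 2, 20.0)])
        sti = sti_table(tab).set_index(["line", "year"])["sti"]
        assert sti[("A", 1)] == pytest.approx(10 * 5 / 100)
        assert sti[("A", 2)] == pytest.approx(1.0)


class TestCorrelations:
    def test_self_correlation_is_one_and_matrix_symmetric(self, small_dataset):
        _, r, n = lsmeans_and_correlations(small_dataset.phenotypes, "WW")
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert (n >= 3).all().all()

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(8)
        lines = [f"L{i}" for i in range(534)]
        tab = pd.concat([
            _long([(l, t, "WW", 1, rng.normal()) for l in lines])
            for t in ("a", "b")])
        _, r, _ = lsmeans_and_correlations(tab, "WW")
        assert abs(r.loc["a", "b"]) < 0.12

    def test_linear_dependence_gives_unit_correlation(self):
        lines = [f"L{i}" for i in range(20)]
        base = np.arange(20.0)
        tab = pd.concat([_long([(l, "a", "WW", 1, v) for l, v in zip(lines, base)]),
                         _long([(l, "b", "WW", 1, 2 * v + 1e-9) for l, v in
                                zip(lines, base)])])
        _, r, _ = lsmeans_and_correlations(tab, "WW")
        assert r.loc["a", "b"] == pytest.approx(1.0)


def test_treatment_effect_detected_on_shifted_trait(small_dataset):
    out = treatment_effect_test(small_dataset.phenotypes, "NK")
    assert out["P"] < 1e-6 and out["mean_difference"] > 0
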