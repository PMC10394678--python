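"""Scan machinery: sequential F-tests, permutation thresholds, forward
selection, FDR adjustment, cross-validation, interaction scan and explained
variance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magicscan import (ScanConfig, cross_validate_qtl, fdr_adjust,
                       forward_multilocus_scan, mxt_scan,
                       permutation_threshold, single_marker_test,
                       variance_explained)


def brute_force_bh(p):
    """Step-up definition applied literally: adj_(i) = min over j >= i of
    min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestSingleMarker:
    def test_hand_computed_anova_f(self):
        # two genotype groups {1,2,3} vs {4,5,6}: F = 13.5 on (1, 4) df
        y = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array([0.0, 0, 0, 2, 2, 2])
        t = single_marker_test(y, g)
        assert t.F == pytest.approx(13.5)
        assert t.P == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_perfect_fit_gives_zero_p(self):
        y = np.array([0.0, 0, 2, 2, 0, 2])
        t = single_marker_test(y, y.copy())
        assert t.P < 1e-12

    def test_constant_marker_skipped_with_reason(self):
        t = single_marker_test(np.arange(6.0), np.full(6, 2.0))
        assert t.skipped is not None

    def test_collinear_with_cofactor_skipped(self):
        g = np.array([0.0, 0, 2, 2, 0, 2])
        t = single_marker_test(np.arange(6.0), g, cofactors=g.reshape(-1, 1))
        assert t.skipped is not None

    def test_null_pvalues_uniform(self):
        # independent response: P must be U(0,1); KS over 1000 replicates
        rng = np.random.default_rng(5)
        n = 120
        g = rng.choice([0.0, 2.0], size=n)
        ps = [single_marker_test(rng.normal(size=n), g).P for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFdr:
    def test_hand_applied_step_up(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.all(fdr_adjust([1.0, 1.0, 1.0]) == 1.0)
        assert fdr_adjust([]).size == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(fdr_adjust(p), brute_force_bh(p))

    def test_monotone_order_preserving(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


class TestPermutationThreshold:
    def test_single_marker_threshold_near_alpha(self, rng):
        n = 200
        g = pd.DataFrame({"m1": rng.choice([0.0, 2.0], n)},
                         index=[f"L{i}" for i in range(n)])
        y = pd.Series(rng.normal(size=n), index=g.index)
        cfg = ScanConfig(alpha=0.05, n_perm=500, seed=1)
        thr, min_p = permutation_threshold(y, g, None, cfg)
        # with one marker, min-P is U(0,1): the 5% quantile ~ 0.05
        assert 0.02 < thr < 0.09
        assert len(min_p) == 500

    def test_fixed_seed_reproducible(self, rng, magic_genotypes):
        _, _, G = magic_genotypes
        y = pd.Series(rng.normal(size=len(G)), index=G.index)
        cfg = ScanConfig(alpha=0.05, n_perm=100, seed=3)
        t1, _ = permutation_threshold(y, G, None, cfg)
        t2, _ = permutation_threshold(y, G, None, cfg)
        assert t1 == t2


def _greedy_oracle_step(y, G, selected, alpha, fdr_q, thr):
    """Exhaustive single-addition search by explicit OLS refits."""
    n = len(y)
    best = None
    ps = {}
    for m in G.columns:
        if m in selected:
            continue
        X0 = np.column_stack([np.ones(n)] + [G[s].to_numpy() for s in selected])
        X1 = np.column_stack([X0, G[m].to_numpy()])
        if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
            continue
        rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
        rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
        df = n - X1.shape[1]
        f = (rss0 - rss1) / (rss1 / df)
        ps[m] = stats.f.sf(f, 1, df)
    gate = {m: p for m, p in ps.items() if p <= alpha and p <= thr}
    if gate:
        adj = fdr_adjust(list(ps.values()))
        adj_map = dict(zip(ps.keys(), adj))
        gate = {m: p for m, p in gate.items() if adj_map[m] <= fdr_q}
    if not gate:
        return None
    return min(gate, key=lambda m: gate[m])


class TestForwardScan:
    def test_constant_response_selects_nothing(self, magic_genotypes):
        gmap, _, G = magic_genotypes
        y = pd.Series(1.0, index=G.index)
        res = forward_multilocus_scan(y, G, ScanConfig(n_perm=20, seed=1), gmap)
        assert res.selected.empty and res.total_r2 == 0.0

    def test_two_planted_qtl_recovered_in_significance_order(self, magic_genotypes):
        gmap, _, G = magic_genotypes
        rng = np.random.default_rng(10)
        m1 = gmap.marker_ids[gmap.nearest_marker("2H", 40.0)]
        m2 = gmap.marker_ids[gmap.nearest_marker("5H", 60.0)]
        g1, g2 = G[m1], G[m2]
        y = (1.2 * (g1 - g1.mean()) / g1.std()
             + 0.8 * (g2 - g2.mean()) / g2.std()
             + rng.normal(0, 0.5, len(G)))
        res = forward_multilocus_scan(pd.Series(y, index=G.index), G,
                                      ScanConfig(n_perm=100, seed=2), gmap)
        sel = res.selected
        assert len(sel) >= 2
        assert sel.iloc[0]["chromosome"] == "2H"
        assert abs(sel.iloc[0]["position_cM"] - 40.0) <= 6.0
        chroms = set(sel["chromosome"][:2])
        assert chroms == {"2H", "5H"}
        # decreasing significance across iterations
        assert sel.iloc[0]["P"] <= sel.iloc[1]["P"] + 1e-12

    def test_matches_exhaustive_greedy_on_small_instances(self):
        rng = np.random.default_rng(11)
        cfg = ScanConfig(alpha=0.3, n_perm=60, fdr_q=0.9, seed=4)
        for rep in range(20):
            n, m = 40, rng.integers(4, 11)
            G = pd.DataFrame(rng.choice([0.0, 2.0], (n, m)),
                             columns=[f"m{j}" for j in range(m)],
                             index=[f"L{i}" for i in range(n)])
            y = pd.Series(rng.normal(size=n), index=G.index)
            if rep % 3 == 0:  # sometimes plant a real signal
                y = y + G.iloc[:, 0] * 0.8
            res = forward_multilocus_scan(y, G, cfg)
            yv = y.to_numpy()
            selected = []
            thr = res.perm_threshold
            while True:
                pick = _greedy_oracle_step(yv, G, selected, cfg.alpha,
                                           cfg.fdr_q, thr)
                if pick is None or len(selected) >= cfg.max_iterations:
                    break
                selected.append(pick)
            assert list(res.selected["marker_id"]) == selected

    def test_full_scan_deterministic_under_seed(self, magic_genotypes):
        gmap, _, G = magic_genotypes
        rng = np.random.default_rng(13)
        y = pd.Series(G.iloc[:, 10] + rng.normal(0, 1, len(G)), index=G.index)
        cfg = ScanConfig(n_perm=100, seed=21)
        a = forward_multilocus_scan(y, G, cfg, gmap)
        b = forward_multilocus_scan(y, G, cfg, gmap)
        pd.testing.assert_frame_equal(a.selected, b.selected)
        assert a.perm_threshold == b.perm_threshold


class TestCrossValidation:
    def test_no_holdout_single_round_equals_full_data_p(self, magic_genotypes):
        _, _, G = magic_genotypes
        rng = np.random.default_rng(14)
        m = G.columns[5]
        y = pd.Series(G[m] + rng.normal(0, 1.0, len(G)), index=G.index)
        cv = cross_validate_qtl(y, G, [m],
                                ScanConfig(cv_rounds=1, cv_holdout=0.0, seed=1))
        full = single_marker_test(y.to_numpy(),
                                  G[m].loc[y.index].to_numpy())
        assert cv["cv_mean_P"].iloc[0] == pytest.approx(full.P, rel=1e-9)

    def test_strong_marker_retained(self, magic_genotypes):
        _, _, G = magic_genotypes
        rng = np.random.default_rng(15)
        m = G.columns[40]
        g = G[m]
        y = pd.Series(2.0 * (g - g.mean()) / g.std() + rng.normal(0, 1, len(G)),
                      index=G.index)
        cv = cross_validate_qtl(y, G, [m], ScanConfig(cv_rounds=20, seed=2))
        assert bool(cv["cv_retained"].iloc[0])
        assert cv["cv_mean_P"].iloc[0] < 1e-6

    def test_empty_selection_rejected(self, magic_genotypes):
        _, _, G = magic_genotypes
        y = pd.Series(np.arange(float(len(G))), index=G.index)
        with pytest.raises(ValueError, match="empty"):
            cross_validate_qtl(y, G, [])


class TestVarianceExplained:
    def test_single_marker_explaining_everything(self, magic_genotypes):
        _, _, G = magic_genotypes
        m = G.columns[3]
        y = pd.Series(G[m].to_numpy() * 1.7 + 3, index=G.index)
        r2, total = variance_explained(y, [m], G)
        assert r2.iloc[0] == pytest.approx(1.0)
        assert total == pytest.approx(1.0)

    def test_orthogonal_markers_partition_variance(self):
        rng = np.random.default_rng(16)
        n = 1000
        g1 = np.tile([0.0, 2.0], n // 2)
        g2 = np.repeat([0.0, 2.0], n // 2)  # orthogonal to g1 by design
        noise = rng.normal(0, np.sqrt(6.0), n)
        y = g1 + g2 + noise  # each marker: var 1 of total ~8 -> ~12.5%... scale:
        # Var(g_i)=1, noise 6 => each R2 ~ 1/8; rescale to hit ~20% each
        y = np.sqrt(1.5) * (g1 - 1) + np.sqrt(1.5) * (g2 - 1) + rng.normal(0, np.sqrt(4.5), n)
        G = pd.DataFrame({"g1": g1, "g2": g2}, index=range(n))
        r2, total = variance_explained(pd.Series(y, index=G.index), ["g1", "g2"], G)
        assert r2["g1"] == pytest.approx(0.20, abs=0.04)
        assert r2["g2"] == pytest.approx(0.20, abs=0.04)
        assert total == pytest.approx(0.40, abs=0.06)

    def test_independent_marker_near_zero(self, magic_genotypes):
        _, _, G = magic_genotypes
        rng = np.random.default_rng(17)
        y = pd.Series(rng.normal(size=len(G)), index=G.index)
        r2, _ = variance_explained(y, [G.columns[0]], G)
        assert r2.iloc[0] < 0.03

    def test_invariant_to_marker_scaling(self, magic_genotypes):
        _, _, G = magic_genotypes
        rng = np.random.default_rng(18)
        m = G.columns[7]
        y = pd.Series(G[m] + rng.normal(0, 1, len(G)), index=G.index)
        r2a, _ = variance_explained(y, [m], G)
        G2 = G.copy()
        G2[m] = G2[m] * 57.0
        r2b, _ = variance_explained(y, [m], G2)
        assert r2a.iloc[0] == pytest.approx(r2b.iloc[0])


class TestMxT:
    def test_identical_responses_yield_no_interaction(self, magic_genotypes):
        gmap, _, G = magic_genotypes
        rng = np.random.default_rng(19)
        y = pd.Series(rng.normal(size=len(G)), index=G.index)
        res = mxt_scan(y, y.copy(), G, ScanConfig(n_perm=50, seed=5), gmap)
        assert res.selected.empty
        it1 = res.iterations[0]
        assert float(np.nanmax(it1["F"])) < 1e-6

    def test_td_only_effect_detected(self, magic_genotypes):
        gmap, _, G = magic_genotypes
        rng = np.random.default_rng(20)
        m = gmap.marker_ids[gmap.nearest_marker("4H", 60.0)]
        g = G[m]
        base = rng.normal(0, 1.0, len(G))
        y_ww = pd.Series(base + rng.normal(0, 0.3, len(G)), index=G.index)
        y_td = pd.Series(base + 1.0 * (g - g.mean()) / g.std()
                         + rng.normal(0, 0.3, len(G)), index=G.index)
        res = mxt_scan(y_ww, y_td, G, ScanConfig(n_perm=100, seed=6), gmap)
        assert not res.selected.empty
        top = res.selected.iloc[0]
        assert top["chromosome"] == "4H"
        assert abs(top["position_cM"] - 60.0) <= 9.0

    def test_empty_stratum_rejected(self, magic_genotypes):
        _, _, G = magic_genotypes
        y = pd.Series(np.arange(float(len(G))), index=G.index)
        with pytest.raises(ValueError, match="empty"):
            mxt_scan(y, pd.Series(dtype=float), G)
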