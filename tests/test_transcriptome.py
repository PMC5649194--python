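"""Normalization pipeline, moderated test, FDR, set logic, and enrichment."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wallomics import synthetic_data as sd
from wallomics import transcriptome as tx


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = tx.quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_single_column_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        assert tx.quantile_normalize(m)["a"].tolist() == [3.0, 1.0, 2.0]

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        pd.testing.assert_frame_equal(tx.quantile_normalize(m), m)

    def test_columns_share_sorted_values(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)))
        out = tx.quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)


class TestPreprocess:
    def test_single_array_collapses_to_median_centering(self):
        raw = pd.DataFrame({"a1_1": [4.0, 8.0, 16.0]}, index=["p1", "p2", "p3"])
        w = pd.DataFrame(1, index=raw.index, columns=raw.columns)
        p2g = {"p1": "g1", "p2": "g2", "p3": "g3"}
        out = tx.preprocess(raw, w, p2g, {"a1_1": "a1"})
        log2 = np.log2(raw["a1_1"])
        expected = log2 - log2.median()
        assert np.allclose(out["a1_1"].to_numpy(),
                           expected.to_numpy())

    def test_toy_with_zero_weight_spot_matches_step_by_step_oracle(self):
        """6 probes (3 genes x 2 spots), 3 arrays, one bad spot: the pipeline
        output equals an independent step-by-step computation."""
        probes = ["g1_s1", "g1_s2", "g2_s1", "g2_s2", "g3_s1", "g3_s2"]
        arrays = ["S_1", "S_2", "S_3"]
        rng = np.random.default_rng(7)
        raw = pd.DataFrame(np.exp2(rng.normal(8, 1, (6, 3))),
                           index=probes, columns=arrays)
        w = pd.DataFrame(1, index=probes, columns=arrays)
        w.loc["g2_s1", "S_2"] = 0
        p2g = {p: p.split("_")[0] for p in probes}
        out = tx.preprocess(raw, w, p2g, {a: "S" for a in arrays})

        # oracle: explicit loops, statistics.median, manual quantile step
        log2 = {(p, a): math.log2(raw.loc[p, a]) for p in probes for a in arrays}
        centred = {}
        for a in arrays:
            good = [log2[p, a] for p in probes if w.loc[p, a] == 1]
            med = statistics.median(good)
            for p in probes:
                centred[p, a] = log2[p, a] - med
        # impute the bad spot with its array's median of good centred values
        for a in arrays:
            med = statistics.median(centred[p, a] for p in probes
                                    if w.loc[p, a] == 1)
            for p in probes:
                if w.loc[p, a] == 0:
                    centred[p, a] = med
        # quantile normalize across the 3 arrays; tied values get the average
        # rank and interpolate linearly into the target quantile curve
        cols = {a: sorted(centred[p, a] for p in probes) for a in arrays}
        target = [statistics.mean(cols[a][i] for a in arrays) for i in range(6)]

        def interp(r):
            lo = int(math.floor(r))
            if lo == r:
                return target[lo]
            return target[lo] + (r - lo) * (target[lo + 1] - target[lo])

        qn = {}
        for a in arrays:
            vals = [centred[p, a] for p in probes]
            for p in probes:
                v = centred[p, a]
                positions = [i for i, u in enumerate(sorted(vals)) if u == v]
                qn[p, a] = interp(statistics.mean(positions))
        # per-gene median over good spots
        for gene in ("g1", "g2", "g3"):
            for a in arrays:
                vals = [qn[p, a] for p in probes
                        if p.startswith(gene) and w.loc[p, a] == 1]
                assert out.loc[gene, a] == pytest.approx(statistics.median(vals))

    def test_all_zero_weight_array_rejected(self):
        raw = pd.DataFrame({"a_1": [2.0], "b_1": [4.0]}, index=["p1"])
        w = pd.DataFrame({"a_1": [0], "b_1": [1]}, index=["p1"])
        with pytest.raises(ValueError):
            tx.preprocess(raw, w, {"p1": "g1"}, {})


class TestModeratedTTest:
    def test_d0_zero_equals_pooled_t(self, rng):
        A = rng.normal(0, 1, (200, 3))
        B = rng.normal(0, 1, (200, 3))
        t_mod, p = tx.moderated_ttest(A, B, d0=0.0, s0sq=1.0)
        ref = stats.ttest_ind(A, B, axis=1)
        assert np.allclose(t_mod, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)

    def test_identical_groups_null(self, rng):
        A = rng.normal(0, 1, (50, 3))
        t_mod, p = tx.moderated_ttest(A, A.copy(), d0=4.0, s0sq=1.0)
        assert np.allclose(t_mod, 0.0)
        assert np.allclose(p, 1.0)

    def test_infinite_prior_orders_by_mean_difference(self, rng):
        A = rng.normal(0, 1, (100, 3))
        B = rng.normal(0, 1, (100, 3))
        t_mod, _ = tx.moderated_ttest(A, B, d0=1e9, s0sq=0.5)
        diff = A.mean(axis=1) - B.mean(axis=1)
        assert np.array_equal(np.argsort(t_mod), np.argsort(diff))

    def test_prior_estimation_recovers_planted_hyperparameters(self, rng):
        # variances from s0^2 * d0 / chi2_d0, i.e. scaled inverse chi-square
        d0_true, s0_true, dg = 6.0, 0.04, 4
        n = 20000
        s2 = s0_true * d0_true / rng.chisquare(d0_true, n) * rng.chisquare(dg, n) / dg
        d0, s0sq = tx.estimate_variance_prior(s2, dg)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0sq == pytest.approx(s0_true, rel=0.05)

    def test_null_calibration_through_full_pipeline(self):
        """Fraction of null genes at p<0.01 is 1.0 +/- 0.5%."""
        fracs = []
        for seed in (9, 10):
            cfg = sd.ExprSimConfig(n_genes=2000, n_de_per_strain=0,
                                   common_core_size=0, seed=seed)
            raw, w, p2g, truth = sd.gen_expression(cfg)
            expr = tx.preprocess(raw, w, p2g, truth["array_to_group"])
            t = tx.differential_expression(expr, truth["array_to_group"],
                                           "L71", "BY4743")
            fracs.append(float((t["p"] < 0.01).mean()))
        assert np.mean(fracs) == pytest.approx(0.01, abs=0.005)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = tx.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert tx.bh_adjust([0.2]).tolist() == [0.2]

    def test_all_ones(self):
        assert tx.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_adjust([0.5, 1.5])

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        def brute(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            q = [0.0] * m
            for rank_pos, i in enumerate(order):
                q[i] = min(min(1.0, m * p[j] / (order.index(j) + 1))
                           for j in order[rank_pos:])
            return q

        for _ in range(40):
            p = rng.uniform(size=rng.integers(1, 25))
            assert np.allclose(tx.bh_adjust(p), brute(list(p)), atol=1e-12)

    def test_agrees_with_statsmodels_on_large_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(10):
            p = rng.uniform(size=1000)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(tx.bh_adjust(p), ref, atol=1e-12)


class TestDEFilterAndSets:
    def _table(self, fcs, ps):
        return pd.DataFrame({"log2_fc": fcs, "p": ps},
                            index=[f"g{i}" for i in range(len(fcs))])

    def test_empty_table(self):
        assert tx.de_filter(self._table([], [])) == set()

    def test_toy_two_of_five_pass(self):
        t = self._table([2.0, -1.5, 0.5, 1.0, -0.2],
                        [0.001, 0.005, 0.001, 0.2, 0.5])
        assert tx.de_filter(t) == {"g0", "g1"}

    def test_degenerate_fc_threshold(self):
        t = self._table([0.1, 0.0, 2.0], [0.001, 0.5, 0.005])
        assert tx.de_filter(t, fc_threshold=1.0) == {"g0", "g2"}

    def test_common_set_identical(self):
        s = {"a", "b"}
        out = tx.common_set([s, set(s), set(s)])
        assert out["intersection"] == s
        assert all(e == set() for e in out["exclusive"])

    def test_common_set_disjoint(self):
        out = tx.common_set([{"a"}, {"b"}])
        assert out["intersection"] == set()
        assert out["exclusive"] == [{"a"}, {"b"}]

    def test_common_set_needs_two(self):
        with pytest.raises(ValueError):
            tx.common_set([{"a"}])

    def test_planted_core_recovered(self, rng):
        core = {f"core{i}" for i in range(71)}
        sets = [core | {f"s{j}_{i}" for i in range(30)} for j in range(4)]
        out = tx.common_set(sets)
        assert out["intersection"] == core

    def test_power_and_false_positives_with_planted_effects(self):
        """Planted >=2-fold effects: >=90% recovered, <=1% false positives."""
        cfg = sd.ExprSimConfig(seed=4)
        raw, w, p2g, truth = sd.gen_expression(cfg)
        expr = tx.preprocess(raw, w, p2g, truth["array_to_group"])
        for strain, planted in truth["de_sets"].items():
            t = tx.differential_expression(expr, truth["array_to_group"],
                                           strain, "BY4743")
            found = tx.de_filter(t)
            assert len(found & planted) >= 0.9 * len(planted)
            assert len(found - planted) <= 0.01 * (cfg.n_genes - len(planted))


class TestEnrichment:
    def test_zero_overlap_certain(self):
        r = tx.hypergeometric_enrichment({"a", "b"}, {"c", "d"}, 100)
        assert r.k == 0 and r.p == 1.0

    def test_category_is_universe(self):
        cluster = {f"g{i}" for i in range(5)}
        cat = {f"g{i}" for i in range(50)}
        r = tx.hypergeometric_enrichment(cluster, cat, 50)
        assert r.p == pytest.approx(1.0)

    def test_brute_force_tail_sum(self):
        """k=5, n=23, f=11, N=6000 against the explicit hypergeometric sum."""
        cluster = {f"c{i}" for i in range(23)}
        category = {f"c{i}" for i in range(5)} | {f"f{i}" for i in range(6)}
        r = tx.hypergeometric_enrichment(cluster, category, 6000)
        assert (r.k, r.n, r.f, r.N) == (5, 23, 11, 6000)
        expected = sum(
            math.comb(11, i) * math.comb(6000 - 11, 23 - i) / math.comb(6000, 23)
            for i in range(5, 12))
        assert r.p == pytest.approx(expected, rel=1e-10)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            tx.hypergeometric_enrichment({"a"}, {"b"}, 0)
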