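"""Redistribution metrics, optimal transport, pseudo-bulk DE, overlaps."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from cortical_continuum.deprivation import (
    classify_regulation_groups,
    coarse_grained_vector_field,
    density_difference,
    focused_kmeans,
    js_divergence,
    optimal_transport_map,
    overlap_enrichment,
    pseudobulk_deg,
)
from cortical_continuum.errors import DataError


class TestDensity:
    def test_identical_samples_zero_difference(self):
        pts = np.random.default_rng(0).normal(size=(500, 2))
        cmp = density_difference(pts, pts.copy(), binwidth=1.0)
        assert np.all(cmp.difference == 0.0)

    def test_difference_sums_to_zero(self):
        rng = np.random.default_rng(1)
        cmp = density_difference(rng.normal(size=(300, 2)), rng.normal(1, 1, (400, 2)))
        assert abs(cmp.difference.sum()) < 1e-12

    def test_point_mass_moved_one_bin(self):
        a = np.tile([[0.5, 0.5]], (10, 1))
        b = np.tile([[1.5, 0.5]], (10, 1))
        cmp = density_difference(a, b, binwidth=1.0)
        assert (cmp.difference > 0).sum() == 1
        assert (cmp.difference < 0).sum() == 1
        np.testing.assert_allclose(np.abs(cmp.difference).sum(), 2.0)


class TestJSDivergence:
    def test_identical_zero_and_disjoint_maximum(self):
        h1 = np.array([[1.0, 0.0], [0.0, 0.0]])
        h2 = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert js_divergence(h1, h1) == 0.0
        assert abs(js_divergence(h1, h2) - np.sqrt(np.log(2))) < 1e-12

    def test_grid_mismatch_rejected(self):
        with pytest.raises(DataError):
            js_divergence(np.ones((2, 2)), np.ones((3, 2)))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_metric_properties_on_random_histograms(self, s1, s2, s3):
        """Symmetry and triangle inequality of the JS distance."""
        hs = []
        for s in (s1, s2, s3):
            h = np.random.default_rng(s).uniform(size=8)
            hs.append(h / h.sum())
        a, b, c = hs
        dab, dba = js_divergence(a, b), js_divergence(b, a)
        assert abs(dab - dba) < 1e-12
        assert js_divergence(a, c) <= dab + js_divergence(b, c) + 1e-12


class TestOptimalTransport:
    def test_identical_sets_zero_cost(self):
        pts = np.random.default_rng(0).normal(size=(20, 2))
        tr = optimal_transport_map(pts, pts.copy())
        assert tr.cost < 1e-12
        np.testing.assert_allclose(np.diag(tr.coupling), 1.0 / 20)

    def test_two_point_vertical_match(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0]])
        tgt = np.array([[0.0, 1.0], [1.0, 1.0]])
        tr = optimal_transport_map(src, tgt)
        np.testing.assert_allclose(tr.coupling, np.eye(2) / 2)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_exhaustive_assignment(self, n):
        rng = np.random.default_rng(n)
        src, tgt = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        tr = optimal_transport_map(src, tgt)
        C = ((src[:, None, :] - tgt[None, :, :]) ** 2).sum(-1)
        brute = min(sum(C[i, p[i]] for i in range(n)) for p in permutations(range(n))) / n
        assert abs(tr.cost - brute) < 1e-10

    def test_unequal_sizes_satisfy_marginals(self):
        rng = np.random.default_rng(7)
        tr = optimal_transport_map(rng.normal(size=(9, 2)), rng.normal(size=(5, 2)))
        np.testing.assert_allclose(tr.coupling.sum(axis=1), 1.0 / 9, atol=1e-8)
        np.testing.assert_allclose(tr.coupling.sum(axis=0), 1.0 / 5, atol=1e-8)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            optimal_transport_map(np.empty((0, 2)), np.ones((3, 2)))


class TestVectorField:
    def test_pure_translation(self):
        src = np.random.default_rng(0).normal(size=(300, 2))
        tgt = src + np.array([2.0, 0.0])
        tr = optimal_transport_map(src, tgt)
        vf = coarse_grained_vector_field(tr, src, tgt, grid_binwidth=1.0)
        np.testing.assert_allclose(vf["dx"], 2.0, atol=1e-6)
        np.testing.assert_allclose(vf["dy"], 0.0, atol=1e-6)

    def test_self_transport_is_still(self):
        src = np.random.default_rng(1).normal(size=(100, 2))
        tr = optimal_transport_map(src, src.copy())
        vf = coarse_grained_vector_field(tr, src, src, grid_binwidth=1.0)
        assert np.abs(vf[["dx", "dy"]].to_numpy()).max() < 1e-9

    def test_one_arrow_per_occupied_bin(self):
        src = np.random.default_rng(2).normal(size=(50, 2))
        tgt = src + 0.5
        tr = optimal_transport_map(src, tgt)
        vf = coarse_grained_vector_field(tr, src, tgt, grid_binwidth=1.0)
        occupied = {(int(np.floor(x)), int(np.floor(y))) for x, y in src}
        assert len(vf) == len(occupied)


class TestFocusedKmeans:
    def test_planted_types_recovered(self, section_data, section_identity_sets):
        _, _, truth, nm = section_data
        l23 = nm[(nm.obs["subclass"] == "L23").to_numpy()]
        genes = sum(section_identity_sets.values(), [])
        labels = focused_kmeans(l23, genes, k=3, seed=0)
        # planted zone = nearest A/B/C gradient center by true depth
        centers = np.asarray(truth.planted_effects["abc_gradient_centers"])
        zone = np.argmin(
            np.abs(l23.obs["depth_true"].to_numpy()[:, None] - centers[None, :]), axis=1
        )
        assert adjusted_rand_score(zone, labels.to_numpy()) > 0.3

    def test_k_one_single_label(self, section_data, section_identity_sets):
        _, _, _, nm = section_data
        l23 = nm[(nm.obs["subclass"] == "L23").to_numpy()][:100]
        genes = sum(section_identity_sets.values(), [])
        assert focused_kmeans(l23, genes, k=1, seed=0).nunique() == 1

    def test_deterministic_under_seed(self, section_data, section_identity_sets):
        _, _, _, nm = section_data
        l23 = nm[(nm.obs["subclass"] == "L23").to_numpy()][:500]
        genes = sum(section_identity_sets.values(), [])
        a = focused_kmeans(l23, genes, k=3, seed=7)
        b = focused_kmeans(l23, genes, k=3, seed=7)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())


def _null_pseudobulk(rng, n_genes=1000):
    """4 vs 4 samples, one cell per sample, no true effect."""
    lam = rng.uniform(20, 200, size=n_genes)
    X = rng.poisson(np.tile(lam, (8, 1)))
    samples = [f"s{i}" for i in range(8)]
    conds = ["NR"] * 4 + ["DR"] * 4
    return X, ["T"] * 8, samples, conds


class TestPseudobulkDEG:
    def test_planted_fold_change_and_hand_computed_t(self):
        rng = np.random.default_rng(0)
        n_genes = 60
        base = rng.uniform(20, 100, size=n_genes)
        X, types, samples, conds = [], [], [], []
        for cond in ("NR", "DR"):
            for r in range(4):
                lam = base * np.exp(rng.normal(0, 0.1))
                if cond == "DR":
                    lam = lam.copy()
                    lam[0] *= 4.0
                for _ in range(80):
                    X.append(rng.poisson(lam))
                    types.append("T")
                    samples.append(f"{cond}{r}")
                    conds.append(cond)
        X = np.asarray(X)
        deg = pseudobulk_deg(X, types, samples, conds, conditions=("NR", "DR"))
        row = deg[deg.gene == "g0"].iloc[0]
        assert row.is_deg and row.log2fc > 1.0

        # hand-computed two-sample t on the 8 pseudo-bulk CPM values
        cpm = {}
        for s in set(samples):
            rows = np.array(samples) == s
            v = X[rows].sum(axis=0)
            cpm[s] = v[0] * 1e6 / v.sum()
        nr = [cpm[f"NR{r}"] for r in range(4)]
        dr = [cpm[f"DR{r}"] for r in range(4)]
        t_hand = stats.ttest_ind(dr, nr).statistic
        assert abs(row.t_statistic - t_hand) < 1e-10

    def test_constant_gene_never_deg(self):
        X = np.tile([100, 50, 10], (8, 1)) * 10
        deg = pseudobulk_deg(
            X, ["T"] * 8, [f"s{i}" for i in range(8)], ["NR"] * 4 + ["DR"] * 4
        )
        assert not deg.is_deg.any()
        assert (deg.p_value == 1.0).all() or (deg.t_statistic == 0.0).all()

    def test_null_fdr_controlled(self):
        """Empirical FDP on fully-null simulations stays near nominal."""
        rng = np.random.default_rng(0)
        fdp = []
        for _ in range(20):
            X, types, samples, conds = _null_pseudobulk(rng)
            deg = pseudobulk_deg(X, types, samples, conds, conditions=("NR", "DR"))
            n_disc = int(deg.is_deg.sum())
            fdp.append(n_disc / max(n_disc, 1) if n_disc else 0.0)
        assert np.mean(fdp) <= 0.10

    def test_single_sample_condition_rejected(self):
        X = np.ones((3, 5), dtype=int)
        with pytest.raises(DataError):
            pseudobulk_deg(X, ["T"] * 3, ["s1", "s2", "s3"], ["NR", "NR", "DR"])


class TestOverlapEnrichment:
    def test_table_and_odds_ratio_vs_hypergeometric_oracle(self):
        """(a,b,c,d) = (10,10,10,70): OR 7.0 and exact two-sided p."""
        bg = [f"g{i}" for i in range(100)]
        a_list = bg[:20]  # a+b = 20
        b_list = bg[10:30]  # c = 10, overlap a = 10
        res = overlap_enrichment(a_list, b_list, bg)
        assert res.table == (10, 10, 10, 70)
        assert res.odds_ratio == 7.0
        # oracle: sum hypergeometric pmf over tables as or more extreme
        pmf = [stats.hypergeom.pmf(k, 100, 20, 20) for k in range(21)]
        p_oracle = sum(p for p in pmf if p <= pmf[10] * (1 + 1e-7))
        assert abs(res.p_value - p_oracle) < 1e-10

    def test_perfect_association_flagged(self):
        bg = [f"g{i}" for i in range(40)]
        half = bg[:20]
        res = overlap_enrichment(half, half, bg)
        assert res.haldane_corrected and np.isfinite(res.odds_ratio)
        assert res.odds_ratio > 100

    def test_null_pvalues_uniform(self):
        """Independent random lists give uniform p-values (KS check)."""
        rng = np.random.default_rng(0)
        bg = [f"g{i}" for i in range(1000)]
        ps = [
            overlap_enrichment(
                rng.choice(bg, 200, replace=False), rng.choice(bg, 300, replace=False), bg
            ).p_value
            for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_background_rejected(self):
        with pytest.raises(DataError):
            overlap_enrichment([], [], [])


class TestRegulationGroups:
    def _deg_table(self, patterns):
        rows = []
        for gene, pat in patterns.items():
            for t, ch in zip("ABC", pat):
                rows.append(
                    dict(
                        gene=gene,
                        type=t,
                        log2fc={"+": 2.0, "-": -2.0, "0": 0.1}[ch],
                        t_statistic=0.0,
                        p_value=0.5,
                        fdr=0.9 if ch == "0" else 0.001,
                        is_deg=ch != "0",
                    )
                )
        return pd.DataFrame(rows)

    def test_rule_table_oracle_over_planted_patterns(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("+-0"))
        patterns = {
            f"gene{i:02d}": "".join(rng.choice(chars, 3)) for i in range(30)
        }
        deg = self._deg_table(patterns)
        identity = {"identity": list(patterns)}
        groups, _ = classify_regulation_groups(deg, identity)
        oracle = {
            "000": "vision-independent",
            "+++": "group1_up_all",
            "---": "group2_down_all",
            "0++": "group3_up_BC_only",
            "0--": "group4_down_BC_only",
        }
        for gene, pat in patterns.items():
            if pat in oracle:
                assert groups[gene] == oracle[pat]
            elif (pat.count("+") + pat.count("-")) == 1:
                assert groups[gene] == "group5_single_type"
            else:
                assert groups[gene] == "group6_mixed"

    def test_upregulated_in_b_and_c_only(self):
        deg = self._deg_table({"x": "0++"})
        groups, _ = classify_regulation_groups(deg, {"identity": ["x"]})
        assert groups["x"] == "group3_up_BC_only"

    def test_untouched_identity_gene_is_vision_independent(self):
        deg = self._deg_table({"x": "000"})
        groups, venn = classify_regulation_groups(deg, {"identity": ["x"], "ieg": []})
        assert groups["x"] == "vision-independent"
        assert venn["vision_dependent"] == 0

    def test_venn_counts(self):
        deg = self._deg_table({"x": "+++", "y": "0+0", "z": "000"})
        groups, venn = classify_regulation_groups(
            deg, {"identity": ["x", "z"], "ieg": ["x", "y"]}
        )
        assert venn["vision_dependent"] == 2
        assert venn["vision_dependent&identity"] == 1
        assert venn["vision_dependent&identity&ieg"] == 1

    def test_missing_type_rejected(self):
        deg = self._deg_table({"x": "++0"})
        deg = deg[deg["type"] != "C"]
        with pytest.raises(DataError):
            classify_regulation_groups(deg, {"identity": ["x"]})
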