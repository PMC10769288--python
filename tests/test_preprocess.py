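"""QC, normalization, HVG and marker-derivation behaviour."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from cortical_continuum.errors import ConfigError, DataError, NormalizationError, SchemaError
from cortical_continuum.preprocess import (
    derive_identity_genes,
    normalize_merfish,
    normalize_snrnaseq,
    qc_filter_cells,
    select_hvgs,
)


def _adata(X, volume=None, blanks=None, sample=None):
    n = X.shape[0]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    if volume is not None:
        obs["volume"] = volume
    if blanks is not None:
        obs["blanks"] = blanks
    obs["sample"] = sample if sample is not None else "s0"
    return ad.AnnData(
        X=np.asarray(X, dtype=np.int64),
        obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]),
    )


class TestQCFilter:
    def test_volume_bounds_enumerated(self):
        """Volumes (30, 50, 100, 2000, 2500) with valid counts -> 3 kept."""
        X = np.full((5, 4), 10)
        m = _adata(X, volume=[30, 50, 100, 2000, 2500], blanks=[0] * 5)
        out = qc_filter_cells(m, (50, 2000), 10, 0.05)
        assert out.n_obs == 3
        assert list(out.obs["volume"]) == [50, 100, 2000]

    def test_transcript_threshold_is_strict(self):
        X = np.array([[10, 0], [11, 0], [5, 6]])
        m = _adata(X, volume=[100] * 3, blanks=[0] * 3)
        assert qc_filter_cells(m, (50, 2000), 10, 0.05).n_obs == 2

    def test_blank_rate_filter(self):
        X = np.full((2, 2), 50)
        m = _adata(X, volume=[100, 100], blanks=[0, 20])  # 20/120 = 17%
        out = qc_filter_cells(m, (50, 2000), 10, 0.05)
        assert list(out.obs_names) == ["c0"]

    def test_missing_meta_is_schema_error(self):
        m = _adata(np.ones((3, 2)), volume=[100] * 3)  # no blanks column
        with pytest.raises(SchemaError):
            qc_filter_cells(m)


class TestMerfishNormalization:
    def test_sample_means_hit_target_exactly(self, section_data):
        counts, _, _, nm = section_data
        excluded = nm.uns["excluded_genes"]
        keep = ~nm.var_names.isin(excluded)
        linear = 10.0 ** np.asarray(nm.layers["lognorm"]) - 1.0
        for s in nm.obs["sample"].unique():
            rows = (nm.obs["sample"] == s).to_numpy()
            np.testing.assert_allclose(linear[rows][:, keep].sum(axis=1).mean(), 250.0)

    def test_volume_division_is_linear(self):
        X = np.tile([4, 8, 2], (2, 1))
        m = _adata(X, volume=[100.0, 200.0], blanks=[0, 0])
        nm = normalize_merfish(m, target_mean=10.0)
        lin = 10.0 ** np.asarray(nm.layers["lognorm"]) - 1.0
        np.testing.assert_allclose(lin[0], 2.0 * lin[1])

    def test_scale_factor_arithmetic(self):
        """Totals (100, 300) over non-excluded genes -> factor 1.25."""
        X = np.array([[100, 7], [300, 9]])
        m = _adata(X, volume=[1.0, 1.0], blanks=[0, 0])
        nm = normalize_merfish(m, target_mean=250.0, exclude=["g1"])
        lin = 10.0 ** np.asarray(nm.layers["lognorm"]) - 1.0
        np.testing.assert_allclose(lin[:, 0], [125.0, 375.0])
        np.testing.assert_allclose(lin[:, 1], [7 * 1.25, 9 * 1.25])

    def test_zero_total_sample_named_in_error(self):
        X = np.array([[0, 5], [3, 2]])
        m = _adata(X, volume=[1.0, 1.0], blanks=[0, 0], sample=["bad", "ok"])
        with pytest.raises(NormalizationError, match="bad"):
            normalize_merfish(m, exclude=["g1"])

    def test_zscore_layer_is_standardized(self, section_data):
        _, _, _, nm = section_data
        z = np.asarray(nm.X)
        sd = z.std(axis=0)
        varying = sd > 0
        assert np.abs(z.mean(axis=0)).max() < 1e-8
        assert np.abs(sd[varying] - 1.0).max() < 1e-6

    def test_deterministic(self):
        X = np.random.default_rng(0).poisson(5, size=(20, 6))
        m = _adata(X, volume=np.linspace(50, 150, 20), blanks=[0] * 20)
        a = normalize_merfish(m)
        b = normalize_merfish(m)
        np.testing.assert_array_equal(np.asarray(a.X), np.asarray(b.X))


class TestSnrnaseqNormalization:
    def test_totals_rescaled_to_10k(self):
        X = np.random.default_rng(1).poisson(4, size=(30, 8)) + 1
        nm = normalize_snrnaseq(_adata(X))
        lin = 10.0 ** np.asarray(nm.layers["lognorm"]) - 1.0
        np.testing.assert_allclose(lin.sum(axis=1), 10_000.0)

    def test_zero_gene_log_layer_is_zero(self):
        X = np.array([[5, 0], [3, 0]])
        nm = normalize_snrnaseq(_adata(X))
        assert np.all(np.asarray(nm.layers["lognorm"])[:, 1] == 0.0)

    def test_two_gene_arithmetic(self):
        X = np.array([[1, 3], [1, 3]])
        nm = normalize_snrnaseq(_adata(X))
        lin = 10.0 ** np.asarray(nm.layers["lognorm"]) - 1.0
        np.testing.assert_allclose(lin[0], [2500.0, 7500.0])
        np.testing.assert_allclose(
            np.asarray(nm.layers["lognorm"])[0], [np.log10(2501), np.log10(7501)]
        )

    def test_all_zero_cell_dropped_with_warning(self):
        X = np.array([[0, 0], [1, 2]])
        with pytest.warns(UserWarning, match="all-zero"):
            nm = normalize_snrnaseq(_adata(X))
        assert nm.n_obs == 1


class TestHVGSelection:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        g = 60
        lam = rng.uniform(1, 50, size=g)
        X = rng.poisson(np.tile(lam, (400, 1))).astype(float)
        for j in (5, 25, 45):  # negative binomial, dispersion 0.5
            r = 2.0
            X[:, j] = rng.negative_binomial(r, r / (r + lam[j]), size=400)
        return _adata(X.astype(int))

    def test_planted_overdispersed_genes_selected(self):
        hvgs = select_hvgs(self._planted(), min_cells=10, n_bins=10, top_fraction=0.30)
        assert {"g5", "g25", "g45"} <= set(hvgs)

    def test_rare_genes_excluded_before_binning(self):
        X = np.random.default_rng(2).poisson(10, size=(50, 20))
        X[:, 3] = 0
        X[:5, 3] = 1  # expressed in 5 cells only
        hvgs = select_hvgs(_adata(X), min_cells=10, n_bins=4, top_fraction=0.5)
        assert "g3" not in hvgs

    def test_invariant_to_gene_permutation(self):
        m = self._planted(3)
        perm = np.random.default_rng(0).permutation(m.n_vars)
        m2 = m[:, perm].copy()
        a = set(select_hvgs(m, 10, 10, 0.3))
        b = set(select_hvgs(m2, 10, 10, 0.3))
        assert a == b

    def test_too_many_bins_rejected(self):
        with pytest.raises(ConfigError):
            select_hvgs(_adata(np.ones((10, 4), dtype=int)), n_bins=10)


class TestIdentityGenes:
    def _two_type_data(self, fc=4.0, frac=0.8, n_per=200, seed=0):
        rng = np.random.default_rng(seed)
        lam = np.full(20, 5.0)
        Xa = rng.poisson(np.tile(lam, (n_per, 1)))
        lam_b = lam.copy()
        lam_b[0] *= fc
        Xb = rng.poisson(np.tile(lam_b, (n_per, 1)))
        # thin gene 0 in type b to the requested expressing fraction
        keep = rng.uniform(size=n_per) < frac
        Xb[~keep, 0] = 0
        m = _adata(np.vstack([Xa, Xb]))
        labels = np.repeat(["t1", "t2"], n_per)
        return normalize_snrnaseq(m), labels

    def test_planted_marker_detected(self):
        nm, labels = self._two_type_data()
        mk = derive_identity_genes(nm, labels)
        row = mk[(mk.gene == "g0") & (mk.group == "t2")].iloc[0]
        assert row.is_marker
        assert row.fold_change > 2.0 and row.frac_in_group > 0.3

    def test_agrees_with_permutation_oracle(self):
        """The Wilcoxon p for the planted marker is consistent with a
        seeded permutation null on the rank-sum statistic."""
        rng = np.random.default_rng(0)
        a = rng.poisson(5.0, size=40).astype(float)
        b = rng.poisson(7.0, size=40).astype(float)
        X = np.concatenate([a, b])[:, None]
        m = _adata(np.column_stack([X, np.ones(80)]).astype(int))
        nm = normalize_snrnaseq(m)
        labels = np.repeat(["t1", "t2"], 40)
        mk = derive_identity_genes(nm, labels)
        p_impl = mk[(mk.gene == "g0") & (mk.group == "t2")].p_value.iloc[0]

        vals = 10.0 ** np.asarray(nm.layers["lognorm"])[:, 0] - 1.0
        from scipy.stats import rankdata

        ranks = rankdata(vals)
        obs = ranks[40:].sum()
        null = np.empty(20_000)
        for i in range(20_000):
            null[i] = ranks[rng.permutation(80)[40:]].sum()
        p_perm = 2 * min(
            (1 + (null >= obs).sum()) / 20_001, (1 + (null <= obs).sum()) / 20_001
        )
        # both should call the same significance regime
        assert (p_impl < 0.01) == (p_perm < 0.01)
        assert abs(np.log10(p_impl + 1e-12) - np.log10(p_perm + 1e-12)) < 1.0

    def test_uniform_gene_never_marker(self):
        nm, labels = self._two_type_data()
        mk = derive_identity_genes(nm, labels)
        assert not mk[mk.gene == "g5"].is_marker.any()

    def test_tiny_type_excluded_with_warning(self):
        nm, labels = self._two_type_data(n_per=50)
        labels = labels.astype(object)
        labels[:2] = "tiny"
        labels[2:50] = "t1"
        with pytest.warns(UserWarning, match="tiny"):
            derive_identity_genes(nm, labels)

    def test_single_type_rejected(self):
        nm, _ = self._two_type_data(n_per=20)
        with pytest.raises(DataError):
            derive_identity_genes(nm, np.repeat("only", nm.n_obs))
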