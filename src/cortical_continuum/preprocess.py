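"""QC, normalization, HVG selection and marker derivation.

Count matrices are :class:`anndata.AnnData` with raw integer counts in
``X`` and per-cell metadata in ``obs``. Normalized matrices are AnnData
with ``X`` holding per-gene z-scores, a ``"lognorm"`` layer holding the
non-negative size- and log-normalized values ``x_gc`` (log10 of x+1), and
``uns["provenance"]`` recording each transform applied in order.

MERFISH-style normalization follows the imaging convention: counts are
divided by segmented cell volume, each sample is rescaled so the mean
per-cell total over non-excluded genes hits a common target (250 by
default, computed excluding activity-induced IEGs so a condition-specific
IEG surge cannot skew size factors), then log10(x+1) and per-gene
z-scoring across all retained cells. snRNA-seq normalization rescales each
cell to 10,000 total counts before the same log/z steps.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, NormalizationError, SchemaError

__all__ = [
    "qc_filter_cells",
    "normalize_merfish",
    "normalize_snrnaseq",
    "select_hvgs",
    "derive_identity_genes",
    "cp10k",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def qc_filter_cells(
    m: ad.AnnData,
    volume_range: tuple[float, float] = (50.0, 2000.0),
    min_transcripts: int = 10,
    max_blank_rate: float = 0.05,
) -> ad.AnnData:
    """Remove low-quality cells from an imaging-based count matrix.

    Keeps cells whose segmented volume lies in the closed ``volume_range``,
    whose total transcript count is strictly greater than
    ``min_transcripts``, and whose blank-barcode false-positive rate
    ``blanks / (blanks + total)`` is strictly below ``max_blank_rate``.
    Cell order is preserved. A second, stricter pass (e.g. ``>50``
    transcripts before type-level analysis) is simply another call.
    """
    for col in ("volume", "blanks"):
        if col not in m.obs.columns:
            raise SchemaError(f"cell metadata is missing required column {col!r}")
    total = _dense(m.X).sum(axis=1)
    volume = m.obs["volume"].to_numpy(dtype=float)
    blanks = m.obs["blanks"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        blank_rate = np.where(blanks + total > 0, blanks / (blanks + total), 1.0)
    keep = (
        (volume >= volume_range[0])
        & (volume <= volume_range[1])
        & (total > min_transcripts)
        & (blank_rate < max_blank_rate)
    )
    return m[keep].copy()


def _log_z(values: np.ndarray, provenance: list[dict]) -> tuple[np.ndarray, np.ndarray]:
    log = np.log10(values + 1.0)
    provenance.append({"step": "log10(x+1)"})
    mu = log.mean(axis=0)
    sd = log.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (log - mu) / safe
    z[:, sd == 0] = 0.0
    provenance.append({"step": "zscore_per_gene", "pooled_across_samples": True})
    return log, z


def _normalized_anndata(
    m: ad.AnnData, lognorm: np.ndarray, z: np.ndarray, provenance: list[dict], excluded: list[str]
) -> ad.AnnData:
    nm = ad.AnnData(X=z, obs=m.obs.copy(), var=m.var.copy())
    nm.layers["lognorm"] = lognorm
    # JSON strings keep the record ordered and h5ad-serializable
    nm.uns["provenance"] = [json.dumps(step) for step in provenance]
    nm.uns["excluded_genes"] = list(excluded)
    return nm


def normalize_merfish(
    m: ad.AnnData,
    target_mean: float = 250.0,
    exclude: Iterable[str] = (),
) -> ad.AnnData:
    """Volume-, sample- and log/z-normalize an imaging count matrix.

    Per cell, counts are divided by volume; per sample, values are rescaled
    so the mean per-cell total over genes *not* in ``exclude`` equals
    ``target_mean`` exactly; then log10(x+1) and per-gene z-scoring across
    all cells pooled. ``exclude`` (typically the IEG panel) only affects the
    size factors — excluded genes are still carried and normalized.
    """
    if "volume" not in m.obs.columns:
        raise SchemaError("cell metadata is missing required column 'volume'")
    if "sample" not in m.obs.columns:
        raise SchemaError("cell metadata is missing required column 'sample'")
    volume = m.obs["volume"].to_numpy(dtype=float)
    if np.any(volume <= 0):
        raise DataError("all cell volumes must be positive")
    excluded = [g for g in exclude]
    missing = set(excluded) - set(m.var_names)
    if missing:
        raise SchemaError(f"excluded genes not in matrix: {sorted(missing)}")

    provenance: list[dict] = [{"step": "divide_by_volume"}]
    values = _dense(m.X).astype(float) / volume[:, None]

    keep_mask = ~m.var_names.isin(excluded)
    samples = m.obs["sample"].to_numpy()
    for s in pd.unique(samples):
        rows = samples == s
        mean_total = values[np.ix_(rows, keep_mask)].sum(axis=1).mean()
        if mean_total <= 0:
            raise NormalizationError(f"sample {s!r} has zero total over non-excluded genes")
        values[rows] *= target_mean / mean_total
    provenance.append(
        {
            "step": "per_sample_rescale",
            "target_mean": target_mean,
            "excluded_genes": excluded,
        }
    )
    lognorm, z = _log_z(values, provenance)
    return _normalized_anndata(m, lognorm, z, provenance, excluded)


def normalize_snrnaseq(m: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Size-normalize each cell to ``target_sum`` then log10(x+1) and z-score.

    All-zero cells cannot be size-normalized; they are dropped with a
    warning.
    """
    counts = _dense(m.X).astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        n_zero = int((totals == 0).sum())
        warnings.warn(f"dropping {n_zero} all-zero cell(s) before size normalization")
        m = m[totals > 0].copy()
        counts = counts[totals > 0]
        totals = totals[totals > 0]
    provenance: list[dict] = [{"step": "rescale_per_cell", "target_sum": target_sum}]
    values = counts * (target_sum / totals[:, None])
    lognorm, z = _log_z(values, provenance)
    return _normalized_anndata(m, lognorm, z, provenance, [])


def cp10k(counts: np.ndarray) -> np.ndarray:
    """Counts-per-10k-transcripts normalization of a dense count matrix."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(totals > 0, counts * (1e4 / totals), 0.0)
    return out


def select_hvgs(
    m: ad.AnnData,
    min_cells: int = 10,
    n_bins: int = 10,
    top_fraction: float = 0.30,
) -> list[str]:
    """Highly variable genes by binned variance-to-mean ratio.

    Genes with non-zero counts in fewer than ``min_cells`` cells are dropped;
    the variance/mean ratio is computed on CP10k values (constant under pure
    Poisson sampling, so excess flags real overdispersion); genes are ranked
    into ``n_bins`` equal-size bins by mean expression and the
    ``top_fraction`` highest-ratio genes per bin are selected.
    """
    counts = _dense(m.X).astype(float)
    if n_bins > counts.shape[1]:
        raise ConfigError("n_bins exceeds the number of genes")
    detected = (counts > 0).sum(axis=0)
    keep = detected >= min_cells
    if keep.sum() == 0:
        raise DataError("no gene passes the min_cells filter")
    vals = cp10k(counts)[:, keep]
    names = np.asarray(m.var_names)[keep]
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mean > 0, var / mean, 0.0)

    # equal-count bins by mean expression; stable sort keeps ties in the
    # lower bin
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, len(order)))
    selected: list[str] = []
    for b in bins:
        n_top = max(1, int(np.ceil(top_fraction * len(b))))
        top = b[np.argsort(ratio[b], kind="stable")[::-1][:n_top]]
        selected.extend(names[top])
    order_map = {g: i for i, g in enumerate(m.var_names)}
    return sorted(selected, key=order_map.__getitem__)


def derive_identity_genes(
    nm: ad.AnnData,
    labels: pd.Series | Sequence[str],
    min_frac: float = 0.30,
    min_fc: float = 2.0,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker derivation.

    For each type and gene: a Wilcoxon rank-sum test of the type's cells
    against all others on the size-normalized expression, BH-FDR within the
    type, fold change on linear-scale means with a pseudo-count of 1, and
    the fraction of expressing cells in the up-regulated type. A gene is a
    marker of a type when ``fdr < max_fdr``, ``fold_change > min_fc`` and
    ``frac_in_group > min_frac``. Types with fewer than 3 cells are excluded
    with a warning.
    """
    labels = pd.Series(np.asarray(labels), index=nm.obs_names)
    groups = [g for g in pd.unique(labels)]
    sizes = labels.value_counts()
    usable = [g for g in groups if sizes[g] >= 3]
    for g in set(groups) - set(usable):
        warnings.warn(f"type {g!r} has fewer than 3 cells and is excluded")
    if len(usable) < 2:
        raise DataError("need at least 2 types with >=3 cells each")

    lognorm = np.asarray(nm.layers["lognorm"])
    linear = 10.0**lognorm - 1.0  # recover size-normalized expression
    rows = []
    for g in usable:
        in_g = (labels == g).to_numpy()
        a, b = linear[in_g], linear[~in_g]
        # exact Wilcoxon for small groups, tie-corrected normal otherwise
        method = "exact" if min(len(a), len(b)) < 25 else "asymptotic"
        pvals = np.empty(linear.shape[1])
        for j in range(linear.shape[1]):
            try:
                pvals[j] = stats.mannwhitneyu(
                    a[:, j], b[:, j], alternative="two-sided", method=method
                ).pvalue
            except ValueError:  # all values identical
                pvals[j] = 1.0
        fdr = multipletests(pvals, method="fdr_bh")[1]
        fc = (a.mean(axis=0) + 1.0) / (b.mean(axis=0) + 1.0)
        frac = (a > 0).mean(axis=0)
        for j, gene in enumerate(nm.var_names):
            rows.append(
                dict(
                    gene=gene,
                    group=g,
                    p_value=pvals[j],
                    fdr=fdr[j],
                    fold_change=fc[j],
                    frac_in_group=frac[j],
                    is_marker=bool(
                        fdr[j] < max_fdr and fc[j] > min_fc and frac[j] > min_frac
                    ),
                )
            )
    return pd.DataFrame(rows)
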