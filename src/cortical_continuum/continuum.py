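"""Continuum structure of a cell population: PCA, shuffling tests, ABC
scores and pseudotime.

The central question this module answers is whether a set of cells is a
genuine expression continuum or a handful of discrete types blurred by
measurement noise. The discriminating operation is *within-type
shuffling*: permuting each gene independently across cells inside each
labelled group preserves every per-(gene, type) expression distribution
but destroys within-type gene-gene correlations. Shuffling a true
continuum collapses the within-type gradients and splits the data into
clean clusters (silhouette rises and the selected k matches the number of
groups); shuffling already-discrete types changes nothing.

ABC scores turn mean z-scores over three identity-gene sets into per-cell
probabilities (pa, pb, pc) summing to one, via a percentile rescaling
(40th percentile -> 0, 95th -> 1, clipped); cells whose top probability
exceeds 0.6 are flagged archetypal. Values below the 40th percentile clip
to 0 rather than reflecting about it, so anti-correlated cells cannot
score high.

Pseudotime uses diffusion pseudotime on a kNN graph in identity-gene PC
space, rooted at the cell with the smallest PC1, min-max rescaled to
[0, 1]. Genes are ordered by *gene pseudotime*: the expression-weighted
average of cell pseudotime, computed on non-negative size- and
log-normalized values and conventionally frozen on a reference condition
for cross-condition comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .archetypes import pca_embed
from .errors import ConfigError, DataError

__all__ = [
    "pca_identity",
    "shuffle_within_types",
    "continuum_vs_discrete_test",
    "abc_scores",
    "PseudotimeResult",
    "cell_pseudotime",
    "gene_pseudotime",
]


@dataclass
class PCAResult:
    embedding: np.ndarray  # cells x k scores
    loadings: np.ndarray  # genes x k orthonormal eigenvectors
    eigenvalues: np.ndarray  # variance spectrum for gap inspection
    genes: list[str]


def pca_identity(nm, gene_set: list[str] | None = None, n_components: int = 2) -> PCAResult:
    """PCA of the z-scored matrix restricted to an identity-gene set.

    Returns scores, orthonormal loadings and the full eigenvalue spectrum
    (useful for spotting the spectral gap that separates structured
    components from noise).
    """
    if gene_set is not None:
        genes = [g for g in gene_set if g in nm.var_names]
        if not genes:
            raise DataError("no gene of the set is present in the matrix")
        values = np.asarray(nm[:, genes].X, dtype=float)
    else:
        genes = list(nm.var_names)
        values = np.asarray(nm.X, dtype=float)
    n, g = values.shape
    if n < n_components:
        raise ConfigError("fewer cells than requested components")
    Xc = values - values.mean(axis=0)
    cov = (Xc.T @ Xc) / max(n - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(n_components, g)
    return PCAResult(
        embedding=Xc @ evecs[:, :k],
        loadings=evecs[:, :k],
        eigenvalues=evals,
        genes=genes,
    )


def shuffle_within_types(nm, labels, seed: int = 0):
    """Permute each gene independently across cells within each type.

    Accepts an AnnData (all layers are permuted coherently) or a plain
    array. Per-(gene, type) value multisets are exactly preserved.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    if hasattr(nm, "X"):
        if len(labels) != nm.n_obs:
            raise DataError("labels must cover every cell")
        out = nm.copy()
        X = np.asarray(out.X, dtype=float)
        layers = {name: np.asarray(out.layers[name]) for name in out.layers.keys()}
        for group in pd.unique(labels):
            idx = np.flatnonzero(labels == group)
            for j in range(X.shape[1]):
                perm = rng.permutation(idx)
                X[idx, j] = X[perm, j]
                for L in layers.values():
                    L[idx, j] = L[perm, j]
        out.X = X
        for name, L in layers.items():
            out.layers[name] = L
        return out
    values = np.array(nm, dtype=float)
    if len(labels) != values.shape[0]:
        raise DataError("labels must cover every cell")
    for group in pd.unique(labels):
        idx = np.flatnonzero(labels == group)
        for j in range(values.shape[1]):
            values[rng.permutation(idx), j] = values[idx, j]
    return values


def continuum_vs_discrete_test(
    nm,
    labels,
    k_range=range(2, 7),
    seed: int = 0,
    margin: float = 0.05,
    n_pcs: int = 10,
) -> dict:
    """Continuum-vs-discrete verdict from within-type shuffling.

    K-means over ``k_range`` in PC space selects k by maximal mean
    silhouette, on the original matrix and on its within-type-shuffled
    counterpart (PCA refit on the shuffled data). Verdict ``"continuum"``
    when shuffling raises the silhouette at the shuffled-selected k by more
    than ``margin`` and that k equals the number of label groups;
    ``"discrete"`` when the silhouette change stays within ``margin``;
    ``"ambiguous"`` otherwise.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise DataError("labels must define at least 2 groups")
    values = np.asarray(nm.X, dtype=float) if hasattr(nm, "X") else np.asarray(nm, dtype=float)
    k_range = list(k_range)
    if min(k_range) < 2 or max(k_range) > values.shape[0] - 1:
        raise ConfigError("k_range must lie within [2, n_cells - 1]")

    shuffled = shuffle_within_types(values, labels, seed=seed)

    def profile(mat: np.ndarray) -> dict:
        emb = pca_embed(mat, min(n_pcs, mat.shape[1]))
        sil = {}
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
            sil[k] = float(silhouette_score(emb, km.labels_))
        k_sel = max(sil, key=sil.get)
        return {"silhouettes": sil, "k_selected": k_sel}

    orig = profile(values)
    shuf = profile(shuffled)
    k_sel = shuf["k_selected"]
    delta = shuf["silhouettes"][k_sel] - orig["silhouettes"][k_sel]
    if delta > margin and k_sel == len(groups):
        verdict = "continuum"
    elif abs(delta) <= margin:
        verdict = "discrete"
    else:
        verdict = "ambiguous"
    return {
        "original": orig,
        "shuffled": shuf,
        "silhouette_increase": float(delta),
        "margin": margin,
        "n_groups": int(len(groups)),
        "verdict": verdict,
    }


def abc_scores(
    nm,
    gene_sets: dict[str, list[str]],
    lo_pct: float = 40.0,
    hi_pct: float = 95.0,
    archetypal_threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-cell type probabilities from three identity-gene sets.

    For each set the mean per-cell z-score is percentile-rescaled to [0, 1]
    (``lo_pct`` -> 0, ``hi_pct`` -> 1, clipped) and the three rescaled
    scores are normalized to probabilities summing to 1. Cells with all
    three rescaled scores equal to zero get the uniform (1/3, 1/3, 1/3).
    """
    names = list(gene_sets)
    if len(names) != 3:
        raise ConfigError("expected exactly three gene sets")
    z = {}
    for name in names:
        genes = [g for g in gene_sets[name] if g in nm.var_names]
        if not genes:
            raise DataError(f"gene set {name!r} has no gene in the matrix")
        z[name] = np.asarray(nm[:, genes].X, dtype=float).mean(axis=1)

    s = {}
    for name in names:
        zmin = np.percentile(z[name], lo_pct)
        zmax = np.percentile(z[name], hi_pct)
        if zmax == zmin:
            raise DataError(f"degenerate percentile scale for set {name!r}")
        s[name] = np.clip((z[name] - zmin) / (zmax - zmin), 0.0, 1.0)

    S = np.column_stack([s[name] for name in names])
    total = S.sum(axis=1)
    P = np.where(total[:, None] > 0, S / np.where(total == 0, 1, total)[:, None], 1.0 / 3.0)
    assigned = np.asarray(names)[np.argmax(P, axis=1)]
    table = pd.DataFrame(index=nm.obs_names)
    for i, name in enumerate(names):
        table[f"z_{name}"] = z[name]
        table[f"s_{name}"] = S[:, i]
        table[f"p_{name}"] = P[:, i]
    table["assigned_type"] = assigned
    table["archetypal"] = P.max(axis=1) > archetypal_threshold
    return table


@dataclass
class PseudotimeResult:
    """Cell pseudotime (and optionally gene pseudotime) for a continuum."""

    tc: pd.Series  # per-cell pseudotime in [0, 1]
    root_cell_id: str
    reachable: pd.Series  # False for cells outside the root's graph component
    Tg: pd.Series | None = None
    meta: dict = field(default_factory=dict)


def cell_pseudotime(
    nm,
    gene_set: list[str] | None = None,
    n_pcs: int = 50,
    k: int = 50,
    seed: int = 0,
) -> PseudotimeResult:
    """Diffusion pseudotime rooted at the minimum-PC1 cell.

    A kNN graph (k neighbours) is built in the top-``n_pcs`` PC space of
    the z-scored identity genes, a diffusion map is computed, and diffusion
    pseudotime is measured from the cell with the smallest PC1, then
    min-max rescaled to [0, 1]. If the graph is disconnected, pseudotime is
    reported on the root's component and other cells are flagged
    unreachable.
    """
    if nm.n_obs < k + 1:
        raise ConfigError("need at least k+1 cells")
    pca = pca_identity(nm, gene_set, n_components=min(n_pcs, nm.n_vars, nm.n_obs - 1))
    work = ad.AnnData(
        X=np.asarray(nm[:, pca.genes].X, dtype=float),
        obs=pd.DataFrame(index=nm.obs_names),
    )
    work.obsm["X_pca"] = pca.embedding
    sc.pp.neighbors(work, n_neighbors=k, use_rep="X_pca", random_state=seed)
    sc.tl.diffmap(work)
    work.uns["iroot"] = int(np.argmin(pca.embedding[:, 0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.dpt(work)
    t = work.obs["dpt_pseudotime"].to_numpy(dtype=float)
    reachable = np.isfinite(t)
    if not reachable.all():
        warnings.warn(
            f"{int((~reachable).sum())} cell(s) unreachable from the root; "
            "pseudotime reported on the root's component"
        )
    t_fin = t[reachable]
    lo, hi = t_fin.min(), t_fin.max()
    scaled = np.full_like(t, np.nan)
    scaled[reachable] = (t_fin - lo) / (hi - lo) if hi > lo else 0.0
    return PseudotimeResult(
        tc=pd.Series(scaled, index=nm.obs_names, name="pseudotime"),
        root_cell_id=str(nm.obs_names[work.uns["iroot"]]),
        reachable=pd.Series(reachable, index=nm.obs_names, name="reachable"),
        meta={"n_pcs": n_pcs, "k": k},
    )


def gene_pseudotime(expr_nonneg, tc: pd.Series | np.ndarray) -> pd.Series:
    """Expression-weighted average of cell pseudotime, per gene.

    ``expr_nonneg`` is a cells x genes matrix of non-negative size- and
    log-normalized expression (an AnnData's ``"lognorm"`` layer or a
    DataFrame/array); weights are each gene's expression normalized to sum
    to 1 over cells. All-zero genes have no defined pseudotime and return
    NaN. To compare conditions, compute Tg once on a reference condition
    and hold it fixed.
    """
    if hasattr(expr_nonneg, "layers") and "lognorm" in expr_nonneg.layers:
        values = np.asarray(expr_nonneg.layers["lognorm"], dtype=float)
        genes = list(expr_nonneg.var_names)
    elif isinstance(expr_nonneg, pd.DataFrame):
        values = expr_nonneg.to_numpy(dtype=float)
        genes = list(expr_nonneg.columns)
    else:
        values = np.asarray(expr_nonneg, dtype=float)
        genes = [f"g{j}" for j in range(values.shape[1])]
    if (values < 0).any():
        raise DataError("gene pseudotime requires non-negative expression values")
    t = np.asarray(tc, dtype=float)
    if len(t) != values.shape[0]:
        raise DataError("pseudotime must cover every cell")
    totals = values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Tg = (values * t[:, None]).sum(axis=0) / totals
    Tg[totals == 0] = np.nan
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} all-zero gene(s) have undefined pseudotime")
    return pd.Series(Tg, index=genes, name="gene_pseudotime")
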