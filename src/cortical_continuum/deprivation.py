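"""Condition-driven redistribution on the identity-gene manifold.

Quantifies how a perturbation (e.g. dark rearing) moves cells within the
2-D archetype manifold and which genes drive it:

* paired 2-D density histograms and their difference map;
* the Jensen-Shannon distance between densities (square root of the JS
  divergence, natural-log convention, so its maximum for disjoint
  supports is sqrt(ln 2));
* the exact optimal-transport (earth mover's) coupling between the two
  empirical point clouds under squared-Euclidean cost, summarized as a
  coarse-grained vector field of mean displacements;
* focused K-means on identity genes only, to recover matched types when
  state-program variance masks them;
* pseudo-bulk differential expression where biological samples, not
  cells, are the statistical units (per-type t-tests on CPM with BH-FDR);
* Fisher-exact overlap enrichment between gene lists over a fixed
  background;
* classification of vision-dependent identity genes into regulation
  groups from their signed significance pattern across types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist, jensenshannon
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, NumericalError
from .preprocess import _dense

__all__ = [
    "DensityComparison",
    "density_difference",
    "js_divergence",
    "TransportResult",
    "optimal_transport_map",
    "coarse_grained_vector_field",
    "focused_kmeans",
    "pseudobulk_deg",
    "OverlapResult",
    "overlap_enrichment",
    "classify_regulation_groups",
]


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


@dataclass
class DensityComparison:
    hist_a: np.ndarray
    hist_b: np.ndarray
    difference: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


def density_difference(
    emb_a: np.ndarray, emb_b: np.ndarray, binwidth: float = 1.25
) -> DensityComparison:
    """Paired probability histograms on a shared grid plus their difference.

    Both embeddings must live on the same axes; the grid covers the joint
    extent with equal square bins of side ``binwidth`` (1-1.5 PC units is a
    robust choice for archetype embeddings). Each histogram is normalized
    to total probability 1, so the difference sums to 0 by construction.
    """
    a = np.asarray(emb_a, dtype=float)
    b = np.asarray(emb_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("empty embedding")
    allpts = np.vstack([a, b])
    lo = np.floor(allpts.min(axis=0) / binwidth) * binwidth
    hi = np.ceil(allpts.max(axis=0) / binwidth) * binwidth
    x_edges = np.arange(lo[0], hi[0] + binwidth, binwidth)
    y_edges = np.arange(lo[1], hi[1] + binwidth, binwidth)
    ha, _, _ = np.histogram2d(a[:, 0], a[:, 1], bins=(x_edges, y_edges))
    hb, _, _ = np.histogram2d(b[:, 0], b[:, 1], bins=(x_edges, y_edges))
    ha /= ha.sum()
    hb /= hb.sum()
    return DensityComparison(ha, hb, ha - hb, x_edges, y_edges)


def js_divergence(hist_a: np.ndarray, hist_b: np.ndarray, base: float | None = None) -> float:
    """Jensen-Shannon distance between two histograms on identical grids.

    Returns the square root of the JS divergence in natural-log units by
    default (pass ``base=2`` for the bounded-by-1 convention). Symmetric and
    zero iff the histograms are equal; for disjoint supports the value is
    sqrt(ln 2) ~ 0.8326.
    """
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("histograms must share a grid")
    return float(jensenshannon(a.ravel(), b.ravel(), base=base))


# ---------------------------------------------------------------------------
# optimal transport
# ---------------------------------------------------------------------------


@dataclass
class TransportResult:
    """Exact EMD coupling between two uniform empirical distributions."""

    coupling: np.ndarray  # source x target, rows sum to 1/n_src, cols to 1/n_tgt
    cost: float
    cost_convention: str
    source_marginal: np.ndarray = field(default=None)
    target_marginal: np.ndarray = field(default=None)


def optimal_transport_map(
    source_pts: np.ndarray,
    target_pts: np.ndarray,
    cost: str = "sqeuclidean",
) -> TransportResult:
    """Exact earth mover's coupling between two point clouds.

    Uniform weights on both sides; cost is pairwise squared Euclidean
    distance by default (``cost="euclidean"`` for plain distance). With
    equal set sizes the problem is an assignment problem and is solved
    exactly by the Hungarian algorithm; otherwise it is solved as the
    transportation linear program (HiGHS).
    """
    src = np.atleast_2d(np.asarray(source_pts, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_pts, dtype=float))
    if src.size == 0 or tgt.size == 0:
        raise DataError("both point sets must be non-empty")
    if cost not in ("sqeuclidean", "euclidean"):
        raise ConfigError("cost must be 'sqeuclidean' or 'euclidean'")
    C = cdist(src, tgt, metric=cost)
    n, m = C.shape
    if n == m:
        rows, cols = linear_sum_assignment(C)
        G = np.zeros_like(C)
        G[rows, cols] = 1.0 / n
        total = float(C[rows, cols].sum() / n)
    else:
        if n * m > 4_000_000:
            raise ConfigError("transport problem too large; subsample the point clouds")
        # marginal constraints: row sums = 1/n, column sums = 1/m
        A_rows = sp.kron(sp.eye(n), np.ones((1, m)))
        A_cols = sp.kron(np.ones((1, n)), sp.eye(m))
        A = sp.vstack([A_rows, A_cols]).tocsc()[:-1]  # drop one redundant constraint
        rhs = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])[:-1]
        res = linprog(C.ravel(), A_eq=A, b_eq=rhs, bounds=(0, None), method="highs")
        if not res.success:
            raise NumericalError(f"transport LP failed: {res.message}")
        G = res.x.reshape(n, m)
        total = float(res.fun)
    return TransportResult(
        coupling=G,
        cost=total,
        cost_convention=cost,
        source_marginal=np.full(n, 1.0 / n),
        target_marginal=np.full(m, 1.0 / m),
    )


def coarse_grained_vector_field(
    tr: TransportResult,
    source_pts: np.ndarray,
    target_pts: np.ndarray,
    grid_binwidth: float = 1.25,
) -> pd.DataFrame:
    """Mean transport displacement per source-grid bin.

    Each source cell's displacement is the coupling-weighted barycenter of
    its targets minus its own position; bins of side ``grid_binwidth``
    average these over member cells. Returns one row per occupied bin with
    the bin center, mean displacement vector and cell count (the natural
    aesthetics: arrow length ~ displacement, darkness ~ count).
    """
    src = np.asarray(source_pts, dtype=float)
    tgt = np.asarray(target_pts, dtype=float)
    G = tr.coupling
    row_mass = G.sum(axis=1)
    bary = np.where(row_mass[:, None] > 0, (G @ tgt) / np.where(row_mass == 0, 1, row_mass)[:, None], src)
    disp = bary - src

    bx = np.floor(src[:, 0] / grid_binwidth).astype(int)
    by = np.floor(src[:, 1] / grid_binwidth).astype(int)
    rows = []
    for key in set(zip(bx.tolist(), by.tolist())):
        mask = (bx == key[0]) & (by == key[1])
        rows.append(
            dict(
                x=(key[0] + 0.5) * grid_binwidth,
                y=(key[1] + 0.5) * grid_binwidth,
                dx=float(disp[mask, 0].mean()),
                dy=float(disp[mask, 1].mean()),
                n_cells=int(mask.sum()),
            )
        )
    return pd.DataFrame(rows).sort_values(["x", "y"], ignore_index=True)


# ---------------------------------------------------------------------------
# focused clustering & pseudo-bulk DE
# ---------------------------------------------------------------------------


def focused_kmeans(
    nm, gene_set: list[str], k: int = 3, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """K-means on the z-scored identity-gene space only.

    Restricting the feature space to type-identity genes recovers matched
    types across conditions when state-program variance dominates the HVG
    space.
    """
    genes = [g for g in gene_set if g in nm.var_names]
    if not genes:
        raise DataError("no gene of the set is present in the matrix")
    X = np.asarray(nm[:, genes].X, dtype=float)
    if k > X.shape[0]:
        raise ConfigError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return pd.Series(km.labels_, index=nm.obs_names, name="focused_cluster")


def pseudobulk_deg(
    counts,
    type_labels,
    sample_labels,
    condition_labels,
    min_cpm: float = 10.0,
    min_fc: float = 2.0,
    max_fdr: float = 0.05,
    pseudocount: float = 1.0,
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Replicate-level differential expression between two conditions.

    Raw counts are aggregated per (type, sample) into pseudo-bulk profiles
    and CPM-normalized; genes with mean CPM above ``min_cpm`` in at least
    one type in either condition are tested. Per gene and type, a
    two-sided independent-samples t-test compares sample-level CPM between
    conditions, with BH-FDR within each type. A gene is a DEG for a type
    when ``fdr < max_fdr`` and ``|log2FC| > log2(min_fc)``; log2FC is
    condition-2 over condition-1 mean CPM with ``pseudocount`` added to
    both sides.
    """
    X = _dense(counts.X) if hasattr(counts, "X") else np.asarray(counts, dtype=float)
    types = np.asarray(type_labels)
    samples = np.asarray(sample_labels)
    conds = np.asarray(condition_labels)
    gene_names = (
        list(counts.var_names) if hasattr(counts, "var_names") else [f"g{j}" for j in range(X.shape[1])]
    )
    if conditions is None:
        conditions = tuple(pd.unique(conds))
    if len(conditions) != 2:
        raise DataError("exactly two conditions are required")
    c1, c2 = conditions
    sample_cond = {}
    for s, c in zip(samples, conds):
        sample_cond[s] = c
    for c in conditions:
        if sum(v == c for v in sample_cond.values()) < 2:
            raise DataError(f"condition {c!r} has fewer than 2 samples")

    # pseudo-bulk: sum raw counts per (type, sample), then CPM
    bulk: dict[tuple[str, str], np.ndarray] = {}
    for t in pd.unique(types):
        for s in pd.unique(samples):
            mask = (types == t) & (samples == s)
            if mask.any():
                v = X[mask].sum(axis=0)
                tot = v.sum()
                bulk[(t, s)] = v * (1e6 / tot) if tot > 0 else v
    # gene filter: mean CPM > min_cpm in at least one (type, condition)
    testable = np.zeros(X.shape[1], dtype=bool)
    for t in pd.unique(types):
        for c in conditions:
            mats = [bulk[(t, s)] for s in pd.unique(samples) if (t, s) in bulk and sample_cond[s] == c]
            if mats:
                testable |= np.mean(mats, axis=0) > min_cpm

    rows = []
    for t in pd.unique(types):
        m1 = np.array([bulk[(t, s)] for s in pd.unique(samples) if (t, s) in bulk and sample_cond[s] == c1])
        m2 = np.array([bulk[(t, s)] for s in pd.unique(samples) if (t, s) in bulk and sample_cond[s] == c2])
        if len(m1) < 2 or len(m2) < 2:
            raise DataError(f"type {t!r} lacks two samples in each condition")
        idx = np.flatnonzero(testable)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat, pval = stats.ttest_ind(m2[:, idx], m1[:, idx], axis=0)
        pval = np.where(np.isnan(pval), 1.0, pval)
        tstat = np.where(np.isnan(tstat), 0.0, tstat)
        fdr = multipletests(pval, method="fdr_bh")[1]
        log2fc = np.log2((m2[:, idx].mean(axis=0) + pseudocount) / (m1[:, idx].mean(axis=0) + pseudocount))
        for i, j in enumerate(idx):
            rows.append(
                dict(
                    gene=gene_names[j],
                    type=t,
                    log2fc=float(log2fc[i]),
                    t_statistic=float(tstat[i]),
                    p_value=float(pval[i]),
                    fdr=float(fdr[i]),
                    is_deg=bool(fdr[i] < max_fdr and abs(log2fc[i]) > np.log2(min_fc)),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap enrichment & regulation groups
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    odds_ratio: float
    p_value: float
    table: tuple[int, int, int, int]  # (a, b, c, d)
    haldane_corrected: bool


def overlap_enrichment(list_a: Iterable, list_b: Iterable, background: Iterable) -> OverlapResult:
    """Fisher exact test of overlap between two gene lists over a background.

    The 2x2 table counts membership in ``list_a`` x ``list_b`` over the
    background; the sample odds ratio is ``ad/bc`` with a Haldane 0.5
    correction (flagged) when any cell is zero; the two-sided p-value is the
    exact hypergeometric one.
    """
    bg = set(background)
    if not bg:
        raise DataError("empty background")
    A = set(list_a) & bg
    B = set(list_b) & bg
    if set(list_a) - bg or set(list_b) - bg:
        raise DataError("gene lists must be subsets of the background")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(bg - A - B)
    corrected = min(a, b, c, d) == 0
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapResult(float(odds), float(p), (a, b, c, d), corrected)


_DEFAULT_TYPE_ORDER = ("A", "B", "C")


def _default_group_rule(pattern: str) -> str:
    """Map an (A, B, C) signed-significance pattern to a regulation group.

    Characters are '+' (up), '-' (down), '0' (unchanged) in type order.
    The six groups are a documented reconstruction: the source material
    enumerates only the "up in B and C, unchanged in A" group explicitly.
    """
    if pattern == "000":
        return "vision-independent"
    n_up = pattern.count("+")
    n_dn = pattern.count("-")
    a, b, c = pattern
    if n_up == 3:
        return "group1_up_all"
    if n_dn == 3:
        return "group2_down_all"
    if a == "0" and b == "+" and c == "+":
        return "group3_up_BC_only"
    if a == "0" and b == "-" and c == "-":
        return "group4_down_BC_only"
    if (n_up + n_dn) == 1:
        return "group5_single_type"
    return "group6_mixed"


def classify_regulation_groups(
    deg: pd.DataFrame,
    identity_sets: Mapping[str, Iterable[str]],
    rule: Callable[[str], str] = _default_group_rule,
    type_order: tuple[str, ...] = _DEFAULT_TYPE_ORDER,
) -> tuple[pd.Series, dict[str, int]]:
    """Group vision-dependent identity genes by regulation pattern.

    ``deg`` is a :func:`pseudobulk_deg` table with per-(gene, type) calls.
    Each identity gene gets a pattern string over ``type_order`` ('+', '-',
    '0' per type from the DEG flag and log2FC sign), mapped to a group by
    ``rule`` (configurable; the default is a reconstruction). Also returns
    the three-way overlap counts between the union of vision-dependent
    genes, the identity genes and the IEG set (``identity_sets`` must
    contain ``"identity"`` and may contain ``"ieg"``).
    """
    if "identity" not in identity_sets:
        raise ConfigError("identity_sets must contain an 'identity' list")
    missing = [t for t in type_order if t not in set(deg["type"])]
    if missing:
        raise DataError(f"missing per-type DEG calls for {missing}")
    identity = set(identity_sets["identity"])
    iegs = set(identity_sets.get("ieg", ()))

    calls = deg.set_index(["gene", "type"])
    groups = {}
    for gene in sorted(identity):
        pattern = ""
        complete = True
        for t in type_order:
            if (gene, t) not in calls.index:
                complete = False
                break
            row = calls.loc[(gene, t)]
            if bool(row["is_deg"]):
                pattern += "+" if row["log2fc"] > 0 else "-"
            else:
                pattern += "0"
        if complete:
            groups[gene] = rule(pattern)
    series = pd.Series(groups, name="regulation_group")

    deg_union = set(deg.loc[deg["is_deg"], "gene"])
    venn = {
        "vision_dependent": len(deg_union),
        "identity": len(identity),
        "ieg": len(iegs),
        "vision_dependent&identity": len(deg_union & identity),
        "vision_dependent&ieg": len(deg_union & iegs),
        "identity&ieg": len(identity & iegs),
        "vision_dependent&identity&ieg": len(deg_union & identity & iegs),
    }
    return series, venn
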