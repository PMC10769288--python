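"""Archetypal analysis and the t-ratio triangularity test.

Archetypes are fitted by principal convex hull analysis (PCHA): archetypes
are constrained to be convex combinations of data points, and each data
point is approximated by a convex combination of archetypes. The fit
alternates projected-gradient least squares on the two stochastic matrices
(C and S) with simplex projection, FurthestSum initialization, and stops
when the relative loss change drops below 1e-6.

Triangularity of a 2-D point cloud is measured by the t-ratio: the area of
the data's convex hull divided by the area of its minimal-area enclosing
triangle, a number in (0, 1] that equals 1 exactly when the hull is itself
a triangle. Because PCHA archetypes are convex combinations of data points,
the PCHA triangle is inscribed in the data and its area can exceed the
hull's; the enclosing-triangle convention keeps the ratio bounded and
drives the permutation p-value, while PCHA supplies the reported archetype
positions. Both triangles are returned.

Significance is assessed by permuting each gene independently across all
cells, refitting the PCA per shuffle, and recomputing the t-ratio; the
p-value uses the add-one estimator (never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import minimize
from scipy.spatial import ConvexHull

from .errors import ConfigError, DataError, FitError, NumericalError

__all__ = [
    "TriangleFit",
    "fit_archetypes",
    "min_enclosing_triangle",
    "t_ratio",
    "t_ratio_test",
    "archetype_stability",
    "pca_embed",
]


# ---------------------------------------------------------------------------
# PCHA
# ---------------------------------------------------------------------------


def _simplex_project_columns(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    k, n = V.shape
    U = np.sort(V, axis=0)[::-1]
    css = np.cumsum(U, axis=0) - 1.0
    ind = np.arange(1, k + 1)[:, None]
    cond = U - css / ind > 0
    rho = k - 1 - np.argmax(cond[::-1], axis=0)  # last True index per column
    theta = css[rho, np.arange(n)] / (rho + 1.0)
    return np.maximum(V - theta[None, :], 0.0)


def _furthest_sum(X: np.ndarray, k: int, seed: int) -> list[int]:
    """FurthestSum seeding: greedily pick mutually distant data points."""
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    start = int(rng.integers(n))
    chosen = [start]
    sum_dist = np.linalg.norm(X - X[:, [start]], axis=0)
    for _ in range(k - 1):
        sum_dist[chosen] = -np.inf
        nxt = int(np.argmax(sum_dist))
        chosen.append(nxt)
        sum_dist = np.where(
            np.isinf(sum_dist), sum_dist, sum_dist + np.linalg.norm(X - X[:, [nxt]], axis=0)
        )
    # drop the random start, as is conventional, if we can replace it
    if k < n:
        sum_dist = np.zeros(n)
        for c in chosen[1:]:
            sum_dist += np.linalg.norm(X - X[:, [c]], axis=0)
        sum_dist[chosen[1:]] = -np.inf
        chosen[0] = int(np.argmax(sum_dist))
    return chosen


def _triangle_barycentric_projection(P: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric weights of each point's Euclidean projection onto a
    triangle (vectorized closest-point-on-triangle).

    ``P``: (n, 2) points; ``tri``: (3, 2) vertices. Returns (n, 3) convex
    weights. This solves the simplex-constrained least-squares subproblem
    of PCHA exactly in the 2-D / 3-archetype case.
    """
    a, b, c = tri
    T = np.column_stack([b - a, c - a])  # 2x2
    det = np.linalg.det(T)
    if abs(det) < 1e-14:
        raise FitError("degenerate (collinear) triangle")
    inv = np.linalg.inv(T)
    uv = (P - a) @ inv.T
    w = np.column_stack([1.0 - uv.sum(axis=1), uv])  # barycentric (a, b, c)

    out = np.empty((len(P), 3))
    inside = (w >= 0).all(axis=1)
    out[inside] = w[inside]
    if (~inside).any():
        Q = P[~inside]
        best_d = np.full(len(Q), np.inf)
        best_w = np.zeros((len(Q), 3))
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e = tri[j] - tri[i]
            t = np.clip(((Q - tri[i]) @ e) / (e @ e), 0.0, 1.0)
            proj = tri[i] + t[:, None] * e
            d = ((Q - proj) ** 2).sum(axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_w[better] = 0.0
            best_w[better, i] = 1.0 - t[better]
            best_w[better, j] = t[better]
        out[~inside] = best_w
    return out


def _project_to_convex_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Euclidean projection of points onto a convex CCW polygon (2-D)."""
    P = np.atleast_2d(pts)
    E0 = poly
    E1 = np.roll(poly, -1, axis=0)
    edge = E1 - E0
    # inside test: all cross products >= 0 for CCW polygons
    cross = (
        edge[None, :, 0] * (P[:, None, 1] - E0[None, :, 1])
        - edge[None, :, 1] * (P[:, None, 0] - E0[None, :, 0])
    )
    inside = (cross >= -1e-12).all(axis=1)
    out = P.copy()
    if (~inside).any():
        Q = P[~inside]
        t = np.clip(
            ((Q[:, None, :] - E0[None, :, :]) * edge[None, :, :]).sum(-1)
            / (edge * edge).sum(-1)[None, :],
            0.0,
            1.0,
        )
        proj = E0[None, :, :] + t[:, :, None] * edge[None, :, :]
        d = ((Q[:, None, :] - proj) ** 2).sum(-1)
        best = np.argmin(d, axis=1)
        out[~inside] = proj[np.arange(len(Q)), best]
    return out


def _fit_archetypes_2d3(pts: np.ndarray, max_iter: int, tol: float, seed: int) -> np.ndarray:
    """Alternating least squares specialized to 2-D embeddings, 3 archetypes.

    The S-subproblem is solved exactly by point-to-triangle projection; the
    archetype positions are updated toward their unconstrained least-squares
    optimum and projected back onto the data's convex hull (the delta=0
    constraint), with step damping to keep the loss monotone.
    """
    hull = ConvexHull(pts)
    poly = pts[hull.vertices]
    idx = _furthest_sum(pts.T, 3, seed)
    B = pts[idx].astype(float)

    S = _triangle_barycentric_projection(pts, B)
    f = float(((pts - S @ B) ** 2).sum())
    for _ in range(max_iter):
        f_prev = f
        # B-step: damped move toward the unconstrained optimum, projected
        # onto the hull
        StS = S.T @ S + 1e-12 * np.eye(3)
        B_target = np.linalg.solve(StS, S.T @ pts)
        step = 1.0
        for _ in range(12):
            B_new = _project_to_convex_polygon(B + step * (B_target - B), poly)
            try:
                S_new = _triangle_barycentric_projection(pts, B_new)
            except FitError:
                step /= 2.0
                continue
            f_new = float(((pts - S_new @ B_new) ** 2).sum())
            if f_new <= f:
                B, S, f = B_new, S_new, f_new
                break
            step /= 2.0
        if f_prev - f < tol * max(f_prev, 1e-30):
            break
    return B


def fit_archetypes(
    points: np.ndarray,
    n_archetypes: int = 3,
    delta: float = 0.0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Fit archetypes to ``points`` (n_obs x n_dim) by PCHA.

    Returns the archetype coordinates (n_archetypes x n_dim). Only the
    strict convex-hull variant (``delta=0``) is supported; the relaxation
    parameter is accepted for interface compatibility.
    """
    if delta != 0.0:
        raise ConfigError("only delta=0 (strict convex combinations) is supported")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < n_archetypes:
        raise ConfigError(f"need at least {n_archetypes} points")
    if n_archetypes >= 3 and pts.shape[1] >= 2:
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] < 1e-12 * max(sv[0], 1.0):
            raise FitError("points are collinear; archetypal fit is degenerate")

    X = pts.T  # d x n
    d, n = X.shape
    k = n_archetypes
    if n == k:
        return pts.copy()
    if d == 2 and k == 3:
        return _fit_archetypes_2d3(pts, max_iter, tol, seed)

    C = np.zeros((n, k))
    for j, idx in enumerate(_furthest_sum(X, k, seed)):
        C[idx, j] = 1.0
    S = np.full((k, n), 1.0 / k)

    sst = float(np.sum(X * X))
    XC = X @ C

    def loss(S_: np.ndarray, XC_: np.ndarray) -> float:
        R = XC_ @ S_ - X
        return float(np.sum(R * R))

    mu_s, mu_c = 1.0, 1.0
    f = loss(S, XC)
    for _ in range(max_iter):
        f_prev = f
        # S update (projected gradient with backtracking)
        G = XC.T @ (XC @ S - X)
        gnorm = np.linalg.norm(G) + 1e-30
        for _ in range(20):
            S_new = _simplex_project_columns(S - mu_s / gnorm * G)
            f_new = loss(S_new, XC)
            if f_new <= f:
                S, f = S_new, f_new
                mu_s *= 1.2
                break
            mu_s /= 2.0
        # C update
        R = XC @ S - X
        Gc = X.T @ R @ S.T
        gnorm = np.linalg.norm(Gc) + 1e-30
        for _ in range(20):
            C_new = _simplex_project_columns(C - mu_c / gnorm * Gc)
            XC_new = X @ C_new
            f_new = loss(S, XC_new)
            if f_new <= f:
                C, XC, f = C_new, XC_new, f_new
                mu_c *= 1.2
                break
            mu_c /= 2.0
        if f_prev - f < tol * max(f_prev, 1e-12 * sst, 1e-30):
            break
    return (X @ C).T


# ---------------------------------------------------------------------------
# minimal-area enclosing triangle
# ---------------------------------------------------------------------------


def _hull_ccw(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DataError("need at least 3 points")
    hull = ConvexHull(pts)
    return pts[hull.vertices]  # counter-clockwise by scipy convention


def _triangle_area(verts: np.ndarray) -> float:
    a, b, c = verts
    return 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


def _area_for_angles(
    xi: np.ndarray, eta: np.ndarray, th2: np.ndarray, th3: np.ndarray
) -> np.ndarray:
    """Triangle area per (edge, angle pair), +inf when unbounded/invalid.

    Works in each flush edge's frame (base line eta=0, hull in eta >= 0).
    ``xi, eta``: (E, h) vertex coordinates per edge frame; ``th2, th3``:
    (E, m) candidate outward-normal angles of the two free sides,
    th2 in (-pi/2, pi/2), th3 in (pi/2, 3pi/2).
    """
    c2, s2 = np.cos(th2), np.sin(th2)
    c3, s3 = np.cos(th3), np.sin(th3)
    # support values: max over hull vertices of n . v
    sup2 = np.max(c2[..., None] * xi[:, None, :] + s2[..., None] * eta[:, None, :], axis=-1)
    sup3 = np.max(c3[..., None] * xi[:, None, :] + s3[..., None] * eta[:, None, :], axis=-1)
    # base intersections (y = 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        xB = sup2 / c2
        xC = sup3 / c3
        # apex: solve [c2 s2; c3 s3] [x y]' = [sup2 sup3]'
        det = c2 * s3 - s2 * c3
        xA = (sup2 * s3 - sup3 * s2) / det
        yA = (c2 * sup3 - c3 * sup2) / det
        area = 0.5 * np.abs((xB - xC) * yA)
    bad = ~np.isfinite(area) | (yA <= 1e-12)
    return np.where(bad, np.inf, area)


def min_enclosing_triangle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimal-area triangle enclosing the convex hull of ``points``.

    Uses the classical property that some side of the optimal triangle is
    flush with a hull edge: for every hull edge as the flush base, the area
    is minimized over the outward-normal angles of the two remaining
    supporting lines (coarse grid, then golden-section coordinate descent,
    then a Nelder-Mead polish of the best candidate). Returns
    ``(vertices (3, 2), area)``.
    """
    V = _hull_ccw(points)
    h = len(V)
    if h == 3:
        return V.copy(), _triangle_area(V)

    P = V
    Q = np.roll(V, -1, axis=0)
    u = Q - P
    ulen = np.linalg.norm(u, axis=1, keepdims=True)
    u = u / ulen
    w = np.column_stack([-u[:, 1], u[:, 0]])  # inward normal for CCW hulls
    rel = V[None, :, :] - P[:, None, :]
    xi = np.einsum("ehd,ed->eh", rel, u)  # (E, h)
    eta = np.einsum("ehd,ed->eh", rel, w)

    m = 24
    th2_grid = np.linspace(-np.pi / 2 + 0.02, np.pi / 2 - 0.02, m)
    th3_grid = np.linspace(np.pi / 2 + 0.02, 3 * np.pi / 2 - 0.02, m)
    T2, T3 = np.meshgrid(th2_grid, th3_grid, indexing="ij")
    area = _area_for_angles(xi, eta, np.broadcast_to(T2.ravel(), (h, m * m)),
                            np.broadcast_to(T3.ravel(), (h, m * m)))
    best_flat = np.argmin(area, axis=1)
    th2 = T2.ravel()[best_flat].copy()
    th3 = T3.ravel()[best_flat].copy()

    # golden-section coordinate descent around the grid optimum, all edges
    # in parallel
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    span = (th2_grid[1] - th2_grid[0]) * 1.5
    for _ in range(3):
        for which in (0, 1):
            lo = (th2 if which == 0 else th3) - span
            hi = (th2 if which == 0 else th3) + span
            a_, b_ = lo.copy(), hi.copy()
            c_ = b_ - gr * (b_ - a_)
            d_ = a_ + gr * (b_ - a_)
            for _ in range(30):
                if which == 0:
                    fc = _area_for_angles(xi, eta, c_[:, None], th3[:, None])[:, 0]
                    fd = _area_for_angles(xi, eta, d_[:, None], th3[:, None])[:, 0]
                else:
                    fc = _area_for_angles(xi, eta, th2[:, None], c_[:, None])[:, 0]
                    fd = _area_for_angles(xi, eta, th2[:, None], d_[:, None])[:, 0]
                move_right = fc > fd
                a_ = np.where(move_right, c_, a_)
                b_ = np.where(move_right, b_, d_)
                c_ = b_ - gr * (b_ - a_)
                d_ = a_ + gr * (b_ - a_)
            opt = 0.5 * (a_ + b_)
            if which == 0:
                th2 = opt
            else:
                th3 = opt
        span /= 4.0

    final = _area_for_angles(xi, eta, th2[:, None], th3[:, None])[:, 0]
    e = int(np.argmin(final))

    # Nelder-Mead polish of the winning edge
    def obj(t):
        return _area_for_angles(xi[[e]], eta[[e]], np.array([[t[0]]]), np.array([[t[1]]]))[0, 0]

    res = minimize(obj, np.array([th2[e], th3[e]]), method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-14, maxiter=400))
    t2, t3 = (res.x if res.fun <= final[e] else (th2[e], th3[e]))
    best_area = float(min(res.fun, final[e]))
    if not np.isfinite(best_area):
        raise NumericalError("enclosing-triangle search failed")

    # reconstruct vertices in the original frame
    c2, s2, c3, s3 = np.cos(t2), np.sin(t2), np.cos(t3), np.sin(t3)
    sup2 = float(np.max(c2 * xi[e] + s2 * eta[e]))
    sup3 = float(np.max(c3 * xi[e] + s3 * eta[e]))
    det = c2 * s3 - s2 * c3
    apex = np.array([(sup2 * s3 - sup3 * s2) / det, (c2 * sup3 - c3 * sup2) / det])
    b_local = np.array([sup2 / c2, 0.0])
    c_local = np.array([sup3 / c3, 0.0])
    frame = np.vstack([u[e], w[e]])  # rows: local axes in world coords
    verts = P[e] + np.vstack([apex, b_local, c_local]) @ frame
    return verts, best_area


def t_ratio(points_2d: np.ndarray, triangle: np.ndarray | None = None) -> float:
    """Convex-hull area divided by enclosing-triangle area.

    With the minimal-area enclosing triangle (the default), the ratio lies
    in (0, 1] and equals 1 exactly when the hull is itself a triangle. An
    explicit ``triangle`` (3 x 2) may be supplied instead.
    """
    hull = ConvexHull(np.asarray(points_2d, dtype=float))
    if triangle is None:
        _, tri_area = min_enclosing_triangle(points_2d)
    else:
        tri_area = _triangle_area(np.asarray(triangle, dtype=float))
    if tri_area <= 0:
        raise DataError("triangle has zero area")
    return float(hull.volume / tri_area)  # ConvexHull.volume is area in 2-D


# ---------------------------------------------------------------------------
# permutation test & stability
# ---------------------------------------------------------------------------


def pca_embed(values: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Top principal-component scores of a (cells x genes) matrix."""
    from scipy.linalg import eigh

    X = np.asarray(values, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc
    g = cov.shape[0]
    _, vecs = eigh(cov, subset_by_index=[g - n_components, g - 1])
    return Xc @ vecs[:, ::-1]


@dataclass
class TriangleFit:
    """Result of the triangular-boundedness analysis of a 2-D embedding."""

    archetypes: np.ndarray  # PCHA vertices (3 x 2)
    enclosing_triangle: np.ndarray  # minimal enclosing triangle (3 x 2)
    t_ratio: float
    p_value: float | None = None
    n_shuffles: int = 0
    null_t_ratios: np.ndarray | None = None
    stability: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _extract_values(nm, gene_set=None) -> np.ndarray:
    if hasattr(nm, "X"):
        sub = nm[:, [g for g in gene_set if g in nm.var_names]] if gene_set else nm
        return np.asarray(sub.X, dtype=float)
    return np.asarray(nm, dtype=float)


def t_ratio_test(
    nm,
    gene_set: list[str] | None = None,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> TriangleFit:
    """Permutation test of triangular boundedness in PC1-PC2.

    The observed t-ratio is computed on the top-2 PCA of the (z-scored)
    matrix. The null shuffles each gene independently across all cells,
    which preserves marginal gene distributions while destroying their
    correlations, and refits the PCA per shuffle. The p-value is
    ``(1 + #{null >= observed}) / (1 + n_shuffles)``.
    """
    if n_shuffles < 1:
        raise ConfigError("n_shuffles must be >= 1")
    values = _extract_values(nm, gene_set)
    rng = np.random.default_rng(seed)

    emb = pca_embed(values, 2)
    observed = t_ratio(emb)
    arch = fit_archetypes(emb, 3, seed=seed)
    tri, _ = min_enclosing_triangle(emb)

    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        shuffled = rng.permuted(values, axis=0)  # each gene independently
        null[b] = t_ratio(pca_embed(shuffled, 2))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffles)
    return TriangleFit(
        archetypes=arch,
        enclosing_triangle=tri,
        t_ratio=observed,
        p_value=float(p),
        n_shuffles=n_shuffles,
        null_t_ratios=null,
    )


def _match_archetypes(ref: np.ndarray, trial: np.ndarray) -> float:
    """Mean displacement after the best of the 6 label permutations."""
    from itertools import permutations

    best = np.inf
    for perm in permutations(range(len(ref))):
        d = np.linalg.norm(ref - trial[list(perm)], axis=1).mean()
        best = min(best, d)
    return best


def archetype_stability(
    nm,
    gene_set: list[str] | None = None,
    subsample_fraction: float = 0.8,
    n_trials: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Archetype displacement under cell and gene subsampling.

    Refits PCA + PCHA on random subsamples of cells and, separately, of
    genes; trial archetypes are aligned to the full-data archetypes
    (orthogonal Procrustes over the shared cells for gene subsampling, then
    the best of the 6 vertex permutations) and the per-trial mean
    displacement is reported as a fraction of the full fit's minimum
    inter-archetype distance.
    """
    import warnings

    values = _extract_values(nm, gene_set)
    n, g = values.shape
    rng = np.random.default_rng(seed)
    emb_full = pca_embed(values, 2)
    arch_full = fit_archetypes(emb_full, 3, seed=seed)
    dmin = min(
        np.linalg.norm(arch_full[i] - arch_full[j])
        for i in range(3)
        for j in range(i + 1, 3)
    )

    rows = []
    for mode in ("cells", "genes"):
        size = int(round(subsample_fraction * (n if mode == "cells" else g)))
        for trial in range(n_trials):
            if (mode == "cells" and size < 3) or (mode == "genes" and size < 2):
                warnings.warn(f"subsample too small for a fit; skipping {mode} trial {trial}")
                continue
            if size == (n if mode == "cells" else g):
                # full "subsample": the fit is the full fit by construction
                rows.append(dict(mode=mode, trial=trial, displacement_frac=0.0))
                continue
            if mode == "cells":
                idx = rng.choice(n, size=size, replace=False)
                emb = pca_embed(values[idx], 2)
                # align the subsample's PC frame to the full embedding
                R, _ = orthogonal_procrustes(emb, emb_full[idx])
                emb = emb @ R
            else:
                idx = rng.choice(g, size=size, replace=False)
                emb = pca_embed(values[:, idx], 2)
                R, _ = orthogonal_procrustes(emb, emb_full)
                emb = emb @ R
            arch = fit_archetypes(emb, 3, seed=seed + trial + 1)
            disp = _match_archetypes(arch_full, arch)
            rows.append(dict(mode=mode, trial=trial, displacement_frac=disp / dmin))
    return pd.DataFrame(rows)
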