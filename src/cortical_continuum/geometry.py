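"""Curved cortical coordinates.

The pial surface of a coronal section is modelled as a single-valued
degree-4 polynomial ``y = f(x)`` fitted to pial anchor cells (meningeal
cells positive for a pial marker). Sections whose surface is not
single-valued in ``x`` must be pre-rotated before fitting — that is a
documented precondition of this module. Each cell then receives a *depth*
(Euclidean distance to its nearest point on the curve) and a *tangent*
(arc length from the curve's domain start to that nearest point). V1 is
located along the tangential axis from the smoothed profiles of an
areal enrichment marker and a depletion marker, and tangential coordinates
are normalized so that 0 and 1 are the two ends of V1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError, FitError, SchemaError

__all__ = [
    "CorticalFrame",
    "fit_pial_surface",
    "assign_cortical_coordinates",
    "locate_v1",
    "normalize_tangential",
    "depth_expression_profile",
]

_ARC_STEP_UM = 1.0  # parameter step for arc length / nearest-point search


@dataclass
class CorticalFrame:
    """Fitted curve plus per-cell curved coordinates.

    ``coords`` is indexed by cell id with columns ``depth_um``,
    ``tangent_um``, ``extrapolated`` and, once V1 is set, ``tangent_norm``.
    """

    curve_coeffs: np.ndarray
    coords: pd.DataFrame
    v1_interval: tuple[float, float] | None = None
    x_domain: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)


def _check_spatial_table(cells: pd.DataFrame) -> None:
    for col in ("cell_id", "x_um", "y_um"):
        if col not in cells.columns:
            raise SchemaError(f"spatial table is missing required column {col!r}")
    if not np.isfinite(cells[["x_um", "y_um"]].to_numpy()).all():
        raise DataError("spatial coordinates must be finite")


def _point_curve_distance(
    coeffs: np.ndarray, x: np.ndarray, y: np.ndarray, x_domain: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points to the curve and the abscissa of the foot point.

    Dense sampling of the curve at 1 um steps (domain extended by 10% each
    side), nearest neighbour via a KD-tree, then local quadratic refinement
    of the squared distance through the three bracketing samples.
    """
    lo, hi = x_domain
    pad = 0.1 * (hi - lo)
    grid = np.arange(lo - pad, hi + pad + _ARC_STEP_UM, _ARC_STEP_UM)
    curve = np.column_stack([grid, np.polyval(coeffs, grid)])
    tree = cKDTree(curve)
    _, idx = tree.query(np.column_stack([x, y]))
    idx = np.clip(idx, 1, len(grid) - 2)

    # parabolic refinement of d^2(x) through the 3 bracketing grid points
    def sqdist(i: np.ndarray, off: int) -> np.ndarray:
        g = grid[i + off]
        return (x - g) ** 2 + (y - np.polyval(coeffs, g)) ** 2

    d_m, d_0, d_p = sqdist(idx, -1), sqdist(idx, 0), sqdist(idx, 1)
    denom = d_m - 2 * d_0 + d_p
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (d_m - d_p) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    x_foot = grid[idx] + shift * _ARC_STEP_UM
    dist = np.hypot(x - x_foot, y - np.polyval(coeffs, x_foot))
    return dist, x_foot


def fit_pial_surface(
    cells: pd.DataFrame,
    max_iter: int = 10,
    prune_fraction: float = 0.5,
    degree: int = 4,
    stable_tol_um: float = 1.0,
) -> np.ndarray:
    """Iteratively fit the pial reference curve to anchor cells.

    Fits a degree-4 polynomial to anchor cells (``anchor_flag``), computes
    each anchor's depth against the fit, prunes anchors deeper than
    ``prune_fraction`` times the robust maximum depth (the 95th percentile),
    and refits. Iteration stops when the curve is stable (successive fits
    deviate by less than ``stable_tol_um`` over the anchor domain), when the
    retained set stops changing, or at ``max_iter``; stopping on curve
    stability prevents the pruning threshold from chasing the anchor jitter
    once all genuine outliers are gone. Returns the polynomial
    coefficients, highest power first.
    """
    _check_spatial_table(cells)
    if "anchor_flag" not in cells.columns:
        raise SchemaError("spatial table is missing required column 'anchor_flag'")
    anchors = cells.loc[cells["anchor_flag"].astype(bool)]
    if len(anchors) < 10:
        raise FitError(f"need >=10 anchor cells, found {len(anchors)}")
    x = anchors["x_um"].to_numpy(dtype=float)
    y = anchors["y_um"].to_numpy(dtype=float)
    domain = (float(x.min()), float(x.max()))

    keep = np.ones(len(x), dtype=bool)
    grid = np.linspace(domain[0], domain[1], 200)
    prev = None
    coeffs = np.polyfit(x, y, degree)
    for _ in range(max_iter):
        coeffs = np.polyfit(x[keep], y[keep], degree)
        if prev is not None and np.max(np.abs(np.polyval(coeffs, grid) - np.polyval(prev, grid))) < stable_tol_um:
            break
        prev = coeffs
        depth, _ = _point_curve_distance(coeffs, x[keep], y[keep], domain)
        robust_max = np.percentile(depth, 95)
        # anchors within the curve-sampling resolution are "on the curve";
        # never prune below that floor
        threshold = max(prune_fraction * robust_max, _ARC_STEP_UM)
        new_keep = keep.copy()
        new_keep[keep] = depth <= threshold
        if new_keep.sum() < 5:
            raise FitError("fewer than 5 anchors remain after pruning")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return coeffs


def assign_cortical_coordinates(cells: pd.DataFrame, curve_coeffs: np.ndarray) -> CorticalFrame:
    """Assign per-cell depth and tangential (arc-length) coordinates.

    Depth is the unsigned Euclidean distance to the nearest point of the
    fitted curve; tangent is the arc length from the curve's domain start to
    that foot point (trapezoidal integration at 1 um steps). Cells whose
    ``x`` lies outside the anchor domain by more than 10% of its width are
    flagged ``extrapolated``.
    """
    _check_spatial_table(cells)
    coeffs = np.asarray(curve_coeffs, dtype=float)
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    domain = (float(x.min()), float(x.max()))

    dist, x_foot = _point_curve_distance(coeffs, x, y, domain)

    lo, hi = domain
    pad = 0.1 * (hi - lo)
    grid = np.arange(lo - pad, hi + pad + _ARC_STEP_UM, _ARC_STEP_UM)
    slope = np.polyval(np.polyder(coeffs), grid)
    # trapezoidal arc length: integrate sqrt(1 + f'(x)^2)
    integrand = np.sqrt(1.0 + slope**2)
    arc = np.concatenate([[0.0], np.cumsum((integrand[:-1] + integrand[1:]) * 0.5 * np.diff(grid))])
    tangent = np.interp(x_foot, grid, arc)
    tangent0 = np.interp(lo, grid, arc)
    tangent = tangent - tangent0  # arc length measured from the domain start

    width = hi - lo
    extrapolated = (x < lo - 0.1 * width) | (x > hi + 0.1 * width)
    coords = pd.DataFrame(
        {
            "depth_um": dist,
            "tangent_um": tangent,
            "extrapolated": extrapolated,
        },
        index=pd.Index(cells["cell_id"], name="cell_id"),
    )
    for extra in ("sample", "condition"):
        if extra in cells.columns:
            coords[extra] = cells[extra].to_numpy()
    return CorticalFrame(curve_coeffs=coeffs, coords=coords, x_domain=domain)


def _smooth_profile(
    t: np.ndarray, values: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Nadaraya-Watson smoothing of a per-cell profile along the tangent."""
    w = np.exp(-(((grid[:, None] - t[None, :]) / bandwidth) ** 2))
    num = w @ values
    den = w.sum(axis=1)
    return np.where(den > 0, num / np.where(den == 0, 1, den), np.nan)


def locate_v1(
    frame: CorticalFrame,
    expr_on: np.ndarray | pd.Series,
    expr_off: np.ndarray | pd.Series,
    smoothing_um: float = 100.0,
) -> tuple[float, float]:
    """Locate the V1 interval along the tangential axis.

    Both marker profiles are kernel-smoothed along the tangent (Gaussian
    bandwidth ``smoothing_um``); V1 is the maximal contiguous interval where
    the enrichment marker exceeds its tangential median while the depletion
    marker falls below its own. The endpoints are stored on the frame and
    returned. The median-threshold rule is this module's own reconstruction
    of a qualitative marker-based localization.
    """
    t = frame.coords["tangent_um"].to_numpy(dtype=float)
    on = np.asarray(expr_on, dtype=float)
    off = np.asarray(expr_off, dtype=float)
    if len(on) != len(t) or len(off) != len(t):
        raise DataError("marker profiles must align with the frame's cells")
    grid = np.arange(t.min(), t.max() + smoothing_um / 4, smoothing_um / 4)
    on_s = _smooth_profile(t, on, grid, smoothing_um)
    off_s = _smooth_profile(t, off, grid, smoothing_um)
    med_on, med_off = np.nanmedian(on_s), np.nanmedian(off_s)
    tol_on = 1e-9 * (abs(med_on) + 1.0)
    tol_off = 1e-9 * (abs(med_off) + 1.0)
    mask = (on_s > med_on + tol_on) & (off_s < med_off - tol_off)
    if not mask.any():
        # degenerate flat profiles: every position qualifies up to numerical
        # noise, so the interval is the full tangential extent
        mask = (on_s >= med_on - tol_on) & (off_s <= med_off + tol_off)
    if not mask.any():
        raise DataError("no tangential interval satisfies the V1 marker criteria")
    # maximal contiguous run of True
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    best = np.argmax(ends - starts)
    tm, tl = float(grid[starts[best]]), float(grid[ends[best] - 1])
    frame.v1_interval = (tm, tl)
    return tm, tl


def normalize_tangential(frame: CorticalFrame) -> CorticalFrame:
    """Add the V1-normalized tangential coordinate t~ = (t - tm)/(tl - tm).

    0 and 1 are the two ends of V1; values outside [0, 1] are preserved and
    denote flanking regions (t~ < 0 medial, t~ > 1 lateral).
    """
    if frame.v1_interval is None:
        raise DataError("v1_interval is not set; run locate_v1 first")
    tm, tl = frame.v1_interval
    if tl == tm:
        raise ConfigError("degenerate V1 interval (tl == tm)")
    t = frame.coords["tangent_um"].to_numpy(dtype=float)
    frame.coords["tangent_norm"] = (t - tm) / (tl - tm)
    return frame


def depth_expression_profile(
    frame: CorticalFrame,
    nm,
    gene_set: list[str],
    n_bins: int = 20,
    depth_range: tuple[float, float] = (0.0, 400.0),
    layer: str = "lognorm",
    baseline: float | None = None,
) -> pd.DataFrame:
    """Mean gene-set expression along cortical depth, with SEM over samples.

    Cells are binned by depth within ``depth_range``; per bin, the gene-set
    mean expression is averaged within each sample and then across samples
    (SEM over samples). Empty bins yield NaN, not zero. If ``baseline`` is
    given (e.g. the mean expression over V1 in reference-condition samples),
    the profile is reported as fold change relative to it.
    """
    cells = frame.coords.index.intersection(nm.obs_names)
    if len(cells) == 0:
        raise DataError("frame and normalized matrix share no cells")
    sub = nm[cells]
    genes = [g for g in gene_set if g in sub.var_names]
    if not genes:
        raise DataError("no gene of the set is present in the matrix")
    vals = np.asarray(sub[:, genes].layers[layer]).mean(axis=1)
    depth = frame.coords.loc[cells, "depth_um"].to_numpy(dtype=float)
    sample = (
        sub.obs["sample"].to_numpy() if "sample" in sub.obs.columns else np.repeat("s0", len(cells))
    )
    edges = np.linspace(depth_range[0], depth_range[1], n_bins + 1)
    which = np.digitize(depth, edges) - 1
    ok = (which >= 0) & (which < n_bins)

    rows = []
    for b in range(n_bins):
        in_bin = ok & (which == b)
        per_sample = [
            vals[in_bin & (sample == s)].mean()
            for s in pd.unique(sample)
            if (in_bin & (sample == s)).any()
        ]
        mean = float(np.mean(per_sample)) if per_sample else np.nan
        sem = (
            float(np.std(per_sample, ddof=1) / np.sqrt(len(per_sample)))
            if len(per_sample) > 1
            else np.nan
        )
        if baseline is not None and np.isfinite(mean):
            mean = mean / baseline
            sem = sem / baseline if np.isfinite(sem) else sem
        rows.append(
            dict(
                bin_center=0.5 * (edges[b] + edges[b + 1]),
                mean=mean,
                sem=sem,
                n_cells=int(in_bin.sum()),
            )
        )
    return pd.DataFrame(rows)
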