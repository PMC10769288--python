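"""Synthetic count-matrix generators.

Three generators cover the inputs the downstream pipeline needs:

``simulate_continuum``
    A 1-D latent expression continuum. Cells and genes carry normalized
    rankings ``p_i = i/Nc`` and ``p_j = j/Ng`` (1-based ranks), and the
    expected expression of gene *j* in cell *i* is the Gaussian kernel
    ``lambda_ij = exp(-((p_i - p_j)/epsilon)**2)``. Counts are drawn as
    ``s * Poisson(lambda_ij)`` — a scaled Poisson with the scale outside the
    distribution, so counts are integer multiples of ``s`` when ``s`` is
    integral.

``simulate_discrete_types``
    Discrete types with leaky markers: ``lambda_ij = 1`` when the cell's type
    equals the gene's type, else ``epsilon``. A fixed number of each type's
    markers is additionally expressed in the *next* type in order (A markers
    leak into B, B into C, ...; no wraparound), which imposes an ordering on
    the types.

``simulate_cortical_section``
    A curved cortical slab emulating an imaging-based spatial transcriptomics
    section: pial anchor cells on a quartic reference curve, depth-zoned
    subclasses, overlapping A/B/C identity-gene gradients in the upper
    layers, a tangential V1 marker interval, per-sample batch factors,
    volumes and blank (false-positive) counts, and a planted IEG upshift in
    dark-reared samples.

All generators are exactly reproducible under a fixed seed and return an
:class:`anndata.AnnData` count matrix plus a :class:`SimulatedTruth` record
of the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "ContinuumSimParams",
    "DiscreteSimParams",
    "SpatialSectionSpec",
    "SimulatedTruth",
    "simulate_continuum",
    "simulate_discrete_types",
    "simulate_archetype_mixture",
    "simulate_cortical_section",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContinuumSimParams:
    """Parameters of the 1-D continuum simulator.

    Defaults are the published configuration: 600 cells, 60 genes, Poisson
    scale 100, with the kernel width ``epsilon`` varied between 0.1 and 1.
    """

    n_cells: int = 600
    n_genes: int = 60
    epsilon: float = 0.2
    scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 2:
            raise ConfigError("n_cells and n_genes must both be >= 2")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")


@dataclass(frozen=True)
class DiscreteSimParams:
    """Parameters of the discrete-type simulator.

    Defaults are the published configuration: 3 types, 20 markers and 200
    cells per type, 6 markers shared with the next type.
    """

    n_types: int = 3
    markers_per_type: int = 20
    cells_per_type: int = 200
    shared_markers: int = 6
    epsilon: float = 0.1
    scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ConfigError("n_types must be >= 2")
        if self.markers_per_type < 1 or self.cells_per_type < 1:
            raise ConfigError("markers_per_type and cells_per_type must be positive")
        if not 0 <= self.shared_markers <= self.markers_per_type:
            raise ConfigError("shared_markers must lie in [0, markers_per_type]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError("epsilon (leaky expression) must lie in [0, 1]")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")


def _default_samples() -> tuple[tuple[str, str], ...]:
    # four biological replicates per rearing condition, as in the study design
    return tuple(
        [(f"NR{i + 1}", "NR") for i in range(4)] + [(f"DR{i + 1}", "DR") for i in range(4)]
    )


def _default_subclass_counts() -> dict[str, int]:
    return {"L23": 600, "L4": 220, "L5": 220, "L6": 220, "VLMC": 80}


def _default_layer_ranges() -> dict[str, tuple[float, float]]:
    return {
        "L23": (100.0, 310.0),
        "L4": (310.0, 450.0),
        "L5": (450.0, 700.0),
        "L6": (700.0, 1000.0),
    }


@dataclass(frozen=True)
class SpatialSectionSpec:
    """Specification of the synthetic curved cortical section.

    Coordinates are microns; ``y`` increases with depth away from the pia.
    The pial surface is ``y = polyval(pial_curve_coeffs, x)`` (highest power
    first, numpy convention, degree <= 4) over ``x_range``; cells sit at a
    planted depth along the local curve normal. ``abc_gradient_centers`` are
    the depths of the A/B/C identity-gene density peaks (strictly increasing:
    upper < middle < lower). ``v1_interval`` is the tangential extent of the
    V1-like region, marked by enrichment of an "on" marker and depletion of
    an "off" marker. Dark-reared ("DR") samples receive a planted IEG log2
    fold-change of ``ieg_logfc_dr`` and mild down-regulation of B/C identity
    genes (``identity_downreg_dr``).
    """

    pial_curve_coeffs: tuple[float, ...] = (-2.5e-9, 1.5e-5, 1.2e-2, 300.0)
    x_range: tuple[float, float] = (0.0, 6000.0)
    n_cells_per_subclass: Mapping[str, int] = field(default_factory=_default_subclass_counts)
    v1_interval: tuple[float, float] = (1500.0, 3500.0)
    layer_depth_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_layer_ranges
    )
    abc_gradient_centers: tuple[float, float, float] = (150.0, 210.0, 280.0)
    abc_gradient_width: float = 45.0
    ieg_logfc_dr: float = 2.0
    identity_downreg_dr: Mapping[str, float] = field(
        default_factory=lambda: {"B": 0.7, "C": 0.6}
    )
    samples: Sequence[tuple[str, str]] = field(default_factory=_default_samples)
    anchor_jitter_um: float = 5.0
    ectopic_anchor_fraction: float = 0.05
    qc_fail_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ConfigError("sample list must be non-empty")
        if any(cond not in ("NR", "DR") for _, cond in self.samples):
            raise ConfigError("every sample needs a condition in {'NR', 'DR'}")
        a, b, c = self.abc_gradient_centers
        if not a < b < c:
            raise ConfigError("abc_gradient_centers must be strictly increasing with depth")
        if self.v1_interval[1] <= self.v1_interval[0]:
            raise ConfigError("v1_interval must have positive width")
        if len(self.pial_curve_coeffs) > 5:
            raise ConfigError("pial curve degree must be <= 4")


@dataclass
class SimulatedTruth:
    """Ground truth planted by a simulator.

    ``cell_ranking`` / ``gene_ranking`` are the normalized rankings in
    (0, 1] (continuum simulator only); ``expected_rates`` is ``lambda_ij``
    before Poisson sampling and scaling; ``type_labels`` is present iff a
    type-structured simulator produced the data; ``planted_effects`` holds
    named ground-truth parameters (IEG log fold-change, pial curve
    coefficients, ...).
    """

    cell_ranking: np.ndarray | None = None
    gene_ranking: np.ndarray | None = None
    type_labels: pd.Series | None = None
    expected_rates: np.ndarray | None = None
    planted_effects: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# continuum & discrete simulators
# ---------------------------------------------------------------------------


def _counts_anndata(counts: np.ndarray, obs: pd.DataFrame, gene_ids: Sequence[str]) -> ad.AnnData:
    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    return adata


def simulate_continuum(params: ContinuumSimParams) -> tuple[ad.AnnData, SimulatedTruth]:
    """Draw a count matrix from the 1-D latent continuum model.

    Returns the ``(cells x genes)`` count matrix and the planted rankings and
    expected rates. Counts are ``scale * Poisson(lambda_ij)`` with
    ``lambda_ij = exp(-((p_i - p_j)/epsilon)**2)``.
    """
    rng = np.random.default_rng(params.seed)
    pi = np.arange(1, params.n_cells + 1) / params.n_cells
    pj = np.arange(1, params.n_genes + 1) / params.n_genes
    lam = np.exp(-(((pi[:, None] - pj[None, :]) / params.epsilon) ** 2))
    counts = params.scale * rng.poisson(lam)
    if float(params.scale).is_integer():
        counts = counts.astype(np.int64)
    obs = pd.DataFrame(
        {"sample": "sim0", "condition": "NR"},
        index=pd.Index([f"cell_{i:04d}" for i in range(params.n_cells)], name="cell_id"),
    )
    genes = [f"gene_{j:03d}" for j in range(params.n_genes)]
    truth = SimulatedTruth(
        cell_ranking=pi,
        gene_ranking=pj,
        expected_rates=lam,
        planted_effects={"epsilon": params.epsilon, "scale": params.scale},
    )
    return _counts_anndata(counts, obs, genes), truth


def simulate_discrete_types(params: DiscreteSimParams) -> tuple[ad.AnnData, SimulatedTruth]:
    """Draw a count matrix from the discrete-type model with leaky markers."""
    rng = np.random.default_rng(params.seed)
    n_cells = params.n_types * params.cells_per_type
    n_genes = params.n_types * params.markers_per_type
    type_names = [chr(ord("A") + t) for t in range(params.n_types)]
    cell_type = np.repeat(np.arange(params.n_types), params.cells_per_type)
    gene_type = np.repeat(np.arange(params.n_types), params.markers_per_type)

    lam = np.full((n_cells, n_genes), params.epsilon, dtype=float)
    lam[cell_type[:, None] == gene_type[None, :]] = 1.0
    # the first `shared_markers` markers of type t are also expressed in type
    # t+1 (chained sharing, no wraparound from the last type)
    for t in range(params.n_types - 1):
        shared = np.arange(
            t * params.markers_per_type, t * params.markers_per_type + params.shared_markers
        )
        lam[np.ix_(cell_type == t + 1, shared)] = 1.0

    counts = params.scale * rng.poisson(lam)
    if float(params.scale).is_integer():
        counts = counts.astype(np.int64)
    labels = pd.Series(
        [type_names[t] for t in cell_type],
        index=pd.Index([f"cell_{i:04d}" for i in range(n_cells)], name="cell_id"),
        name="type",
    )
    obs = pd.DataFrame({"sample": "sim0", "condition": "NR", "type": labels})
    genes = [f"{type_names[t]}_marker_{j:02d}" for t, j in zip(gene_type, _within_type_index(gene_type))]
    truth = SimulatedTruth(
        type_labels=labels,
        expected_rates=lam,
        planted_effects={
            "epsilon": params.epsilon,
            "scale": params.scale,
            "shared_markers": params.shared_markers,
        },
    )
    return _counts_anndata(counts, obs, genes), truth


def _within_type_index(gene_type: np.ndarray) -> np.ndarray:
    idx = np.zeros_like(gene_type)
    for t in np.unique(gene_type):
        mask = gene_type == t
        idx[mask] = np.arange(mask.sum())
    return idx


def simulate_archetype_mixture(
    n_cells: int = 600,
    n_genes: int = 60,
    seed: int = 0,
    high_rate: float = 50.0,
    base_rate: float = 5.0,
) -> tuple[ad.AnnData, SimulatedTruth]:
    """Cells as uniform-Dirichlet convex mixtures of three archetype profiles.

    Each archetype owns a third of the genes at ``high_rate`` (``base_rate``
    elsewhere); a cell's expected expression is its mixture of the three
    profiles and counts are Poisson. The point cloud in PC1-PC2 is a filled
    triangle, the positive control for the t-ratio permutation test.
    """
    if n_genes < 3:
        raise ConfigError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    profiles = np.full((3, n_genes), base_rate)
    thirds = np.array_split(np.arange(n_genes), 3)
    for k, cols in enumerate(thirds):
        profiles[k, cols] = high_rate
    weights = rng.dirichlet(np.ones(3), size=n_cells)
    lam = weights @ profiles
    counts = rng.poisson(lam).astype(np.int64)
    obs = pd.DataFrame(
        {"sample": "sim0", "condition": "NR"},
        index=pd.Index([f"cell_{i:04d}" for i in range(n_cells)], name="cell_id"),
    )
    genes = [f"gene_{j:03d}" for j in range(n_genes)]
    truth = SimulatedTruth(
        expected_rates=lam,
        planted_effects={"mixture_weights": weights, "profiles": profiles},
    )
    return _counts_anndata(counts, obs, genes), truth


# ---------------------------------------------------------------------------
# spatial cortical section
# ---------------------------------------------------------------------------

_N_IDENTITY = 15  # genes per A/B/C identity set
_N_IEG = 8
_N_BG = 10
_SUBCLASS_MARKERS = {"L23": 3, "L4": 3, "L5": 3, "L6": 3}


def _section_gene_table() -> pd.DataFrame:
    rows: list[tuple[str, str]] = [("Slc6a13", "anchor_marker")]
    for sub, n in _SUBCLASS_MARKERS.items():
        rows += [(f"{sub}_marker_{i}", f"subclass:{sub}") for i in range(n)]
    for t in "ABC":
        rows += [(f"id{t}_{i:02d}", f"identity:{t}") for i in range(_N_IDENTITY)]
    rows += [(f"ieg_{i:02d}", "ieg") for i in range(_N_IEG)]
    rows += [("Scnn1a_like", "v1_on"), ("Igfbp4_like", "v1_off")]
    rows += [(f"bg_{i:02d}", "background") for i in range(_N_BG)]
    return pd.DataFrame(rows, columns=["gene_id", "role"]).set_index("gene_id")


def _curve_normal(coeffs: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit normal of ``y = f(x)`` pointing toward increasing depth (+y)."""
    slope = np.polyval(np.polyder(coeffs), x)
    norm = np.hypot(slope, 1.0)
    return -slope / norm, 1.0 / norm


def simulate_cortical_section(
    spec: SpatialSectionSpec,
) -> tuple[ad.AnnData, pd.DataFrame, SimulatedTruth]:
    """Generate a multi-sample synthetic curved cortical section.

    Returns ``(counts, spatial_table, truth)``. ``counts`` is an AnnData with
    per-cell metadata (x_um, y_um, volume, blanks, sample, condition,
    subclass plus planted depth/tangent); ``spatial_table`` is the
    cell-location table used by the geometry module (cell_id, x_um, y_um,
    anchor_flag, sample, condition).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _section_gene_table()
    coeffs = np.asarray(spec.pial_curve_coeffs, dtype=float)
    x_lo, x_hi = spec.x_range
    tm, tl = spec.v1_interval
    centers = dict(zip("ABC", spec.abc_gradient_centers))

    sample_factor = {
        name: float(np.exp(rng.normal(0.0, 0.2))) for name, _ in spec.samples
    }

    records: list[dict] = []
    rate_rows: list[np.ndarray] = []
    gene_roles = genes["role"].to_numpy()
    n_genes = len(genes)

    def base_rates(subclass: str, depth: float, x: float, is_anchor: bool) -> np.ndarray:
        r = np.zeros(n_genes)
        in_v1 = tm <= x <= tl
        for g, role in enumerate(gene_roles):
            if role == "anchor_marker":
                r[g] = 40.0 if is_anchor else 0.05
            elif role.startswith("subclass:"):
                r[g] = 25.0 if role.split(":")[1] == subclass else 0.2
            elif role.startswith("identity:"):
                t = role.split(":")[1]
                if subclass == "L23":
                    prof = np.exp(-(((depth - centers[t]) / spec.abc_gradient_width) ** 2))
                    r[g] = 0.3 + 30.0 * prof
                else:
                    r[g] = 0.3
            elif role == "ieg":
                r[g] = 3.0
            elif role == "v1_on":
                r[g] = 20.0 if in_v1 else 4.0
            elif role == "v1_off":
                r[g] = 4.0 if in_v1 else 20.0
            else:  # background
                r[g] = 5.0
        return r

    ieg_mask = gene_roles == "ieg"
    id_masks = {t: gene_roles == f"identity:{t}" for t in "ABC"}

    true_anchor_ids: list[str] = []
    cell_counter = 0
    for sample, condition in spec.samples:
        sfac = sample_factor[sample]
        for subclass, n in spec.n_cells_per_subclass.items():
            for _ in range(n):
                cid = f"c{cell_counter:06d}"
                cell_counter += 1
                x0 = rng.uniform(x_lo, x_hi)
                if subclass == "VLMC":
                    is_ectopic = rng.uniform() < spec.ectopic_anchor_fraction
                    depth = (
                        rng.uniform(300.0, 500.0)
                        if is_ectopic
                        else abs(rng.normal(0.0, spec.anchor_jitter_um))
                    )
                    is_anchor = True
                    if not is_ectopic:
                        true_anchor_ids.append(cid)
                else:
                    lo, hi = spec.layer_depth_ranges[subclass]
                    depth = rng.uniform(lo, hi)
                    is_anchor = False
                    is_ectopic = False
                nx, ny = _curve_normal(coeffs, np.asarray(x0))
                px = x0 + depth * float(nx)
                py = np.polyval(coeffs, x0) + depth * float(ny)

                r = base_rates(subclass, depth, x0, is_anchor)
                if condition == "DR":
                    r[ieg_mask] *= 2.0**spec.ieg_logfc_dr
                    for t, fac in spec.identity_downreg_dr.items():
                        r[id_masks[t]] *= fac

                qc_fail = rng.uniform() < spec.qc_fail_fraction
                if qc_fail:
                    mode = rng.integers(3)
                    volume = (30.0, 2500.0, 300.0)[mode]
                    r = r * (0.02 if mode == 2 else 1.0)
                else:
                    volume = float(np.clip(np.exp(rng.normal(np.log(300.0), 0.35)), 60.0, 1900.0))
                # expected counts scale with cell volume and a per-sample
                # batch factor, which the normalization stage must remove
                r_eff = r * (volume / 300.0) * sfac
                blank_rate = 0.25 if qc_fail and volume == 300.0 else 0.015
                records.append(
                    dict(
                        cell_id=cid,
                        x_um=float(px),
                        y_um=float(py),
                        volume=volume,
                        sample=sample,
                        condition=condition,
                        subclass=subclass,
                        anchor_flag=is_anchor,
                        ectopic_anchor=bool(is_anchor and is_ectopic),
                        depth_true=float(depth),
                        tangent_true=float(x0),
                        qc_fail=bool(qc_fail),
                        blank_rate=blank_rate,
                    )
                )
                rate_rows.append(r_eff)

    rates = np.vstack(rate_rows)
    counts = rng.poisson(rates).astype(np.int64)
    obs = pd.DataFrame.from_records(records).set_index("cell_id")
    obs["blanks"] = rng.poisson(obs.pop("blank_rate").to_numpy() * counts.sum(axis=1))
    adata = _counts_anndata(counts, obs, genes.index)
    adata.var["role"] = genes["role"].to_numpy()

    spatial = obs.reset_index()[["cell_id", "x_um", "y_um", "anchor_flag", "sample", "condition"]]
    truth = SimulatedTruth(
        type_labels=obs["subclass"].rename("type"),
        planted_effects={
            "pial_curve_coeffs": coeffs.tolist(),
            "v1_interval": list(spec.v1_interval),
            "abc_gradient_centers": list(spec.abc_gradient_centers),
            "ieg_logfc_dr": spec.ieg_logfc_dr,
            "identity_downreg_dr": dict(spec.identity_downreg_dr),
            "true_anchor_ids": true_anchor_ids,
            "sample_factors": sample_factor,
        },
    )
    return adata, spatial, truth
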