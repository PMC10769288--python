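"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket (``matrix.mtx`` + ``genes.tsv`` +
``cells.tsv``) or a single CSV; cell metadata as CSV keyed by ``cell_id``;
simulated ground truth as JSON; gene sets as plain one-gene-per-line text
files; coordinate frames and result tables as CSV/TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import SchemaError
from .simulate import SimulatedTruth

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_counts_csv",
    "read_counts_csv",
    "write_truth_json",
    "read_gene_set",
    "write_gene_set",
    "load_gse190940",
]

_META_COLS = ["x_um", "y_um", "volume", "blanks", "sample", "condition"]


def write_counts_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as MatrixMarket plus gene/cell TSVs and a metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    scipy.io.mmwrite(outdir / "matrix.mtx", X)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "cells.tsv", index=False, header=False)
    meta = adata.obs.copy()
    meta.index.name = "cell_id"
    meta.to_csv(outdir / "cell_meta.csv")


def read_counts_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "cells.tsv", header=None)[0].astype(str)
    meta_path = indir / "cell_meta.csv"
    obs = (
        pd.read_csv(meta_path, index_col="cell_id")
        if meta_path.exists()
        else pd.DataFrame(index=cells)
    )
    obs = obs.reindex(cells)
    obs.index = pd.Index(cells, name="cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    return adata


def write_counts_csv(adata: ad.AnnData, path: str | Path) -> None:
    """Single-CSV export: cells as rows, genes as columns."""
    df = pd.DataFrame(
        np.asarray(adata.X.todense()) if sp.issparse(adata.X) else np.asarray(adata.X),
        index=adata.obs_names,
        columns=adata.var_names,
    )
    df.index.name = "cell_id"
    df.to_csv(path)


def read_counts_csv(path: str | Path, meta_path: str | Path | None = None) -> ad.AnnData:
    df = pd.read_csv(path, index_col=0)
    obs = (
        pd.read_csv(meta_path, index_col="cell_id").reindex(df.index)
        if meta_path
        else pd.DataFrame(index=df.index)
    )
    return ad.AnnData(
        X=df.to_numpy(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(df.columns, name="gene_id")),
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(truth: SimulatedTruth, path: str | Path) -> None:
    payload = {
        "cell_ranking": _jsonable(truth.cell_ranking),
        "gene_ranking": _jsonable(truth.gene_ranking),
        "type_labels": _jsonable(truth.type_labels),
        "planted_effects": _jsonable(truth.planted_effects),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_set(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def load_gse190940(path: str | Path) -> ad.AnnData:
    """Optional loader for a locally downloaded copy of the GSE190940
    snRNA-seq deposit.

    Expects either a 10x-style directory (``matrix.mtx[.gz]`` with
    ``features.tsv``/``genes.tsv`` and ``barcodes.tsv``) or a single
    dense CSV of cells x genes counts. This function performs no network
    access; the accession must already be on disk. No downstream analysis
    depends on it.
    """
    import scanpy as sc

    path = Path(path)
    if path.is_dir():
        return sc.read_10x_mtx(path)
    if path.suffix == ".csv":
        return read_counts_csv(path)
    raise SchemaError(f"unrecognized snRNA-seq deposit layout at {path}")
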