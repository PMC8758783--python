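"""Plain-text IO: MTX count bundles, GMT gene sets, edge tables.

Counts are exchanged as a directory bundle in the droplet-pipeline
convention: ``matrix.mtx`` (genes x cells, MatrixMarket), ``genes.tsv``,
``barcodes.tsv`` and a ``cells.tsv`` metadata table (barcode, line,
timepoint).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_counts",
    "read_counts",
    "write_gmt",
    "read_gmt",
    "write_edge_table",
]


def write_counts(adata: ad.AnnData, outdir: str) -> None:
    """Write an AnnData (cells x genes) as an MTX bundle (genes x cells)."""
    os.makedirs(outdir, exist_ok=True)
    X = sp.csc_matrix(adata.X).T  # genes x cells
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X, field="integer")
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    cols = [c for c in ("barcode", "line", "timepoint", "true_type")
            if c in adata.obs.columns]
    adata.obs[cols].to_csv(
        os.path.join(outdir, "cells.tsv"), sep="\t", index=False
    )


def read_counts(indir: str) -> ad.AnnData:
    """Read an MTX bundle back into AnnData (cells x genes)."""
    X = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, "matrix.mtx")).T)
    genes = pd.read_csv(
        os.path.join(indir, "genes.tsv"), sep="\t", header=None
    )[0].astype(str)
    barcodes = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    obs = pd.DataFrame(index=barcodes.to_numpy())
    cells_path = os.path.join(indir, "cells.tsv")
    if os.path.exists(cells_path):
        meta = pd.read_csv(cells_path, sep="\t", dtype=str)
        meta = meta.set_index("barcode", drop=False)
        obs = meta.loc[obs.index]
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes.to_numpy(), name="gene")),
    )
    return adata


def write_gmt(gene_sets: dict[str, list[str]], path: str,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: {line!r}")
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_edge_table(df: pd.DataFrame, path: str, dialect: str) -> None:
    """Write an edge table in the ``string`` (space-separated) or
    ``genemania`` (tab-separated) dialect."""
    if dialect == "string":
        df.to_csv(path, sep=" ", index=False)
    elif dialect == "genemania":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
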