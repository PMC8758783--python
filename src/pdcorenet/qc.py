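"""Cell and gene quality control.

Cells are optionally pre-ranked by cumulative expression, then filtered
by three robust criteria based on median absolute deviations (MAD, with
the 1.4826 normal-consistency constant):

1. detected genes  >  max(absolute floor, median - k * MAD),
2. |total counts - median|  <=  k * MAD,
3. mitochondrial count fraction  <=  median + k * MAD.

A cell failing any criterion is low quality.  Genes detected in fewer
than a minimum number of surviving cells are dropped.  Medians and MADs
are computed per dataset (line x timepoint) by default, or globally.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "QCThresholds",
    "QCResult",
    "rank_cells_cumulative",
    "mito_fraction",
    "cell_qc_filter",
    "gene_filter",
]

#: normal-consistency constant for the MAD
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class QCThresholds:
    min_genes_absolute: int = 200
    genes_mads: float = 2.0
    counts_mads: float = 2.0
    mito_mads: float = 1.5
    min_cells_per_gene: int = 10
    n_top_cells: int | None = None

    def __post_init__(self) -> None:
        for f in ("genes_mads", "counts_mads", "mito_mads"):
            if getattr(self, f) < 0:
                raise ValueError(f"invalid {f}: MAD multipliers must be >= 0")
        if self.min_genes_absolute < 0 or self.min_cells_per_gene < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class QCResult:
    """Per-cell QC metrics and pass flags; ``cells['pass']`` is the
    conjunction of the three criterion flags."""

    cells: pd.DataFrame

    @property
    def passing_barcodes(self) -> list[str]:
        return list(self.cells.index[self.cells["pass"]])


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return MAD_CONSTANT * float(np.median(np.abs(x - med)))


def rank_cells_cumulative(adata: ad.AnnData, n_top: int) -> list[str]:
    """The ``n_top`` barcodes with largest total counts.

    Ties are broken by lexicographic barcode order; the returned list
    preserves the input cell order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > adata.n_obs:
        raise ValueError(f"n_top={n_top} exceeds number of cells {adata.n_obs}")
    totals = np.asarray(_dense(adata.X).sum(axis=1)).ravel()
    barcodes = np.asarray(adata.obs_names, dtype=object)
    order = sorted(range(len(barcodes)), key=lambda i: (-totals[i], barcodes[i]))
    keep = set(order[:n_top])
    return [b for i, b in enumerate(barcodes) if i in keep]


def mito_fraction(adata: ad.AnnData, mito_genes: set[str]) -> np.ndarray:
    """Per-cell fraction of counts in mitochondrial genes (0 for
    zero-total cells by convention)."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    mask = np.asarray([g in mito_genes for g in adata.var_names])
    mito = X[:, mask].sum(axis=1) if mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1), 0.0)
    return frac


def _band(k: float, mad: float) -> float:
    # inf * 0 would be nan; an infinite multiplier means "no constraint"
    width = k * mad
    return np.inf if np.isnan(width) else width


def _criteria_block(n_genes, totals, mito, t: QCThresholds):
    med_g, mad_g = np.median(n_genes), _mad(n_genes)
    med_c, mad_c = np.median(totals), _mad(totals)
    med_m, mad_m = np.median(mito), _mad(mito)
    pass_genes = n_genes > max(
        t.min_genes_absolute, med_g - _band(t.genes_mads, mad_g)
    )
    pass_counts = np.abs(totals - med_c) <= _band(t.counts_mads, mad_c)
    pass_mito = mito <= med_m + _band(t.mito_mads, mad_m)
    return pass_genes, pass_counts, pass_mito


def cell_qc_filter(
    adata: ad.AnnData,
    mito_genes: set[str],
    thresholds: QCThresholds | None = None,
    scope: str = "per-sample",
) -> QCResult:
    """Apply the three MAD criteria to every cell.

    ``scope='per-sample'`` computes medians/MADs within each
    (line, timepoint) dataset when those obs columns exist; ``'global'``
    pools all cells.  When the MAD is zero the counts criterion
    degenerates to equality with the median.
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix: no cells to filter")
    if scope not in ("per-sample", "global"):
        raise ValueError(f"unknown scope: {scope!r}")
    unknown = set(mito_genes) - set(adata.var_names)
    if unknown:
        raise ValueError(f"mito genes not in matrix: {sorted(unknown)}")
    t = thresholds or QCThresholds()

    X = _dense(adata.X)
    n_genes = (X > 0).sum(axis=1).astype(float)
    totals = X.sum(axis=1).astype(float)
    mito = mito_fraction(adata, mito_genes)

    cells = pd.DataFrame(
        {
            "n_genes_detected": n_genes.astype(int),
            "total_counts": totals,
            "mito_fraction": mito,
        },
        index=adata.obs_names.copy(),
    )
    pg = np.zeros(adata.n_obs, bool)
    pc = np.zeros(adata.n_obs, bool)
    pm = np.zeros(adata.n_obs, bool)

    if (
        scope == "per-sample"
        and {"line", "timepoint"} <= set(adata.obs.columns)
    ):
        groups = adata.obs.groupby(
            ["line", "timepoint"], observed=True, sort=False
        ).indices.values()
    else:
        groups = [np.arange(adata.n_obs)]
    for idx in groups:
        idx = np.asarray(idx)
        a, b, c = _criteria_block(n_genes[idx], totals[idx], mito[idx], t)
        pg[idx], pc[idx], pm[idx] = a, b, c

    cells["pass_genes"] = pg
    cells["pass_counts"] = pc
    cells["pass_mito"] = pm
    cells["pass"] = pg & pc & pm
    return QCResult(cells)


def gene_filter(adata: ad.AnnData, min_cells: int = 10) -> list[str]:
    """Genes detected (nonzero) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_cells = np.asarray((_dense(adata.X) > 0).sum(axis=0)).ravel()
    return [g for g, n in zip(adata.var_names, n_cells) if n >= min_cells]
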