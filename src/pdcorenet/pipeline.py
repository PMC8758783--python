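"""High-level orchestration: counts -> QC -> normalization -> DE -> DEGs.

Thin compositions of the per-stage modules, shared by the CLI and
analysis scripts.
"""

from __future__ import annotations

import anndata as ad
import numpy as np

from . import de as de_mod
from . import normtype, qc

__all__ = ["apply_qc", "run_de", "select_all_schemes"]


def apply_qc(
    adata: ad.AnnData,
    mito_prefix: str = "MT-",
    thresholds: qc.QCThresholds | None = None,
    scope: str = "per-sample",
) -> tuple[ad.AnnData, qc.QCResult]:
    """Rank (optional), cell-filter, then gene-filter a count matrix."""
    t = thresholds or qc.QCThresholds()
    if t.n_top_cells is not None:
        keep = qc.rank_cells_cumulative(adata, t.n_top_cells)
        adata = adata[keep].copy()
    mito = {g for g in adata.var_names if g.startswith(mito_prefix)}
    result = qc.cell_qc_filter(adata, mito, t, scope=scope)
    filtered = adata[result.passing_barcodes].copy()
    genes = qc.gene_filter(filtered, t.min_cells_per_gene)
    return filtered[:, genes].copy(), result


def run_de(
    filtered: ad.AnnData,
    timepoints: list[str] | None = None,
    scale_factor: float = 1e4,
):
    """Log-normalize and test every timepoint; returns (norm, results)."""
    norm = normtype.lognormalize(filtered, scale_factor)
    if timepoints is None:
        timepoints = list(dict.fromkeys(norm.obs["timepoint"].astype(str)))
    results = {tp: de_mod.de_at_timepoint(norm, tp) for tp in timepoints}
    return norm, results


def select_all_schemes(
    results: dict,
    schemes: tuple[str, ...] = ("A", "B", "C", "D"),
    ipsc_label: str = de_mod.IPSC_LABEL,
) -> de_mod.DegSelection:
    sels = []
    for s in schemes:
        if s == "A":
            sels.append(de_mod.select_group_a(results, ipsc_label=ipsc_label))
        else:
            sels.append(
                de_mod.select_group_consistency(results, s, ipsc_label=ipsc_label)
            )
    return de_mod.union_degs(sels)
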