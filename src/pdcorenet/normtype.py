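"""Normalization, marker-module scoring, cell typing, proportions.

Counts are depth-normalized and log-transformed (natural log, pseudocount
1, scale factor 10,000), z-scaled per gene, and scored against marker
modules; each cell is assigned the module with the highest mean z-score
(argmax with an optional margin; exact ties go to "unassigned").
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "lognormalize",
    "zscale",
    "module_score",
    "score_modules",
    "assign_type",
    "type_proportions",
]

UNASSIGNED = "unassigned"


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """ln(1 + count * scale_factor / cell_total), per cell.

    Preserves within-cell rank order of genes.  A zero-total cell is an
    error (it should have been removed by QC).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"zero-total cell cannot be normalized: {bad!r}")
    out = adata.copy()
    out.X = np.log1p(X * scale_factor / totals[:, None])
    out.uns["normalization"] = {
        "scale_factor": float(scale_factor),
        "log_base": "e",
        "pseudocount": 1.0,
    }
    return out


def zscale(norm: ad.AnnData) -> ad.AnnData:
    """Per-gene centering and unit scaling; constant genes map to 0."""
    if norm.n_obs < 2:
        raise ValueError("z-scaling needs at least 2 cells")
    X = _dense(norm.X).astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    out = norm.copy()
    out.X = Z
    return out


def module_score(scaled: ad.AnnData, module: list[str]) -> np.ndarray:
    """Per-cell mean of z-scaled values over module genes present in the
    matrix; absent genes are dropped with a warning."""
    present = [g for g in module if g in scaled.var_names]
    missing = [g for g in module if g not in scaled.var_names]
    if not present:
        raise ValueError("no module gene present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} module gene(s) absent from matrix, dropped: "
            f"{missing[:5]}",
            stacklevel=2,
        )
    sub = scaled[:, present]
    return _dense(sub.X).mean(axis=1)


def score_modules(
    scaled: ad.AnnData, modules: dict[str, list[str]]
) -> pd.DataFrame:
    """Cell x module score table."""
    if not modules:
        raise ValueError("need at least one module")
    return pd.DataFrame(
        {name: module_score(scaled, genes) for name, genes in modules.items()},
        index=scaled.obs_names.copy(),
    )


def assign_type(scores: pd.DataFrame, margin: float = 0.0) -> pd.Series:
    """Argmax module label per cell; exact ties, or a top-two gap below
    ``margin``, give "unassigned"."""
    if scores.shape[1] < 1:
        raise ValueError("need at least one module")
    vals = scores.to_numpy(float)
    order = np.argsort(-vals, axis=1)
    best = vals[np.arange(len(vals)), order[:, 0]]
    labels = np.asarray(scores.columns, dtype=object)[order[:, 0]]
    if scores.shape[1] > 1:
        second = vals[np.arange(len(vals)), order[:, 1]]
        gap = best - second
        tied = (gap == 0) | (gap < margin)
        labels = np.where(tied, UNASSIGNED, labels)
    return pd.Series(labels, index=scores.index, name="cell_type")


def type_proportions(
    labels: pd.Series,
    metadata: pd.DataFrame,
    timepoints: list[str] | None = None,
) -> pd.DataFrame:
    """Timepoint x type fraction table; rows sum to 1 (incl. unassigned)."""
    if not labels.index.equals(metadata.index):
        missing = set(metadata.index) ^ set(labels.index)
        raise ValueError(f"labels must cover all cells; mismatch: {sorted(missing)[:5]}")
    tp = metadata["timepoint"].astype(str)
    if timepoints is not None:
        unknown = set(tp) - set(timepoints)
        if unknown:
            raise ValueError(f"unknown timepoint label(s): {sorted(unknown)}")
    tab = pd.crosstab(tp, labels.astype(str))
    frac = tab.div(tab.sum(axis=1), axis=0)
    if timepoints is not None:
        frac = frac.reindex(timepoints)
    frac.index.name = "timepoint"
    return frac
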