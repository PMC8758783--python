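"""Hurdle-model differential expression and consistency selection.

Per gene and timepoint, expression of mutant vs control cells is tested
with a two-part hurdle model in the MAST tradition:

* discrete part — logistic regression of detection (expr > 0) on the
  group indicator and the cellular detection rate (CDR, the standardized
  per-cell count of detected genes);
* continuous part — Gaussian linear model of log-normalized expression
  on group and CDR over detected cells only.

Each part contributes a 1-df likelihood-ratio statistic; the sum is
referred to a chi-square with df equal to the number of testable parts.
A part is dropped (df reduced) when degenerate: detection all-0/all-1,
fewer than 3 detected cells, or only one group detected.  avg_logFC is
the mutant-minus-control mean of log-normalized expression over ALL
cells (zero-inclusive, natural log).

Four selection schemes combine the per-timepoint results:

* A — significant (p_adj < 0.01, |FC| > 0.1) with the same FC sign at
  every included timepoint;
* B — same sign at all four timepoints, |mean FC| > 0.1,
  max p_adj < 0.01;
* C — as B over all four timepoints, but the iPSC timepoint contributes
  only |FC| to the mean-magnitude criterion (and its p_adj to the max);
  sign consistency is required only across D6/D15/D21;
* D — scheme B applied to D6/D15/D21 only.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "HurdleResult",
    "SchemeSelection",
    "DegSelection",
    "hurdle_test",
    "de_at_timepoint",
    "select_group_a",
    "select_group_consistency",
    "union_degs",
]

IPSC_LABEL = "iPSC"
PADJ_MAX = 0.01
FC_MIN = 0.1


# ---------------------------------------------------------------------------
# hurdle test


@dataclass(frozen=True)
class HurdleResult:
    p_raw: float
    avg_logFC: float
    df: int
    tested_discrete: bool
    tested_continuous: bool
    untestable: bool


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _logistic_deviance(X: np.ndarray, y: np.ndarray) -> float:
    """-2 log-likelihood at the logistic MLE, via Newton-IRLS.

    Iterations are capped; under separation the deviance plateaus near
    its infimum, which is what the likelihood ratio needs.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    for _ in range(50):
        eta = np.clip(X @ beta, -30, 30)
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)
        if not np.all(np.isfinite(beta_new)):
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < 1e-10:
            break
    mu = np.clip(_sigmoid(np.clip(X @ beta, -30, 30)), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def hurdle_test(
    expr: np.ndarray, group: np.ndarray, cdr: np.ndarray
) -> HurdleResult:
    """Two-part hurdle LRT for one gene.

    ``expr``: per-cell log-normalized values; ``group``: boolean, True
    for the mutant line; ``cdr``: per-cell covariate (finite).
    """
    expr = np.asarray(expr, float)
    group = np.asarray(group, bool)
    cdr = np.asarray(cdr, float)
    if not (group.any() and (~group).any()):
        raise ValueError("both groups must be nonempty")
    if not np.all(np.isfinite(cdr)):
        raise ValueError("cdr must be finite")

    fc = float(expr[group].mean() - expr[~group].mean())
    det = expr > 0
    stat, df = 0.0, 0
    tested_d = tested_c = False

    # discrete part: detection ~ group + cdr vs detection ~ cdr
    if det.any() and (~det).any():
        y = det.astype(float)
        X_full = np.column_stack([np.ones(len(y)), group.astype(float), cdr])
        X_null = np.column_stack([np.ones(len(y)), cdr])
        lr = _logistic_deviance(X_null, y) - _logistic_deviance(X_full, y)
        stat += max(lr, 0.0)
        df += 1
        tested_d = True

    # continuous part over detected cells
    nd = int(det.sum())
    if nd >= 3 and group[det].any() and (~group[det]).any():
        yd = expr[det]
        gd = group[det].astype(float)
        cd = cdr[det]
        X_full = np.column_stack([np.ones(nd), gd, cd])
        X_null = np.column_stack([np.ones(nd), cd])
        rss1 = _rss(X_full, yd)
        rss0 = _rss(X_null, yd)
        if rss1 <= 1e-300:
            lr = np.inf if rss0 > 1e-300 else 0.0
        else:
            lr = nd * np.log(rss0 / rss1)
        stat += max(lr, 0.0)
        df += 1
        tested_c = True

    if df == 0:
        return HurdleResult(1.0, 0.0 if not det.any() else fc, 0,
                            False, False, True)
    p = float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else 0.0
    return HurdleResult(p, fc, df, tested_d, tested_c, False)


# ---------------------------------------------------------------------------
# per-timepoint table


def de_at_timepoint(
    norm: ad.AnnData,
    timepoint: str,
    line_col: str = "line",
    control: str = "control",
    mutant: str = "mutant",
    timepoint_col: str = "timepoint",
) -> pd.DataFrame:
    """Hurdle test for every gene at one timepoint, Bonferroni-adjusted.

    The CDR covariate is the standardized per-cell number of detected
    genes.  Bonferroni m = number of genes tested at this timepoint.
    """
    mask = np.asarray(norm.obs[timepoint_col].astype(str) == str(timepoint))
    if not mask.any():
        raise ValueError(f"no cells at timepoint {timepoint!r}")
    sub = norm[mask]
    lines = np.asarray(sub.obs[line_col].astype(str))
    group = lines == mutant
    if not group.any() or not (lines == control).any():
        raise ValueError(
            f"both lines required at timepoint {timepoint!r}; "
            f"found {sorted(set(lines))}"
        )
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, float)
    det = X > 0
    cdr = det.sum(axis=1).astype(float)
    sd = cdr.std()
    cdr = (cdr - cdr.mean()) / sd if sd > 0 else np.zeros_like(cdr)

    rows = []
    for j, gene in enumerate(sub.var_names):
        r = hurdle_test(X[:, j], group, cdr)
        rows.append(
            (
                gene, timepoint, r.avg_logFC, r.p_raw, r.df, r.untestable,
                int((~group).sum()), int(group.sum()),
                float(det[~group, j].mean()), float(det[group, j].mean()),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "timepoint", "avg_logFC", "p_raw", "df", "untestable",
            "n_control", "n_mutant", "pct_control", "pct_mutant",
        ],
    ).set_index("gene")
    m = len(out)
    out.insert(3, "p_adj", np.minimum(1.0, out["p_raw"] * m))
    return out


# ---------------------------------------------------------------------------
# selection schemes


@dataclass(frozen=True)
class SchemeSelection:
    scheme: str
    genes: frozenset[str]
    signs: dict  # gene -> +1/-1
    universe: frozenset[str]


@dataclass
class DegSelection:
    groups: dict[str, frozenset[str]]
    union: frozenset[str]
    provenance: pd.DataFrame  # gene -> schemes, sign


def _aligned(results: dict[str, pd.DataFrame], tps: list[str]):
    missing = [tp for tp in tps if tp not in results]
    if missing:
        raise ValueError(f"missing timepoint table(s): {missing}")
    genes = set(results[tps[0]].index)
    for tp in tps[1:]:
        if set(results[tp].index) != genes:
            raise ValueError("timepoint tables cover different gene sets")
    order = results[tps[0]].index
    fc = np.column_stack([results[tp].loc[order, "avg_logFC"] for tp in tps])
    padj = np.column_stack([results[tp].loc[order, "p_adj"] for tp in tps])
    return order, fc, padj


def select_group_a(
    results: dict[str, pd.DataFrame],
    padj_max: float = PADJ_MAX,
    fc_min: float = FC_MIN,
    include_ipsc: bool = True,
    ipsc_label: str = IPSC_LABEL,
) -> SchemeSelection:
    """Per-timepoint significance with identical FC sign everywhere."""
    tps = [tp for tp in results if include_ipsc or tp != ipsc_label]
    if len(tps) < 2:
        raise ValueError("scheme A needs at least two timepoints")
    order, fc, padj = _aligned(results, tps)
    sig = (padj < padj_max) & (np.abs(fc) > fc_min)
    sgn = np.sign(fc)
    consistent = (np.abs(sgn.sum(axis=1)) == fc.shape[1]) & np.all(sgn != 0, axis=1)
    keep = np.all(sig, axis=1) & consistent
    genes = frozenset(order[keep])
    signs = {g: int(s) for g, s in zip(order[keep], sgn[keep, 0])}
    return SchemeSelection("A", genes, signs, frozenset(order))


def select_group_consistency(
    results: dict[str, pd.DataFrame],
    mode: str,
    padj_max: float = PADJ_MAX,
    fc_min: float = FC_MIN,
    ipsc_label: str = IPSC_LABEL,
) -> SchemeSelection:
    """Max-p / mean-FC selection: modes B, C, D (see module docstring)."""
    if mode not in ("B", "C", "D"):
        raise ValueError(f"unknown mode: {mode!r}")
    all_tps = list(results)
    non_ipsc = [tp for tp in all_tps if tp != ipsc_label]
    if mode == "C" and ipsc_label not in all_tps:
        raise ValueError(f"mode {mode} requires the {ipsc_label!r} timepoint")
    if not non_ipsc:
        raise ValueError("no non-iPSC timepoints present")

    if mode == "D":
        tps = non_ipsc
        sign_tps = non_ipsc
    else:
        tps = all_tps
        sign_tps = all_tps if mode == "B" else non_ipsc

    order, fc, padj = _aligned(results, tps)
    tp_pos = {tp: i for i, tp in enumerate(tps)}
    sgn_cols = [tp_pos[tp] for tp in sign_tps]
    sgn = np.sign(fc[:, sgn_cols])
    consistent = (np.abs(sgn.sum(axis=1)) == len(sgn_cols)) & np.all(
        sgn != 0, axis=1
    )

    if mode == "C":
        # iPSC contributes only its magnitude to the mean-FC criterion
        mag = fc.copy()
        shared = sgn[:, 0]
        i_ipsc = tp_pos[ipsc_label]
        mag[:, i_ipsc] = shared * np.abs(fc[:, i_ipsc])
        mean_fc = mag.mean(axis=1)
    else:
        mean_fc = fc.mean(axis=1)

    keep = consistent & (np.abs(mean_fc) > fc_min) & (
        padj.max(axis=1) < padj_max
    )
    genes = frozenset(order[keep])
    signs = {g: int(s) for g, s in zip(order[keep], sgn[keep, 0])}
    return SchemeSelection(mode, genes, signs, frozenset(order))


def union_degs(selections: list[SchemeSelection]) -> DegSelection:
    """Pool scheme selections into one DEG set with provenance."""
    if not selections:
        raise ValueError("no selections to pool")
    uni = selections[0].universe
    for s in selections[1:]:
        if s.universe != uni:
            raise ValueError("selections computed on different gene universes")
    groups = {s.scheme: s.genes for s in selections}
    union = frozenset().union(*groups.values())
    rows = []
    for g in sorted(union):
        schemes = [s.scheme for s in selections if g in s.genes]
        sign = next(s.signs[g] for s in selections if g in s.genes)
        rows.append((g, ",".join(schemes), sign))
    prov = pd.DataFrame(rows, columns=["gene", "schemes", "sign"]).set_index(
        "gene"
    )
    return DegSelection(groups, union, prov)
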