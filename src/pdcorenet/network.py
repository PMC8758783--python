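"""Curated DEG interaction networks, random-gene-set null, correlation
intersection, seed-gene overlay, and over-representation analysis.

Edges arrive from two database-export dialects.  STRING-like rows carry
per-channel evidence scores; indirect channels (text mining,
co-occurrence, neighborhood) are excluded.  GeneMANIA-like rows carry a
category; only genetic interactions, pathways and physical interactions
are retained.  Curation induces the subgraph on the DEG set and merges
multi-source pairs into a simple graph, so one pair counts once in all
topology metrics.  The curated network is compared against networks
built from equally sized random gene sets (excluding DEGs) via a
rank-sum test on the pooled nonzero degree distributions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import (
    GENEMANIA_RETAINED_CATEGORIES,
    STRING_CHANNELS,
)

__all__ = [
    "EDGE_COLUMNS",
    "Network",
    "NullResult",
    "OverlayResult",
    "parse_string_edges",
    "parse_genemania_edges",
    "merge_edge_sets",
    "curate_deg_network",
    "betweenness",
    "network_diameter",
    "random_network_null",
    "wilcoxon_ranksum",
    "correlation_network",
    "intersect_networks",
    "park_overlay",
    "ora_enrichment",
]

EDGE_COLUMNS = ["gene_a", "gene_b", "source", "channel", "weight"]

STRING_EXCLUDED_DEFAULT = ("textmining", "cooccurence", "neighborhood")


def _canonical_edges(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    swap = a > b
    lo = np.where(swap, b, a)
    hi = np.where(swap, a, b)
    return lo, hi


def _finish_edge_set(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize endpoints, drop self-loops, collapse duplicate
    (pair, source, channel) rows keeping the max weight."""
    if len(df) == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    lo, hi = _canonical_edges(df["gene_a"], df["gene_b"])
    out = df.copy()
    out["gene_a"], out["gene_b"] = lo, hi
    out = out[out["gene_a"] != out["gene_b"]]
    out = (
        out.groupby(["gene_a", "gene_b", "source", "channel"], as_index=False)
        ["weight"].max()
    )
    return out[EDGE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# parsers


def parse_string_edges(
    path: str,
    min_combined_score: int = 0,
    excluded_channels: tuple[str, ...] = STRING_EXCLUDED_DEFAULT,
) -> pd.DataFrame:
    """Read a STRING-like table, keeping an edge iff some non-excluded
    channel score is > 0 and combined_score >= ``min_combined_score``.

    One output row per positive retained channel (channel provenance).
    """
    df = pd.read_csv(path, sep=r"\s+")
    expected = ["protein1", "protein2", *STRING_CHANNELS, "combined_score"]
    unknown = set(df.columns) - set(expected)
    missing = set(expected) - set(df.columns)
    if unknown or missing:
        raise ValueError(
            f"unexpected STRING-like header: unknown={sorted(unknown)}, "
            f"missing={sorted(missing)}"
        )
    for col in expected[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            lineno = int(vals.index[vals.isna()][0]) + 2  # 1-based + header
            raise ValueError(f"malformed score in column {col!r} at line {lineno}")
        df[col] = vals.astype(int)
    retained = [c for c in STRING_CHANNELS if c not in excluded_channels]
    rows = []
    ok = df["combined_score"] >= min_combined_score
    for ch in retained:
        hit = ok & (df[ch] > 0)
        part = df.loc[hit, ["protein1", "protein2", ch]]
        for a, b, s in part.itertuples(index=False):
            rows.append((a, b, "string", ch, float(s)))
    return _finish_edge_set(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def _norm_category(cat: str) -> str:
    # case-insensitive with singular/plural normalization
    c = cat.strip().lower()
    if c.endswith("s"):
        c = c[:-1]
    return c


def parse_genemania_edges(
    path: str,
    allowed_categories: tuple[str, ...] = GENEMANIA_RETAINED_CATEGORIES,
) -> pd.DataFrame:
    """Read a GeneMANIA-like table, keeping only allowed categories
    (matched case-insensitively, singular/plural-insensitively)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"Gene_A", "Gene_B", "Weight", "Network_Group"}
    if set(df.columns) != expected:
        raise ValueError(
            f"unexpected GeneMANIA-like header: {list(df.columns)}"
        )
    w = pd.to_numeric(df["Weight"], errors="coerce")
    if w.isna().any():
        lineno = int(w.index[w.isna()][0]) + 2
        raise ValueError(f"malformed Weight at line {lineno}")
    allowed = {_norm_category(c): c for c in allowed_categories}
    rows = []
    for a, b, weight, cat in df[
        ["Gene_A", "Gene_B", "Weight", "Network_Group"]
    ].itertuples(index=False):
        key = _norm_category(str(cat))
        if key in allowed:
            rows.append((a, b, "genemania", allowed[key], float(weight)))
    return _finish_edge_set(pd.DataFrame(rows, columns=EDGE_COLUMNS))


def merge_edge_sets(*edge_sets: pd.DataFrame) -> pd.DataFrame:
    parts = [e for e in edge_sets if len(e)]
    if not parts:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    return _finish_edge_set(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# curation and topology


@dataclass
class Network:
    """Pair-level simple undirected graph over a DEG set.

    ``graph`` holds only connected nodes (degree >= 1); DEGs with no
    curated interaction are listed in ``disconnected``.
    """

    graph: nx.Graph
    deg_set: frozenset[str]
    disconnected: list[str] = field(default_factory=list)

    @property
    def n_connected(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph) if self.n_connected else 0

    def degrees(self, include_zero: bool = False) -> pd.Series:
        d = {n: int(k) for n, k in self.graph.degree()}
        if include_zero:
            d.update({n: 0 for n in self.disconnected})
        return pd.Series(d, dtype=int).sort_index()


def curate_deg_network(edges: pd.DataFrame, deg_set: set[str]) -> Network:
    """Induced subgraph on ``deg_set``: only DEG-DEG edges survive; a
    pair present in several sources becomes one edge with provenance."""
    if not deg_set:
        raise ValueError("deg_set must be nonempty")
    deg_set = frozenset(deg_set)
    g = nx.Graph()
    if len(edges):
        keep = edges["gene_a"].isin(deg_set) & edges["gene_b"].isin(deg_set)
        for a, b, src, ch, w in edges.loc[keep, EDGE_COLUMNS].itertuples(
            index=False
        ):
            if g.has_edge(a, b):
                g[a][b]["provenance"].add((src, ch))
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, provenance={(src, ch)}, weight=w)
    disconnected = sorted(deg_set - set(g.nodes))
    return Network(g, deg_set, disconnected)


def betweenness(net: Network) -> pd.Series:
    """Unnormalized shortest-path betweenness centrality per node."""
    bc = nx.betweenness_centrality(net.graph, normalized=False)
    return pd.Series(bc, dtype=float).sort_index()


def network_diameter(net: Network) -> int:
    """Diameter (max eccentricity) of the largest connected component."""
    if net.n_edges == 0:
        raise ValueError("diameter undefined: network has no edges")
    comp = max(nx.connected_components(net.graph), key=len)
    return int(nx.diameter(net.graph.subgraph(comp)))


# ---------------------------------------------------------------------------
# rank-sum test


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n].sum() - n * (n + 1) / 2)
    total = math.comb(n + m, n)
    center = n * m / 2.0
    dev = abs(u1 - center)
    allranks = np.arange(1, n + m + 1)
    count = 0
    for comb in itertools.combinations(range(n + m), n):
        u = allranks[list(comb)].sum() - n * (n + 1) / 2
        if abs(u - center) >= dev - 1e-12:
            count += 1
    return u1, count / total


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) with a two-sided p-value.

    Exact by enumeration when max(n, m) <= 8 and the pooled sample is
    tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == n + m
    if max(n, m) <= 8 and no_ties:
        return _exact_ranksum_p(x, y)

    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n].sum() - n * (n + 1) / 2)
    mu = n * m / 2.0
    # tie-corrected variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    N = n + m
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return u1, 1.0
    num = abs(u1 - mu) - 0.5  # continuity correction
    z = max(num, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return u1, p


# ---------------------------------------------------------------------------
# random-gene-set null


@dataclass
class NullResult:
    n_replicates: int
    node_counts: np.ndarray
    edge_counts: np.ndarray
    null_degrees: np.ndarray
    deg_degrees: np.ndarray
    statistic: float
    p_value: float
    seed: int
    include_zero_degree: bool = False


def random_network_null(
    universe: list[str],
    deg_set: set[str],
    edges: pd.DataFrame,
    n_replicates: int = 50,
    seed: int = 0,
    include_zero_degree: bool = False,
) -> NullResult:
    """Compare the DEG network against networks of random gene sets.

    Each replicate draws |deg_set| genes uniformly without replacement
    from ``universe`` excluding the DEGs, curates them against the same
    edge tables, and records node/edge counts and degrees.  The final
    rank-sum test compares the DEG network's degree distribution with
    the pooled null degrees (nonzero degrees by default).
    """
    deg_set = frozenset(deg_set)
    pool = [g for g in universe if g not in deg_set]
    k = len(deg_set)
    if len(pool) < k:
        raise ValueError(
            f"universe too small: need {k} non-DEG genes, have {len(pool)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # pair-level edge array for fast induced-subgraph counting
    if len(edges):
        pairs = edges[["gene_a", "gene_b"]].drop_duplicates()
        pa = pairs["gene_a"].to_numpy(object)
        pb = pairs["gene_b"].to_numpy(object)
    else:
        pa = pb = np.array([], dtype=object)

    def _degree_profile(geneset: frozenset[str]) -> tuple[int, int, np.ndarray]:
        inside = np.fromiter(
            ((a in geneset) and (b in geneset) for a, b in zip(pa, pb)),
            dtype=bool, count=len(pa),
        )
        deg: dict[str, int] = {}
        for a, b in zip(pa[inside], pb[inside]):
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        degs = np.array(sorted(deg.values()), dtype=float)
        if include_zero_degree:
            degs = np.concatenate([degs, np.zeros(len(geneset) - len(deg))])
        return len(deg), int(inside.sum()), degs

    _, _, deg_degrees = _degree_profile(deg_set)

    node_counts = np.empty(n_replicates, int)
    edge_counts = np.empty(n_replicates, int)
    null_parts = []
    for r in range(n_replicates):
        idx = rng.choice(len(pool), size=k, replace=False)
        rep = frozenset(pool[i] for i in idx)
        nn, ne, degs = _degree_profile(rep)
        node_counts[r] = nn
        edge_counts[r] = ne
        null_parts.append(degs)
    null_degrees = (
        np.concatenate(null_parts) if null_parts else np.array([], float)
    )

    if len(deg_degrees) == 0 or len(null_degrees) == 0:
        stat, p = float("nan"), 1.0
    else:
        stat, p = wilcoxon_ranksum(deg_degrees, null_degrees)
    return NullResult(
        n_replicates, node_counts, edge_counts, null_degrees, deg_degrees,
        stat, p, seed, include_zero_degree,
    )


# ---------------------------------------------------------------------------
# correlation network and intersection


def correlation_network(
    norm,
    deg_set: set[str],
    r_min: float = 0.1,
    p_max: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise expression-correlation edges between DEGs.

    An edge is kept iff r > ``r_min`` and the two-sided p-value
    (t-distribution, n-2 df) is < ``p_max``; no multiplicity correction.
    Constant genes are skipped with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    genes = [g for g in norm.var_names if g in deg_set]
    sub = norm[:, genes]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("correlation network needs at least 3 cells")
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        skipped = [g for g, c in zip(genes, const) if c]
        warnings.warn(
            f"{len(skipped)} constant gene(s) skipped in correlation "
            f"network: {skipped[:5]}",
            stacklevel=2,
        )
    keep = ~const
    genes = [g for g, k in zip(genes, keep) if k]
    X = X[:, keep]
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    R = np.corrcoef(X, rowvar=False)
    if R.ndim == 0:  # single gene
        R = np.array([[1.0]])
    iu, ju = np.triu_indices(len(genes), k=1)
    r = R[iu, ju]
    rr = np.clip(r, -0.9999999999, 0.9999999999)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    hit = (r > r_min) & (p < p_max)
    ga = np.asarray(genes, object)
    df = pd.DataFrame(
        {
            "gene_a": ga[iu[hit]],
            "gene_b": ga[ju[hit]],
            "source": "correlation",
            "channel": method,
            "weight": r[hit],
        }
    )
    return _finish_edge_set(df)


def intersect_networks(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pair-level intersection of two edge sets, provenance union."""
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    pairs_a = set(zip(a["gene_a"], a["gene_b"]))
    pairs_b = set(zip(b["gene_a"], b["gene_b"]))
    shared = pairs_a & pairs_b
    both = pd.concat([a, b], ignore_index=True)
    mask = [
        (ga, gb) in shared for ga, gb in zip(both["gene_a"], both["gene_b"])
    ]
    return _finish_edge_set(both.loc[mask])


# ---------------------------------------------------------------------------
# seed-gene overlay


@dataclass
class OverlayResult:
    """Seed-gene (PARK) overlay on the DEG network.

    ``seed_partners`` maps each seed gene to its DEG interaction
    partners; seed-seed edges are removed.  ``all_seeds_connected`` is
    True iff every seed gene touches at least one DEG.
    """

    edges: pd.DataFrame
    seed_partners: dict[str, list[str]]
    deg_touch_counts: pd.Series
    all_seeds_connected: bool


def park_overlay(
    all_edges: pd.DataFrame,
    deg_net: Network,
    seed_genes: list[str],
) -> OverlayResult:
    if not seed_genes:
        raise ValueError("seed_genes must be nonempty")
    seeds = set(seed_genes)
    deg_nodes = set(deg_net.deg_set)
    if len(all_edges):
        a = all_edges["gene_a"]
        b = all_edges["gene_b"]
        keep = (a.isin(seeds) & b.isin(deg_nodes - seeds)) | (
            b.isin(seeds) & a.isin(deg_nodes - seeds)
        )
        kept = all_edges.loc[keep]
    else:
        kept = all_edges
    kept = _finish_edge_set(kept) if len(kept) else pd.DataFrame(
        columns=EDGE_COLUMNS
    )
    partners: dict[str, set[str]] = {s: set() for s in seed_genes}
    touch: dict[str, set[str]] = {}
    for ga, gb in kept[["gene_a", "gene_b"]].drop_duplicates().itertuples(
        index=False
    ):
        s, d = (ga, gb) if ga in seeds else (gb, ga)
        partners[s].add(d)
        touch.setdefault(d, set()).add(s)
    seed_partners = {s: sorted(p) for s, p in partners.items()}
    deg_touch = pd.Series(
        {d: len(s) for d, s in touch.items()}, dtype=int
    ).sort_index()
    all_conn = all(len(p) > 0 for p in seed_partners.values())
    return OverlayResult(kept, seed_partners, deg_touch, all_conn)


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_enrichment(
    query: set[str],
    gene_sets: dict[str, list[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation per gene set, with
    Benjamini-Hochberg adjustment across sets."""
    if not universe:
        raise ValueError("universe must be nonempty")
    query = set(query) & set(universe)
    N = len(universe)
    n = len(query)
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & set(universe)
        K = len(gs)
        k = len(query & gs)
        if k == 0:
            fold, p = 0.0, 1.0
        else:
            fold = (k / n) / (K / N) if K and n else 0.0
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, fold, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["gene_set", "overlap", "set_size", "fold", "p"]
    ).set_index("gene_set")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out
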