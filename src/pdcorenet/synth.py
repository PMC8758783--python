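"""Synthetic data generators with known ground truth.

The pipeline downstream (QC, hurdle differential expression, consistency
selection, network curation) is exercised on data whose properties are
planted here: zero-inflated negative-binomial counts for two cell lines
(control vs mutant) across differentiation timepoints, interaction edge
tables in two database-export dialects, marker-module gene sets, and a
seed-gene list standing in for the protein-coding PARK genes.

All generators are deterministic for a fixed seed: a root
``numpy.random.SeedSequence`` is spawned into per-timepoint (or per-table)
child streams, so adding a timepoint never perturbs draws of another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "NetSimConfig",
    "TruthTable",
    "STRING_CHANNELS",
    "STRING_RETAINED_CHANNELS",
    "GENEMANIA_CATEGORIES",
    "GENEMANIA_RETAINED_CATEGORIES",
    "generate_counts",
    "generate_typed_counts",
    "generate_ppi_tables",
    "generate_marker_sets",
    "generate_seed_gene_list",
]

STRING_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)
#: evidence channels that survive curation downstream
STRING_RETAINED_CHANNELS = ("experimental", "database")

GENEMANIA_CATEGORIES = (
    "Genetic Interactions",
    "Pathways",
    "Physical Interactions",
    "Co-expression",
    "Predicted",
    "Shared protein domains",
    "Co-localization",
)
GENEMANIA_RETAINED_CATEGORIES = (
    "Genetic Interactions",
    "Pathways",
    "Physical Interactions",
)


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {fieldname}: {msg}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the count-matrix generator.

    Parameters mirror a two-line (control vs mutant) differentiation
    time-course: per gene a baseline natural-log mean is drawn uniformly
    from ``baseline_log_mean_range``; detection follows a Bernoulli whose
    logit is linear in the log mean (the hurdle the downstream test
    assumes); detected counts are negative binomial with size
    ``dispersion``.  ``n_true_deg`` genes get a log-mean shift of
    ``effect_size`` in the mutant with the same sign at every timepoint;
    sign-flip decoys (controlled by ``frac_inconsistent``) flip the sign
    at exactly one timepoint so consistency selection has something
    nontrivial to reject.
    """

    n_genes: int = 500
    n_cells_per_group_per_timepoint: int = 200
    timepoints: tuple[str, ...] = ("iPSC", "D6", "D15", "D21")
    baseline_log_mean_range: tuple[float, float] = (0.0, 2.0)
    dispersion: float = 2.0
    dropout_logit_slope: float = 1.0
    dropout_logit_intercept: float = 0.0
    n_true_deg: int = 50
    effect_size: float = 0.8
    frac_inconsistent: float = 0.2
    mito_gene_frac: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(
            self.n_cells_per_group_per_timepoint >= 1,
            "n_cells_per_group_per_timepoint",
            "must be >= 1",
        )
        _require(len(self.timepoints) >= 1, "timepoints", "must be nonempty")
        _require(
            len(set(self.timepoints)) == len(self.timepoints),
            "timepoints",
            "labels must be unique",
        )
        lo, hi = self.baseline_log_mean_range
        _require(np.isfinite(lo) and np.isfinite(hi) and lo <= hi,
                 "baseline_log_mean_range", "must be a finite interval")
        _require(self.dispersion > 0, "dispersion", "must be > 0")
        _require(np.isfinite(self.effect_size), "effect_size", "must be finite")
        _require(0 <= self.frac_inconsistent < 1, "frac_inconsistent",
                 "must be in [0, 1)")
        _require(0 <= self.mito_gene_frac <= 1, "mito_gene_frac",
                 "must be in [0, 1]")
        _require(self.n_true_deg >= 0, "n_true_deg", "must be >= 0")
        n_decoy = self.n_decoy
        _require(
            self.n_true_deg + n_decoy + self.n_mito <= self.n_genes,
            "n_true_deg",
            "true DEGs + decoys + mito genes exceed n_genes",
        )
        if n_decoy > 0:
            _require(len(self.timepoints) >= 2, "frac_inconsistent",
                     "decoys need at least two timepoints")

    @property
    def n_decoy(self) -> int:
        # decoys / (true + decoys) == frac_inconsistent
        f = self.frac_inconsistent
        return int(round(self.n_true_deg * f / (1.0 - f)))

    @property
    def n_mito(self) -> int:
        return int(round(self.mito_gene_frac * self.n_genes))


@dataclass(frozen=True)
class NetSimConfig:
    """Conditions for synthetic interaction-table generation."""

    n_hub_genes: int = 20
    hub_degree_boost: float = 8.0
    background_edge_prob: float = 0.05
    decoy_edge_prob: float = 0.05
    string_channels: tuple[str, ...] = STRING_CHANNELS
    genemania_categories: tuple[str, ...] = GENEMANIA_CATEGORIES
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0 <= self.background_edge_prob <= 1, "background_edge_prob",
                 "must be in [0, 1]")
        _require(0 <= self.decoy_edge_prob <= 1, "decoy_edge_prob",
                 "must be in [0, 1]")
        _require(self.hub_degree_boost >= 0, "hub_degree_boost",
                 "must be >= 0")
        _require(set(self.string_channels) <= set(STRING_CHANNELS),
                 "string_channels", "unknown channel label")
        _require(set(self.genemania_categories) <= set(GENEMANIA_CATEGORIES),
                 "genemania_categories", "unknown category label")


@dataclass
class TruthTable:
    """Gene-level ground truth: a partition of the gene universe.

    ``table`` has one row per gene with columns ``label`` (one of
    ``null``, ``consistent_deg``, ``inconsistent_decoy``), ``sign``
    (+1/-1 for perturbed genes, 0 for null genes) and ``flip_timepoint``
    (decoys only: the single timepoint where the effect sign is flipped).
    """

    table: pd.DataFrame

    @property
    def consistent_degs(self) -> list[str]:
        t = self.table
        return list(t.index[t["label"] == "consistent_deg"])

    @property
    def decoys(self) -> list[str]:
        t = self.table
        return list(t.index[t["label"] == "inconsistent_decoy"])

    @property
    def null_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["label"] == "null"])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    # numpy parameterizes NB by (n, p) with mean n(1-p)/p
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(config: SimConfig) -> tuple[ad.AnnData, TruthTable]:
    """Draw a zero-inflated NB count matrix with planted condition effects.

    Returns an :class:`anndata.AnnData` (cells x genes) with ``obs``
    columns ``barcode``, ``line`` (control/mutant) and ``timepoint``, and
    a :class:`TruthTable` recording which genes carry a planted effect.
    """
    cfg = config
    n_mito = cfg.n_mito
    n_decoy = cfg.n_decoy

    gene_names = [f"MT-{i + 1}" for i in range(n_mito)] + [
        f"GENE{i + 1:04d}" for i in range(cfg.n_genes - n_mito)
    ]
    mito_mask = np.array([g.startswith("MT-") for g in gene_names])

    root = np.random.SeedSequence(cfg.seed)
    ss_genes, ss_tp_parent = root.spawn(2)
    rng_g = np.random.default_rng(ss_genes)

    lo, hi = cfg.baseline_log_mean_range
    base_logmu = rng_g.uniform(lo, hi, size=cfg.n_genes)
    # mitochondrial transcripts sit at the top of the expression range
    base_logmu[mito_mask] = hi + 0.5

    # plant effects on non-mito genes only
    non_mito_idx = np.flatnonzero(~mito_mask)
    perturbed = rng_g.choice(
        non_mito_idx, size=cfg.n_true_deg + n_decoy, replace=False
    )
    true_idx = perturbed[: cfg.n_true_deg]
    decoy_idx = perturbed[cfg.n_true_deg:]
    signs = np.zeros(cfg.n_genes)
    signs[perturbed] = rng_g.choice([-1.0, 1.0], size=perturbed.size)
    flip_tp = {}
    for gi in decoy_idx:
        flip_tp[gi] = cfg.timepoints[rng_g.integers(len(cfg.timepoints))]

    # per-gene, per-timepoint differentiation shift, shared by both lines
    tp_shift = rng_g.normal(0.0, 0.3, size=(len(cfg.timepoints), cfg.n_genes))

    n_cells = cfg.n_cells_per_group_per_timepoint
    blocks, obs_rows = [], []
    tp_children = ss_tp_parent.spawn(len(cfg.timepoints))
    for t, (tp, ss_tp) in enumerate(zip(cfg.timepoints, tp_children)):
        rng = np.random.default_rng(ss_tp)
        for line in ("control", "mutant"):
            logmu = base_logmu + tp_shift[t]
            if line == "mutant":
                eff = signs * cfg.effect_size
                for gi, ftp in flip_tp.items():
                    if ftp == tp:
                        eff[gi] = -eff[gi]
                logmu = logmu + eff
            # per-cell size factor and mito load
            size_f = rng.lognormal(0.0, 0.3, size=n_cells)
            mito_f = rng.lognormal(0.0, 0.4, size=n_cells)
            mu = np.exp(logmu)[None, :] * size_f[:, None]
            mu[:, mito_mask] *= mito_f[:, None]
            det_p = _sigmoid(
                cfg.dropout_logit_intercept
                + cfg.dropout_logit_slope * np.log(mu)
            )
            detected = rng.random(mu.shape) < det_p
            counts = _nb_counts(rng, mu, cfg.dispersion) * detected
            blocks.append(sp.csr_matrix(counts.astype(np.int64)))
            for i in range(n_cells):
                obs_rows.append((f"{tp}-{line}-{i + 1:05d}", line, tp))

    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, columns=["barcode", "line", "timepoint"])
    obs.index = obs["barcode"].to_numpy()
    var = pd.DataFrame(
        {"mito": mito_mask}, index=pd.Index(gene_names, name="gene")
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.obs["timepoint"] = pd.Categorical(
        adata.obs["timepoint"], categories=list(cfg.timepoints)
    )

    labels = np.array(["null"] * cfg.n_genes, dtype=object)
    labels[true_idx] = "consistent_deg"
    labels[decoy_idx] = "inconsistent_decoy"
    truth = pd.DataFrame(
        {
            "label": labels,
            "sign": signs.astype(int),
            "flip_timepoint": [
                flip_tp.get(i, "") for i in range(cfg.n_genes)
            ],
        },
        index=pd.Index(gene_names, name="gene"),
    )
    return adata, TruthTable(truth)


def generate_typed_counts(
    markers: dict[str, list[str]],
    universe: list[str],
    n_cells: int,
    type_probs: dict[str, float] | None = None,
    elevation: float = 1.0,
    elevation_unit: str = "log",
    timepoint: str = "D21",
    dispersion: float = 2.0,
    seed: int = 0,
) -> ad.AnnData:
    """Counts with planted cell-type structure for module-score recovery.

    Each cell is assigned a true type (multinomial over ``type_probs``,
    uniform by default); the marker genes of that type get their natural-log
    mean raised by ``elevation``.  With ``elevation_unit="sd"`` the shift
    is expressed in units of the per-gene standard deviation of
    log-normalized baseline expression, estimated from a pilot draw of the
    same generative process without any planted structure (so "1 sd" is a
    standardized effect size).  The true type is stored in
    ``obs["true_type"]``.
    """
    if not markers:
        raise ValueError("markers must be nonempty")
    for t, genes in markers.items():
        missing = set(genes) - set(universe)
        if missing:
            raise ValueError(f"marker genes not in universe for {t}: {missing}")
    types = list(markers)
    if type_probs is None:
        probs = np.full(len(types), 1.0 / len(types))
    else:
        probs = np.array([type_probs[t] for t in types], dtype=float)
        probs = probs / probs.sum()

    if elevation_unit not in ("log", "sd"):
        raise ValueError(f"unknown elevation_unit: {elevation_unit!r}")
    ss_main, ss_pilot = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss_main)
    n_genes = len(universe)
    gene_idx = {g: i for i, g in enumerate(universe)}
    base_logmu = rng.uniform(0.0, 1.5, size=n_genes)

    if elevation_unit == "sd":
        # unit-calibrate: sd of log-normalized expression in a pilot
        # draw of the same process without planted structure
        prng = np.random.default_rng(ss_pilot)
        pmu = np.exp(np.tile(base_logmu, (200, 1)))
        pdet = prng.random(pmu.shape) < _sigmoid(np.log(pmu))
        pcounts = _nb_counts(prng, pmu, dispersion) * pdet
        ptot = pcounts.sum(axis=1, keepdims=True).astype(float)
        pnorm = np.log1p(pcounts * 1e4 / np.maximum(ptot, 1.0))
        elevation = elevation * float(np.median(pnorm.std(axis=0)))

    assign = rng.choice(len(types), size=n_cells, p=probs)

    logmu = np.tile(base_logmu, (n_cells, 1))
    for ti, t in enumerate(types):
        cols = [gene_idx[g] for g in markers[t]]
        rows = np.flatnonzero(assign == ti)
        logmu[np.ix_(rows, cols)] += elevation
    mu = np.exp(logmu)
    det = rng.random(mu.shape) < _sigmoid(np.log(mu))
    counts = _nb_counts(rng, mu, dispersion) * det

    obs = pd.DataFrame(
        {
            "barcode": [f"cell-{i + 1:05d}" for i in range(n_cells)],
            "line": "control",
            "timepoint": timepoint,
            "true_type": [types[a] for a in assign],
        }
    )
    obs.index = obs["barcode"].to_numpy()
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(universe, name="gene")),
    )
    return adata


def _string_combined(scores: dict[str, int]) -> int:
    # probabilistic combination of per-channel scores, STRING-style
    p = 1.0
    for s in scores.values():
        p *= 1.0 - s / 1000.0
    return min(999, int(round((1.0 - p) * 1000)))


def generate_ppi_tables(
    config: NetSimConfig,
    universe: list[str],
    hub_genes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit STRING-like and GeneMANIA-like edge tables over ``universe``.

    Pairs touching hub genes get their edge probability multiplied by
    ``hub_degree_boost`` per hub endpoint (capped at 0.9), in the
    retained channels/categories only.  Excluded channels (textmining,
    cooccurence, neighborhood; categories outside the retained three)
    are populated independently so that curation has something to drop.
    """
    hubs = set(hub_genes)
    missing = hubs - set(universe)
    if missing:
        raise ValueError(f"hub genes outside universe: {sorted(missing)}")
    if len(set(universe)) != len(universe):
        raise ValueError("universe contains duplicate genes")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = np.asarray(universe, dtype=object)
    is_hub = np.isin(genes, list(hubs))
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    n_hub_ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    p_true = np.minimum(
        0.9,
        config.background_edge_prob * config.hub_degree_boost ** n_hub_ends,
    )
    true_edge = rng.random(iu.size) < p_true
    # route each true interaction to one or both sources
    route = rng.random(iu.size)

    string_retained = [
        c for c in STRING_RETAINED_CHANNELS if c in config.string_channels
    ]
    gm_retained = [
        c for c in GENEMANIA_RETAINED_CATEGORIES
        if c in config.genemania_categories
    ]
    string_excluded = [
        c for c in config.string_channels if c not in STRING_RETAINED_CHANNELS
    ]
    gm_excluded = [
        c for c in config.genemania_categories
        if c not in GENEMANIA_RETAINED_CATEGORIES
    ]

    string_rows: list[dict] = []
    gm_rows: list[tuple] = []
    for k in np.flatnonzero(true_edge):
        a, b = genes[iu[k]], genes[ju[k]]
        to_string = route[k] < 0.7 and string_retained
        to_gm = route[k] > 0.3 and gm_retained
        if to_string:
            ch = string_retained[rng.integers(len(string_retained))]
            scores = {c: 0 for c in STRING_CHANNELS}
            scores[ch] = int(rng.integers(400, 901))
            scores["combined_score"] = _string_combined(
                {c: scores[c] for c in STRING_CHANNELS}
            )
            string_rows.append({"protein1": a, "protein2": b, **scores})
        if to_gm:
            cat = gm_retained[rng.integers(len(gm_retained))]
            gm_rows.append((a, b, float(rng.uniform(0.05, 1.0)), cat))

    # decoy edges in excluded channels/categories
    decoy = rng.random(iu.size) < config.decoy_edge_prob
    for k in np.flatnonzero(decoy):
        a, b = genes[iu[k]], genes[ju[k]]
        if string_excluded and rng.random() < 0.5:
            ch = string_excluded[rng.integers(len(string_excluded))]
            scores = {c: 0 for c in STRING_CHANNELS}
            scores[ch] = int(rng.integers(400, 901))
            scores["combined_score"] = _string_combined(
                {c: scores[c] for c in STRING_CHANNELS}
            )
            string_rows.append({"protein1": a, "protein2": b, **scores})
        elif gm_excluded:
            cat = gm_excluded[rng.integers(len(gm_excluded))]
            gm_rows.append((a, b, float(rng.uniform(0.05, 1.0)), cat))

    string_cols = ["protein1", "protein2", *STRING_CHANNELS, "combined_score"]
    string_df = pd.DataFrame(string_rows, columns=string_cols)
    for c in string_cols[2:]:
        string_df[c] = string_df[c].astype(int) if len(string_df) else string_df[c]
    gm_df = pd.DataFrame(
        gm_rows, columns=["Gene_A", "Gene_B", "Weight", "Network_Group"]
    )
    return string_df, gm_df


def generate_marker_sets(
    cell_types: list[str],
    genes_per_set: int,
    universe: list[str],
    seed: int = 0,
) -> dict[str, list[str]]:
    """Disjoint marker-gene modules, one per cell type."""
    if not cell_types:
        raise ValueError("cell_types must be nonempty")
    need = genes_per_set * len(cell_types)
    if need > len(universe):
        raise ValueError(
            f"universe too small: need {need} genes, have {len(universe)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(len(universe), size=need, replace=False)
    out = {}
    for i, t in enumerate(cell_types):
        idx = chosen[i * genes_per_set:(i + 1) * genes_per_set]
        out[t] = [universe[j] for j in idx]
    return out


def generate_seed_gene_list(
    n: int,
    universe: list[str],
    seed: int = 0,
    deg_set: set[str] | None = None,
    overlap: str = "any",
) -> list[str]:
    """Pick ``n`` distinct seed genes (default use: 19 PARK-gene stand-ins).

    ``overlap`` controls intersection with a supplied DEG set: ``any``
    (unconstrained), ``force`` (sample from the DEG set where possible)
    or ``forbid`` (sample outside it).
    """
    if n > len(universe):
        raise ValueError(f"n={n} exceeds universe size {len(universe)}")
    if overlap not in ("any", "force", "forbid"):
        raise ValueError(f"unknown overlap mode: {overlap!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pool = list(universe)
    if deg_set is not None:
        if overlap == "forbid":
            pool = [g for g in universe if g not in deg_set]
        elif overlap == "force":
            pool = [g for g in universe if g in deg_set]
    if n > len(pool):
        raise ValueError(
            f"cannot draw {n} genes under overlap={overlap!r}: pool has {len(pool)}"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]
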