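# Methods

This note documents the models, parameter choices and numerical
decisions behind `pdcorenet`, and what the synthetic-data tests do and
do not establish about real data.

## Synthetic count model

Counts are drawn from a hurdle negative-binomial process. Per gene a
baseline natural-log mean is drawn uniformly from
`baseline_log_mean_range` (default (0, 2), i.e. mean expression between
1 and ~7.4 counts — a small panel of moderately-to-well expressed genes,
chosen so that typical cells detect comfortably more than the absolute
200-detected-genes QC floor, as they do in real droplet data where the
median genes-per-cell is far above that floor). Detection is Bernoulli
with logit `intercept + slope·log μ` (defaults 0 and 1), so
lowly expressed genes drop out more — the same detection structure the
hurdle test downstream assumes. Detected counts are negative binomial
with size `dispersion` (default 2). Per-cell depth varies by a
lognormal(0, 0.3) size factor; mitochondrial genes (3% of the panel,
`MT-` prefix, pinned near the top of the expression range plus 0.5 log
units) additionally carry a lognormal(0, 0.4) per-cell load so the mito
QC criterion has a realistic tail. Each timepoint adds a N(0, 0.3)
per-gene shift shared by both lines (differentiation dynamics that the
two-line contrast cancels out).

Condition effects: `n_true_deg` genes get a log-mean shift of
`effect_size` (default 0.8) in the mutant line with the same sign at
every timepoint. Decoys flip that sign at exactly one timepoint;
`frac_inconsistent` (default 0.2) is the fraction of perturbed genes
that are decoys, so `n_decoy = round(n_true_deg · f/(1−f))`. Decoys
exist to give the sign-consistency schemes something nontrivial to
reject. Randomness flows from one `SeedSequence` per call with
per-timepoint children, so results are bit-reproducible and adding a
timepoint does not perturb the others.

What the generator does *not* emulate: batch effects, ambient RNA,
doublets, UMI collisions, gene–gene correlation beyond the shared size
factor, and compositional feedback beyond what normalization induces.
Passing tests therefore demonstrate correctness of the pipeline's logic
and calibration under the stated model, not robustness to those
artifacts.

## Quality control

The three cell criteria use the MAD with the 1.4826 normal-consistency
constant. The detected-genes rule is applied as a *lower* bound
`n_genes > max(200, median − 2·MAD)` and the mitochondrial rule as an
*upper* bound `≤ median + 1.5·MAD`: outlier filters of this family
remove cells with too few genes and too much mitochondrial signal, and
the opposite directions would discard half of every dataset. Totals are
kept within a symmetric `± 2·MAD` band. A zero MAD degenerates the band
to equality with the median; infinite multipliers disable a criterion.
Medians and MADs are computed per dataset (line × timepoint) by default
(`scope="per-sample"`), matching filtering done separately per dataset;
a `global` scope is available. The cumulative-expression ranking cutoff
`n_top_cells` has no default — it is never applied silently. Gene
filtering (detected in ≥ 10 cells) runs after cell filtering.

## Hurdle differential expression

The two-part test realizes the MAST-style hurdle concretely:

* discrete part — logistic regression (Newton-IRLS, 50 iterations,
  probabilities clipped at |logit| 30; under separation the deviance
  plateaus, which bounds the LRT) of detection on group + CDR vs. CDR;
* continuous part — OLS of log-normalized expression on group + CDR
  over detected cells; LRT statistic `n·log(RSS₀/RSS₁)`.

CDR is the per-cell count of detected genes, standardized within the
timepoint. Parts are dropped, with the χ² df reduced accordingly, when
degenerate: all/none detected, fewer than 3 detected cells, or one group
absent among detected cells. An all-zero gene returns p = 1 flagged
untestable. `avg_logFC` is the zero-inclusive mutant−control mean of
natural-log normalized expression; a log-of-ratio-of-means form was
considered and not adopted because thresholds of the 0.1 kind are
conventionally applied on the mean-difference scale. Bonferroni m is the
number of genes tested at that timepoint (each pairwise analysis is
corrected on its own). On planted-null data (2000 genes, effect 0) the
combined p-values are uniform and type-I error at α = 0.05 sits inside
[0.03, 0.07]; with planted effects the per-timepoint mutant totals shift
slightly, so null genes in *effect-carrying* simulations absorb a small
compositional bias — a property of normalization, not of the test.

Scheme C's handling of iPSC follows its stated intent: the iPSC
timepoint contributes the magnitude of its fold change to the mean-FC
criterion and its adjusted p to the max-p criterion, but not its sign —
which is exactly how C can admit genes that B rejects. Scheme B is
defined over all timepoints present (with four timepoints that includes
iPSC); scheme D is B restricted to D6/D15/D21 and provably never reads
the iPSC table.

## Network stage

Evidence-channel curation keeps a STRING-like edge iff some non-excluded
channel is positive (excluded: textmining, cooccurence, neighborhood)
and keeps GeneMANIA-like categories matched case- and
plural-insensitively against {genetic interactions, pathways, physical
interactions}. All topology metrics operate on the pair-level simple
graph (a pair supported by both sources counts once), because merged
interaction counts are reported that way. Betweenness is unnormalized
shortest-path betweenness; the diameter is taken over the largest
connected component since curated networks are often disconnected.
Edge endpoints are canonicalized lexicographically; gene symbols are the
join key across expression and network layers.

The random-gene-set null draws `|DEG|` genes without replacement from
the universe excluding the DEGs, 50 times, and compares nonzero degree
distributions with a two-sided Wilcoxon rank-sum (exact enumeration for
tie-free samples up to size 8, otherwise normal approximation with
midrank tie and continuity corrections). Zero-degree nodes can be
included by flag; the default excludes them, matching networks reported
over their connected nodes. Calibration caveat: degrees within one
induced subgraph are positively correlated (every edge feeds two
degrees), which the rank-sum's iid assumption ignores. In the sparse
regime — random sets whose induced networks are mostly disconnected
arrays with mean degree ≲ 1, which is what random gene sets against real
interaction databases look like — the effect is negligible and the null
p-values are uniform; the calibration test and the default
`NetSimConfig` (400-gene universe, 20-gene sets, background edge
probability 0.05) operate in that regime deliberately. For dense query
sets the test grows anticonservative and the p-value should be read as a
ranking score, not a literal error rate.

The correlation network uses Pearson correlation over all retained cells
pooled across timepoints (a per-timepoint mode and Spearman are
flag-selectable), with the literal rule r > 0.1 and two-sided t-test
p < 0.05 and no multiplicity correction, as the interaction rule is a
screen rather than an inference. Constant genes are skipped with a
warning. Intersection is pair-level with provenance union, and is
commutative and idempotent. The seed-gene (PARK) overlay keeps only
seed–DEG edges, discards seed–seed edges, and reports per-seed partner
counts plus a flag for whether every seed touches the network.
Over-representation uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment across gene sets.

## Cell typing

Normalization is `ln(1 + 10⁴·count/total)`; z-scaling is per gene with
constant genes mapped to 0. A module score is the mean z-score over the
module's genes present in the matrix — the simplest score consistent
with heat-level module display; control-gene-bin scoring was considered
and deliberately omitted at this panel size. Cells take the argmax
module label, with exact ties (and optionally margins below a threshold)
labelled "unassigned". In the typed-count generator, "1 sd elevation"
is unit-calibrated: the planted log-mean shift is scaled by the median
per-gene standard deviation of log-normalized expression measured on a
pilot draw of the same process without planted structure, so the
standardized effect size is what the number says. The
proportion-recovery check uses a clearly separated mixture (2 sd), since
it tests proportion estimation rather than classification difficulty.

## Problem sizes

Defaults are desk-scale: 500-gene panels, 200 cells per line per
timepoint, 2000 genes for null calibration, 400-gene interaction
universes, 50 null replicates — sizes at which every property check
(oracle equality, calibration, planted recovery) runs in seconds on one
CPU while keeping the per-criterion statistics (e.g. ±4 standard errors
of margin on the type-I error band) meaningful.

## Known limitations

Real headline numbers of this analysis family (cell counts, group sizes,
interaction counts) depend on the deposited dataset and on specific
interaction-database versions and cannot be recomputed from synthetic
data; the package validates the *procedure*, not those numbers. The
hurdle χ² reference is asymptotic (slightly liberal below ~50 cells per
group); the null-model caveat above applies to dense query sets;
integration/clustering (scTransform, Louvain, UMAP) and live database
queries are out of scope.
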