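# Methods

This note documents the models, statistics and design choices behind
`mcdmkit`, what the synthetic generators do and do not emulate, and the
numerical conventions that make results reproducible.

## Interaction inference and MCDMs

A cell population's **expressed genes** are those whose mean
back-transformed expression `10^x − 1` (the normalized layer is
`log10(x+1)`-scaled) reaches `1e-5`; a warning flags populations outside
the 5,000–10,000-gene band recommended for interaction inference.
**Ligand activity** for a receiver is the Pearson correlation between the
ligand's regulatory-potential weights and the 0/1 DEG-membership vector
over the candidate universe (receiver expressed genes ∩ prior gene space).
Only ligands with positive, defined correlation form edges; their
**targets** are the receiver's DEGs among the ligand's `top_k = 200`
highest-potential genes (weight ties at the boundary all included, so the
result is order-independent).  DEG significance throughout is FDR < 0.05.

An **MCDM** is a directed multigraph over (organ, cell type) nodes; every
ordered sender→receiver pair is tested, autocrine self-loops included.
Nodes carry their cell count plus the expressed-gene and DEG sets, which
lets the **MO-MCDM** builder recompute cross-organ edges directly from a
list of per-organ graphs: all ordered pairs of nodes in different organs,
ligands restricted to `location = extracellular space`.  Self- and
within-organ pairs are excluded there because the multi-organ model is
defined by blood transport.  UR ranking uses (total targets over edges,
distinct receivers, UR id) as a deterministic sort key; edge-order
permutations cannot change it.

**Organ prioritization** ranks organs by the median (configurable to mean)
DEG count over bootstrap rounds (default 40 cells per group, 10 rounds),
after excluding organs with ≤ 25 quality cells.  The median was chosen as
the cross-round statistic because it is insensitive to a single degenerate
resampling round.

**Severity association**: cells are standardized to mean 0 / sd 1 over
genes within each cell; the per-cell mean of the UR's target genes is
compared across severity groups with two-sided Wilcoxon rank-sum tests,
Holm-adjusted within the family of pairwise tests.

## Enrichment statistics

`fisher_enrich` is the right-tailed Fisher exact test: the exact
hypergeometric upper tail of the 2×2 table (overlap, query-only,
target-only, neither) in an explicit background universe.  The odds ratio
is the sample OR with a 0.5 Haldane correction only when a table cell is
zero; the p-value is never corrected.  An empty query returns p = 1 by
convention with a warning.  The enrichment background is always explicit
and configurable — the default for pathway enrichment is the genes
measured in the dataset — because published results are sensitive to this
choice and engines often leave it undocumented.

Pathway significance is raw p < 0.05 (no FDR at that stage); FDR (BH) is
applied where families are well-defined: UR→program mapping, GWAS
enrichment across datasets, treatment analysis.

The **activation z score** is a consistency statistic over a pathway's
signed annotations: among pathway genes that are DEGs,
`z = (n_consistent − n_inconsistent) / sqrt(n)` where consistent means
sign(logFC) equals the annotated direction.  It is undefined (not zero)
when no signed gene overlaps the DEGs.  It is bounded by ±√n and flips
sign when all DEG signs flip.  A UR's activation z treats all its targets
as expected-up.  This is a standard open-stand-in for proprietary causal
z-scores; with user-supplied signed gene sets (GMT dialect
`SYMBOL:+1|-1`) it reproduces the directional calls the labeling rule
needs.

**Fisher's method** combines k p-values as `X² = −2 Σ ln pᵢ` against
χ²(2k); zero p-values are clamped to the smallest positive float with a
warning.  Multiplicity uses statsmodels' BH (step-up) and Holm
(step-down), both monotone and capped at 1.  `cap_degs` keeps the 5,000
lowest-FDR rows, breaking boundary ties by larger |logFC| then gene id.

`simple_de` is a deliberately plain DE stand-in (per-gene two-sided
rank-sum on the normalized layer, exact method for groups ≤ 25, BH FDR,
log2 fold change of back-transformed means with pseudocount 1).  It exists
so the pipeline is closed under its own synthetic data; it makes no claim
to match specialized single-cell DE engines.

## Connective pathway analysis

Pathways are restricted to genes differentially expressed in at least one
dataset of the group; empty restrictions drop the pathway with a warning.
Distances are 1 − Jaccard; clustering is Ward on the precomputed distance
matrix via scipy's linkage, which applies the squared-distance
Lance–Williams update (the `ward.D2` convention in R's hclust — verified
against `Rscript` on a fixture during development).  Merge ties break by
smallest leaf index; the `ProgramTree` records this.  Program cuts remove
the top k−1 merges; subprogram cuts remove the highest merges internal to
each program's subtree, so subprograms nest exactly inside programs.
Labels `P{i}` / `SP{i}.{j}` are ordered by subtree size descending.  The
default subprogram count is 10 per program, configurable per program.

The labeling rule per (pathway, group): among datasets with p < 0.05,
count activated (z > 0), inhibited (z < 0) and direction-less (z
undefined) calls; strict majority of the directional calls decides;
ties with at least one significant dataset, or only direction-less
significances, give `no_direction`; no significant dataset gives
`not_significant`.  A pathway pair of group labels is **opposing** when it
is activated↔inhibited, or significant (label ≠ not_significant) in one
group and not_significant in the other; the opposing fraction is symmetric
in the groups.

Cross-collection program comparison (`program_overlap`) tests every
cluster pair right-tailed on shared pathway ids, or on gene content when
the two collections do not share pathway names, with BH over all pairs.

## Cell typing

QC retains cells with ≥ 10,000 reads, 400–6,000 transcripts (the upper
bound flags likely droplet duplicates), ≥ 200 detected genes and < 20%
mitochondrial fraction, then genes detected in ≥ 10% of retained cells;
cells are filtered before genes, and the filter is idempotent.

The embedding is pluggable; the default is truncated SVD to 32 dimensions
of the normalized layer, deterministic given the seed.  The typing
algorithm itself — Spearman matching, monotonic regression, purity
escalation — is embedding-agnostic, which is why a linear default
suffices for testing it.

Each bulk reference profile is matched to the cell with the highest
Spearman correlation over shared genes (average ranks for ties; pairs with
a zero-variance vector are skipped with a warning; ties break to the
lowest cell index).  The reference is projected into single-cell scale by
least-squares isotonic (non-decreasing) regression of the natural log of
the matched cell's back-transformed expression on the reference values,
returning `round(exp(fitted))`.  Zeros are clipped at `eps = 1e-6` before
the log — bulk-projection inputs in the intended workflow are denoised and
strictly positive, and the clip makes the routine total.

Cells and projected references are clustered jointly (k-NN graph, k = 30,
references with unit weight) with Leiden at resolution 0.5, escalating by
0.1 (cap 5.0, a bounded deterministic search) until every cluster's purity
— the fraction of its cells sharing the modal best-matching reference
type, computed once on expression, not per resolution, with cells only in
the denominator — reaches 0.70.  All cells in a cluster take the modal
type.  Marker finding is a per-label rank-sum test against all other
cells, BH-adjusted, skipping labels with < 3 cells.

## Synthetic data: what it emulates, and what not

`generate_pathway_db` plants programs as a per-program gene core (the
within-program share) plus a globally shared block (the between-program
share) and per-pathway private genes, so pairwise gene sharing matches the
requested fractions by construction; `n_filler_genes` widens the measured
universe with pathway-free genes the way a genome-wide assay does (the
ready-made inflamed/non-inflamed scenario uses 4,500).  Genes carry ±1
activation-direction signs with 80% positive: curated signed collections
are skewed toward genes that rise under activation, and the skew keeps a
pathway's directional call stable under resampling of its DEG overlap
rather than a coin flip.

`generate_prior` seeds each ligand on a program (round-robin) and draws
80% (90% in the multi-organ and takeover scenarios) of its targets from
that program's genes, the rest from the wider universe; weights are
positive uniform; the first ⌊secreted_fraction · n⌋ ligands are
extracellular-space.  `generate_deg_tables` turns active URs into DEGs
with the UR's direction as sign, drops planted DEGs at the false-negative
rate, adds false positives at the given rate, and synthesizes p-values as
Beta(0.01, 1) truncated below 0.05 for significant rows (FDR = min(10p,
0.049)) and Uniform(0.05, 1) for optional null rows — only the ordering
and the FDR < 0.05 cut matter downstream.  `generate_expression` draws
negative-binomial counts with variance μ + αμ², cell-type mean vectors
separated on the log scale by the separation parameter on 10% of genes,
and a noiseless reference profile.  `generate_treatment_cohort` constructs
the five contrast tables so the designated takeover UR satisfies all three
criteria and every decoy fails at least one (cycling the three failure
modes), with the anchor silenced in treated responders.

Deliberately not emulated: batch effects, doublets, ambient RNA,
cross-species ortholog mapping (a single gene namespace is assumed), and
realistic p-value correlation structure.  Passing tests therefore
demonstrate that the algorithms recover the structure they are defined to
recover under calibrated noise — not that any particular biological
dataset will yield a specific pathway count or UR list, which also depends
on the pathway collection and prior network supplied.

## Scenario sizes and determinism

The ready-made scenarios run at desk scale: 2 programs × 10 pathways × 50
genes, 4,500 filler genes, 6–8 URs with 40 targets, 4 datasets per group,
4 × 100 cells × 200 genes for typing.  These sizes keep the planted
effects comfortably above their sampling noise while the full validation
suite runs in minutes.  Every generator and every stochastic algorithm
(Leiden, SVD) takes an explicit seed; rerunning any scenario or the
orchestrated pipeline with the same seed reproduces results
bit-identically, and the pipeline manifest records the parameter hash.

## Known limitations

Ligand activity uses a point-biserial Pearson correlation, not the full
regression machinery of dedicated cell-cell communication tools; receptor
expression on the receiver is not modeled.  The activation z is a
consistency score, not a causal-network propagation.  Ward on 1 − Jaccard
treats the distances as Euclidean-like, which is standard practice but a
heuristic.  The purity escalation recomputes cluster membership per
resolution but reference matches only once; with very noisy references the
two choices can differ.  `simple_de` ignores count overdispersion beyond
what ranks capture.
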