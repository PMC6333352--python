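# Methods

This note documents the models and statistics implemented in `coexprio`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic benchmark does and does not demonstrate.

## Synthetic cohorts: the one-factor block model

Expression for two groups (control, disease) is drawn from a Gaussian
one-factor block model.  Each planted module m has a per-sample latent
factor `f_m ~ N(0, 1)`; gene g of module m in sample s is

    x_gs = λ_g · f_m(s) + ε_gs,   ε_gs ~ N(0, σ²)

Background genes are pure noise.  In the exchangeable case (all λ_g equal)
the within-module correlation has the closed form `λ² / (λ² + σ²)`, which
the tests exploit: with λ = 0.9 and σ² = 1 − 0.81 the expected correlation
is exactly 0.81.

By default the loadings of a module are evenly spaced over
`[λ − spread, λ]` in sorted gene order (`loading_spread = 0.25`).  Real
co-expression modules are not exchangeable: they have hub genes that are
more strongly connected than peripheral ones, and the preservation
statistics that compare *connectivity patterns* between two networks are
only meaningful when such a gradient exists.  With perfectly exchangeable
modules the intramodular connectivity is constant in expectation, so the
correlation of connectivities between two realizations compares pure noise
and carries no signal — for intact and disrupted modules alike.  Setting
`loading_spread = 0` recovers the exchangeable model for the closed-form
tests.

One designated module has its loadings multiplied by `(1 − δ)` in the
disease group only (`δ = perturbation_strength`, default 0.9), planting a
strongly decorrelated "least preserved" disease module.  δ = 0 makes the
two groups identically distributed.

Defaults (chosen once as the study conditions of the synthetic benchmark):
300 genes, three planted modules of 60 genes (120 background), 33 samples
per group — the scale of a post-mortem brain cohort with two groups in the
mid-30s.  Modules are deliberately larger than the minimum detectable
module size M = 50: a module at exactly M is degenerate because losing a
single straggler gene at the tree cut discards it entirely, which no real
study design would tolerate (observed disease modules run to hundreds of
genes).

The PPI scaffold is a Barabási–Albert preferential-attachment graph
(scale-free degree sequence, like curated interactomes) over 450 nodes —
the 300 cohort genes plus 150 unmeasured "protein-only" nodes — with
attachment 2, plus 60 extra random edges wired inside each planted module
so module genes are also topologically adjacent.  30 seed genes are drawn
with half inside the perturbed module, emulating a GWAS-derived seed list
that is enriched in, but not confined to, the disease module.  Reference
gene sets mirror the five standard schizophrenia evidence categories (CNV,
DEG, DMG, exome, GWAS) at sizes 4/60/10/30/24 on the 300-gene universe;
only the DEG analog is constructed with planted signal (50% drawn from the
perturbed module), the others are uniform draws, mirroring a situation in
which only the expression-derived reference carries detectable overlap.

What the generator does **not** emulate: microarray probe chemistry, batch
or array effects, heavy-tailed expression distributions, correlated
background structure, and realistic interactome topology beyond the
scale-free degree law.  Passing the planted-recovery tests therefore shows
the machinery is correct and well-calibrated under the stated model, not
that any particular biological dataset will yield a clean disease module.

## Weighted co-expression networks

- **Adjacency:** unsigned, `a_ij = |Pearson cor|^β`.  The unsigned form is
  the classical default; signed variants are out of scope.
- **Soft threshold:** smallest candidate β whose connectivity distribution
  fits a power law with R² above 0.8.  The fit bins connectivities into 10
  equal-width bins and regresses log10(frequency) on log10(mean bin
  connectivity); degenerate histograms (≤ 1 occupied bin, or flat in either
  axis) score 0.  When no candidate reaches the threshold the pipeline
  falls back to β = 6, the conventional default power for unsigned
  networks; an argmax-R² fallback was rejected because on a flat noisy scan
  it picks extreme powers that annihilate the weak intra-module edges.
- **TOM:** `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  diagonal 1, clipped to [0, 1] against floating-point drift.
- **Module detection:** average-linkage clustering of `1 − TOM` with a
  static cut at `q · (maximum merge height)`; the `deepsplit` parameter is
  a preset for q (2 → 0.99).  The fraction-of-maximum-height reading was
  chosen over a quantile of the merge-height distribution because nearly
  all merges in a structured matrix are low intra-module joins and the
  height distribution's upper quantiles collapse onto the top merges.
  Clusters below the minimum size M (default 50) become `grey`; modules
  whose eigengenes correlate above `1 − merge_cut_height` (default
  cut 0.25) merge iteratively until stable.  Modules are named by size rank
  with the classical color palette.  The full adaptive hybrid tree cut is
  intentionally not reproduced; the preservation analysis downstream does
  not depend on the cut flavor.
- **Eigengenes:** first principal component of the module's standardized
  expression, unit variance, sign-aligned to positive mean correlation with
  the module's genes.  kME is the Pearson correlation of each gene with
  each module eigengene; ktotal is the within-module adjacency row sum.

## Module preservation

For each non-grey reference module, three statistics are computed on the
test network: mean off-diagonal adjacency (density), and two
connectivity-pattern agreements between reference and test restricted to
the module — the correlation of intramodular connectivities and the
correlation of the upper-triangle adjacency entries.  The null resamples
module-sized gene sets uniformly from the network P times (default 100,
seeded); `Z = (obs − mean_null) / sd_null`, `z_connectivity` is the median
of the two pattern Zs, and `Zsummary` is the mean of density and
connectivity components.  A degenerate null (sd = 0, e.g. test ≡
reference) yields a signed infinity sentinel with a warning rather than an
exception.

The agreement correlations are **Spearman**: the β-power makes adjacency
entries heavy-tailed, and at realistic sample sizes a Pearson agreement is
dominated by a few noisy large entries (intact modules scored near zero).
Rank agreement is invariant to the monotone β transform and separates
intact from perturbed modules cleanly.  Density remains the raw mean test
adjacency.

`medianRank` is the per-module median of the modules' ranks under each
*observed* statistic (rank 1 = most preserved, ties averaged), so it is
insensitive to module size in the way the Z statistics are not.  The least
preserved module — the disease-module candidate — is the one with the
highest medianRank.

Internally genes are processed in sorted order so the permutation null is
invariant to the row order of the input matrices.

## Trait screens

- **SVD screen:** principal components of the row-centred expression
  matrix, associated per trait by univariate linear model (continuous) or
  one-way ANOVA (categorical), reporting R² and p.  Constant traits report
  NaN rather than raising.
- **Module–trait association:** one fixed-effects linear model per
  (module eigengene, trait), p from the F comparison of full vs
  intercept-only model — equivalent to the likelihood-ratio/ANOVA
  comparison for nested Gaussian models.  A per-sample random effect is
  unidentifiable with one observation per sample and is deliberately not
  fitted.
- **Demographic ("Table 1") tests:** categorical traits get a chi-square on
  the condition × level contingency table; 2×2 tables use the Yates
  continuity correction in its floored per-cell form
  `max(0, |O − E| − 0.5)`, so tables whose observed counts all sit within
  half a count of expectation score exactly 0 (p = 1).  This floored form
  is deliberate: a correction that always shifts O by 0.5 toward E
  overshoots when |O − E| < 0.5 and produces spurious nonzero statistics
  for near-balanced tables.  Zero-margin levels are dropped before
  testing.  Continuous traits use Welch's t by default, Mann–Whitney as an
  option; which choice a given published table used is generally not
  recoverable from rounded summaries, so it is a configuration knob.

## Seed-based prioritization

- **Graph:** union of interaction tables; symbols uppercased, self-loops
  dropped, duplicate edges collapsed with all source tags retained.  Any
  number of source databases is accepted.
- **Concordance:** Kendall's W over the sample rankings produced by the
  path's genes, with the standard tie correction
  `W = 12 S / (m²(n³ − n) − m ΣT_i)`.  W is invariant under monotone
  per-gene transforms and lies in [0, 1]; two antithetical rankings give
  exactly 0.  Genes absent from the expression matrix reduce the judge
  count m with a warning; m < 2 scores the path 0.  The concordance
  function is pluggable.
- **Cuttings:** qualifying pairs are all unordered seed–seed pairs plus
  each seed's pairs with its own graph neighbors.  All equal-length
  shortest paths per pair are enumerated from the BFS predecessor DAG
  (cap 10,000 paths/pair with a warning; the cap bounds worst-case cost on
  dense graphs), each is scored by W under the condition's expression, and
  the best path is selected — ties broken by lexicographically smallest
  node sequence for determinism.  Unreachable pairs are skipped and
  logged.  A single mapped seed degenerates to the seed-neighbor star;
  zero mapped seeds is an error.
- **Importance:** per condition,
  `importance(g) = prox(g) · Σ_{paths ∋ g} W(path)` with
  `prox = 1 / (1 + d(g, nearest seed in the cutting))` (a bounded, monotone
  decreasing kernel; the exact form is configurable), max-normalized within
  condition.  Σ = case + control, Δ = case − control; Σ′ and Δ′ are the
  same combinations on within-condition fractional ranks in (0, 1]
  (1 = most important, ties averaged), computed over the union of both
  cuttings' genes.
- **Ranking:** the top `ceil(fraction · N)` (default 10%) of the cutting by
  the chosen score.  For Δ′ the sort key is **|Δ′|**: Δ′ measures
  differential importance between conditions, and a gene whose importance
  collapses in disease is exactly as interesting as one that surges — under
  the sign convention Δ = case − control, the genes of a module
  decorrelated in disease have strongly *negative* Δ′ and a signed
  descending sort would bury them.  The signed sort remains available
  (`signed=True`), and Σ′ always sorts on its value.  Ties break by Σ then
  symbol.
- **Seed robustness:** leave-seeds-out cross-validation — remove a fraction
  of seeds (10–40%), rerun the full method, and record the percentage
  overlap of each top-k list with the full-seed reference top-k, over
  n_sets random removals per fraction.  When a list is shorter than k the
  overlap denominator is the effective k.

## Evaluation layer

- **Combination:** set union of the least-preserved module's genes and the
  prioritizer's top list, with per-gene provenance (`both` sorts first).
- **Replication:** intersection of two datasets' lists with an upper-tail
  hypergeometric p against a stated background.
- **MSET-style overlap test:** observed `|query ∩ reference ∩ background|`
  against N uniform query-sized draws from the background (default 10,000,
  seeded), `p = (#{null ≥ obs} + 1) / (N + 1)`.  The +1 correction keeps p
  strictly positive; at N = 10,000 the difference from the raw fraction is
  immaterial.  Query genes outside the background are dropped with a
  warning; per-method backgrounds are reported explicitly (expression
  universe for the module method, cutting-gene union for the prioritizer,
  union of both for the combined list).  Note that the test inherits the
  discreteness of the overlap count: with very small sets the achievable
  type-I rate sits below the nominal level, which is why the calibration
  tests use set sizes large enough for a near-continuous null.
- **Hubs:** module hubs are genes with kME ≥ 0.90 plus genes whose ktotal
  falls in the closed [90th, 99th] percentile window (linear-interpolation
  percentiles); prioritizer hubs are ranked genes whose full-interactome
  degree falls in the same window.  The exclusion of the top percentile
  follows the convention that the extreme hubs are ubiquitously essential
  rather than disease-specific.  Modules under 10 genes degenerate to an
  empty window with a warning.

## Pipeline

The YAML-configured pipeline runs preprocess → wgcna → neri → combine →
replication → mset → hubs → robustness (optional) over one or two
datasets, with a manifest recording parameters and a SHA-256 hash of every
input and output; identical config + seed reruns are byte-identical.  All
randomness derives from the single global seed via per-stage hashes.  The
soft threshold is scanned per group and the larger chosen β is used for
both networks of a dataset.  Sample exclusion (the outlier-removal step of
typical cohort QC) is an explicit config list, not automated.

## Problem sizes

The bundled synthetic study (300 genes, 33+33 samples, 450-node PPI, 30
seeds, P = 100 preservation permutations, 10,000 MSET permutations,
robustness n_sets = 10) was sized so the complete pipeline runs in about a
minute and the full planted-recovery test battery in a few minutes on one
CPU, while every statistic retains enough signal for calibrated checks.
Robustness top-k values are scaled to the cutting size (25–100 instead of
50–200 on the full-size interactome).

## Known limitations

- The static tree cut is a simplification; highly nested module structure
  that only an adaptive cut resolves will be merged or greyed.
- The preservation Z statistics depend on sample size and module size;
  cross-study comparison of raw Zsummary values requires equal P and
  comparable n, which the pipeline enforces within a run but cannot
  enforce across runs.
- The Kendall-W path score treats a path's genes symmetrically and ignores
  edge direction/sign; anti-correlated regulation along a path lowers W
  even when biologically coherent.
- Permutation nulls resample gene sets uniformly, not degree-matched;
  strongly degree-biased queries can inflate MSET significance.
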