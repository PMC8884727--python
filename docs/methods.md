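# Methods

This note documents the models, parameters and design decisions behind
`clonotrace`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, which
knobs matter, and what the synthetic-data tests do and do not establish.

## Barcode extraction

A read is modeled as an ordered template of segments: index segments
(plate/sample indices used for demultiplexing), constant segments
(primer-derived common sequence) and exactly one barcode segment. The
extractor requires a **perfect match** on every constant segment and an
exact index-to-sample lookup; the barcode must appear verbatim in the
reference list. There is no mismatch tolerance and no use of base
qualities anywhere — this mirrors the exact-match filtering convention of
barcode amplicon pipelines, where template mismatches are a reliable sign
of sequencing error or index hopping and the barcode space (20 nt,
thousands of barcodes differing in many positions) makes rescue
unnecessary. Reads failing any stage are tallied by reason (truncated /
constant mismatch / unknown index / non-reference barcode), so
`assigned + rejected == input` is an enforced invariant. Reads matching
the template but carrying a barcode absent from the reference are counted
in the tally and otherwise unused. Indices are read from the 5′ end on
the given strand; no reverse-complement search is attempted (single-read
sequencing of a directional amplicon).

## QC cascade

Order is fixed: minimum reads → normalization → replicate consensus →
minimum barcodes → cross-run sharing correction → per-mouse assembly.

- **min_reads = 5000** (per sample, strict `< 5000` removed). Samples
  below this depth cannot support the replicate-concordance test.
- **norm_total = 10⁵**: each surviving sample is scaled so its column sums
  exactly to 10⁵; values stay fractional (no rounding).
- **Replicate consensus, r_min = 0.9**: the Pearson correlation is
  computed on normalized abundances over the **union** of barcodes
  detected in either replicate. The union (rather than the intersection,
  or all reference barcodes) is the informative choice: barcodes present
  in only one replicate are exactly the disagreement the rule is meant to
  catch, while padding with thousands of shared zeros would inflate r
  toward 1. If r < 0.9 the sample is rejected. Otherwise barcodes nonzero
  in exactly one replicate are zeroed in both and the entrywise mean is
  kept. A replicate with zero variance over the union leaves r undefined;
  such samples are rejected as degenerate rather than passed — the
  conservative reading.
- **min_barcodes = 10**: merged samples with fewer than 10 nonzero
  barcodes (after singleton zeroing) are dropped.
- **Sharing correction.** Mice of one transduction batch sequenced on
  different runs can spuriously share barcodes (index hopping, carryover).
  For each batch whose mice span several runs, the mean pairwise
  percentage of shared barcodes is computed within runs and across runs
  (pair sharing = |B_i ∩ B_j| averaged over both directions, as a
  percentage). If cross-run sharing exceeds within-run sharing, entries of
  the **cross-run-shared barcodes** falling below an abundance threshold
  are zeroed; the threshold is the smallest quantile on the grid
  (0.25, 0.5, 0.75) of the pooled nonzero abundances of the batch's
  samples that brings cross-run sharing down to the within-run level. Two
  scoping decisions are deliberate: (i) the zeroing is restricted to
  barcodes actually shared across runs — they are the artifact being
  corrected, and zeroing every low entry would erase genuine low-output
  clones; (ii) if no grid quantile equalizes the sharing, the largest is
  applied and a warning logged, because a best-effort correction beats
  silently leaving the artifact in place. A batch with no within-run pair
  is held to a baseline of zero sharing.
- **No renormalization after zeroing**: clone-matrix column sums are ≤ 10⁵
  by construction, never re-scaled. Zeroing expresses "we do not believe
  these reads", not "redistribute them".
- **Mouse exclusion**: a mouse enters the output only if *every* lineage
  sample listed for it in the sample sheet survives the cascade —
  partial clone matrices would bias classification (a clone's missing
  lineage is indistinguishable from true zero output).

The cascade is monotone (no step adds reads, barcodes or samples) and
idempotent on its own output when no zeroing occurred; on noise-free
synthetic data it reduces to the normalization.

## Bias classification

A clone's proportions over the chosen lineages (row normalized to 1) are
thresholded at *t* (default 0.10): the class is the set of lineages with
proportion **strictly above** *t*, named in the canonical order M, B, E.
Strictness at the boundary is a required tie rule; "above threshold"
membership makes exactly-10% count as *not* a member. For t ≥ 1/3 an
empty member set is possible and is reported as `unclassified` rather
than forced into a class, keeping the labeling a true partition. *t* is
restricted to (0, 0.5) — beyond 0.5 at most one lineage could ever
qualify.

Auxiliary compartments (DC, MkP) never enter the core M/B/E label: a
clone with any M/B/E output is classified on those three alone; a clone
detected **only** in the auxiliary compartment is labeled `DC-only` /
`MkP-only`. Presence in a compartment means strictly positive post-QC
abundance — the cascade already encodes the detection threshold, so no
secondary read floor is applied.

Derived summaries: class frequencies (% of classified clones), class ×
lineage contributions (a class's summed normalized output in a lineage
over the lineage total, ×100; lineages with zero total reported missing),
barycentric ternary coordinates on a unit equilateral triangle (vertices
M, B, E; point size = pre-normalization summed output), and
progenitor-overlap splits (per lineage, % produced by clones also
detected in the progenitor compartment vs not). Clones detected only in
the progenitor compartment are counted separately rather than folded into
mature-lineage totals.

## Permutation test

Per-mouse statistics are exchangeable under the null, so the test
enumerates all C(n_A+n_B, n_A) assignments of the pooled mice to groups of
the original sizes when that number is ≤ 10⁵ (it always is at cohort
scale: 5 vs 5 gives 252), computing the effect for each. Defaults and
their rationale:

- **Effect = |difference of group means|** (two-sided). A one-sided
  `mean_difference` is exposed; two-sided is the conservative default
  when direction is not pre-registered.
- **Observed grouping included** in numerator and denominator, and ties
  count toward the numerator; hence p ∈ (0, 1] and p ≥ 1/#regroupings.
  In Monte-Carlo mode the add-one rule p = (1+#{≥})/(1+n_perm) gives the
  same guarantee.
- A relative tolerance of 1e−9 guards the ≥ comparison against last-ulp
  differences when permuted sums are accumulated in a different order.
- The per-mouse statistic is supplied by the caller, decoupling the test
  from classification — the same machinery serves any class × lineage
  cell, progenitor-overlap fractions, etc.

The difference-of-means fast path is vectorized over all regroupings;
arbitrary effect callables fall back to explicit enumeration and are
verified against the fast path in tests.

## Single-cell responder arm

- **QC**: genes matching `^Gm\d`, `Rik$`, `^Rp[sl]` are discarded as
  noninformative (predicted genes, ribosomal protein genes); cells with
  fewer than `min_genes_per_cell` detected genes (default 1000, scaled
  down for the small synthetic matrices used in tests) or a mitochondrial
  read fraction (genes prefixed `mt-`) above 0.10 are removed.
  The 0.10 ceiling is a conventional choice: healthy cells of this kind
  average ~5% mitochondrial content, and doubling that marks likely
  damaged cells. Mitochondrial genes themselves are retained.
- **Normalization**: `log1p(count / cell_total × 10⁴)` — the standard
  library-size normalization; depth-invariant by construction.
- **Differential expression**: per gene, a logistic regression of group
  membership on expression, tested against the intercept-only model with
  a 1-df likelihood-ratio chi-square. The fit is a vectorized Newton/IRLS
  over all genes simultaneously with a tiny ridge (1e−6) on the slope so
  perfectly separating genes converge to a finite, highly significant
  solution instead of diverging. Prefilters (expressed in ≥10% of either
  group; |Δ of group means of log-normalized values| ≥ 0.25) and
  Bonferroni adjustment are defaults-with-flags; the DEG-count
  permutation runs observed and permuted datasets through **identical**
  settings, which is what makes its p-value exchangeable.
- **DEG-count permutation null**: group labels permuted n_perm times, DEG
  count recomputed each time, p = (1+#{null ≥ observed})/(1+n_perm); the
  smallest attainable p is 1/(n_perm+1).
- **Module score**: genes are ranked by mean expression and cut into 24
  equal-frequency bins; each signature gene draws up to 100 control genes
  uniformly without replacement from its own bin (signature genes
  excluded from control pools); the score is the per-cell mean over
  signature genes minus the mean over the pooled controls. Bin-matched
  controls remove the depth/abundance component of the raw mean, so a
  random gene set scores ~0 — verified unbiased empirically. Control
  draws are seeded; scores are deterministic per seed.
- **Composite response score** = up-module score − down-module score per
  cell.
- **Responder calling**: the threshold is the 90th percentile of the
  composite score **within the treated group**; treated cells strictly
  above it are responders, control cells never. Computing the percentile
  within the treated group (not over all cells) follows the definition of
  responders as a treated-group subpopulation; with all scores tied, no
  cell is strictly above the threshold and none is flagged.
- **Reference mapping**: the reference map stores per-gene mean/SD of the
  log-normalized reference over its top-2000-variance genes, PCA loadings
  for 10 components (deterministic full-SVD solver, component signs fixed
  so the largest-magnitude loading is positive), reference-cell PC
  coordinates, and a 2-D embedding per reference cell. The published
  embedding of a real atlas is treated as **pluggable data**, not
  recomputed — nonlinear embeddings are nondeterministic and would infect
  the test surface; for testing, the first two PCs serve as a
  deterministic stand-in. Query cells are restricted to the reference
  genes, centered/scaled by the reference statistics (genes missing from
  the query enter as 0 after scaling, i.e. at the reference mean),
  projected through the loadings, and placed at the arithmetic mean of
  the embedding coordinates of their 10 nearest reference cells
  (Euclidean distance in PC space). With k=1 and the reference itself as
  query, mapping is the identity.

## Synthetic data: what it emulates, and what it does not

**Clonal generator.** A cohort of mice per treatment group; each mouse
carries its own disjoint set of barcoded clones (default 100, matching
the ~80–120 barcodes recovered per animal in such experiments). Each
clone draws a bias class from a configurable mixture (default MBE 0.40,
ME 0.20, MB 0.20, E 0.10, M 0.05, B 0.05 — balanced clones dominating an
unperturbed cohort) and lineage-output weights from a Dirichlet around
the class profile (total concentration 50 by default; exact zeros for
non-member lineages). Relative clone sizes are lognormal (σ = 0.75).
Per mouse × lineage sample, a Poisson total at the designed depth
(default 10⁵ reads) is distributed multinomially over clones and split
into two technical replicates by binomial thinning; a beta-binomial
mixing parameter ρ (default 0) adds overdispersion so the Pearson-0.9
rule can be made to fail on demand. Contamination plants barcodes from
same-batch mice sequenced on *other* runs into a sample at 1–6 reads,
drawing donors' bottom-decile clones — matching the remedy the sharing
correction implements (zeroing low-read shared barcodes). A noise-free
mode places rounded expected counts instead of sampling, giving exact
ledger equalities for oracle tests.

**Expression generator.** Negative-binomial counts (dispersion 0.1,
lognormal gene means) for control and treated groups; a fraction
(default 0.10) of treated cells — the planted responders — has an
up-program multiplied and a down-program divided by a fold (default 3,
the "strong effect" regime). Gene names include decoys matching every QC
discard pattern and a block of `mt-` genes scaled to ~5% of reads, so the
QC filters are genuinely exercised. Optional planted QC violators (cells
with almost no detected genes, cells with runaway mitochondrial content)
are appended on request.

**Limitations.** The generators do not model PCR amplification bias,
sequencing error within reads (extraction round-trip tests use error-free
reads), barcode-sharing from library non-uniqueness, doublets, ambient
RNA, batch effects beyond run-level contamination, or the mean-variance
structure of any particular real dataset — no parameter was fit to the
study's real count distributions. Passing tests therefore establish that
the *algorithms* implement their definitions and recover planted truth
under controlled conditions, not that any particular biological dataset
will behave as cleanly.

## Problem sizes and numerical choices

End-to-end checks run at desk scale, chosen as the smallest sizes at
which the measured properties are stable: effect-recovery power uses 100
cohort pairs of 5 vs 5 mice, 60 clones/mouse, depth 3×10⁴, a planted
+30-point shift in ME-class erythroid contribution, and exhaustive
252-way permutation tests; type-I calibration uses 1000 null cohorts;
module-score null centering averages 20 random 100-gene sets (the size
scale of a DEG-derived signature; smaller sets measure the same unbiased
score with proportionally more sampling noise); the DEG-count permutation
null uses 20 runs at 200 genes, 100+100 cells, 49 permutations.
Numerical guards: IRLS step damping and ±30 clipping of logits; p-value
comparisons with 1e−9 relative tolerance; PCA sign fixing for
reproducibility; a standard-deviation floor of 1e−12 when scaling
reference genes.
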