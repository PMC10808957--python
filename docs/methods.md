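# Methods

`chromshift` implements the downstream, desk-scale statistics of a
two-condition epigenomics comparison — wild-type (WT) versus a
chromatin-perturbed knockout (KO) — covering peak-set integration
(ATAC-seq and CUT&Tag style), genomic feature annotation, coverage-density
comparison, known-motif containment, expression dynamic-range analysis,
and replication-fork-rate statistics, together with seeded generators that
produce every input with planted parameters.  This note records the model
behind each stage, the defaults and why, the numerical choices, what the
generators do and do not emulate, and the known limitations.

## Coordinate and overlap conventions

All intervals are 0-based half-open; a single base `b` is `[b, b+1)`.
GTF-lite input (1-based inclusive) is converted on read.  Chromosome names
match by exact string comparison — no `chr` aliasing.  Two intervals
overlap when they share at least `min_bp` bases on the same chromosome;
`min_bp` defaults to 1, the least-assumption criterion, and is exposed
everywhere it matters.  Under the half-open convention touching intervals
(`[0,5)`, `[5,8)`) do not overlap but do merge at `gap=0`.

## Peak-set Venn decomposition

`venn_stats` classifies each peak as condition-unique or shared and counts
shared *clusters*: connected components of the bipartite overlap graph
containing members of both sets.  With one-to-one overlaps the cluster
count, the per-set shared member counts, and the single number printed in
a two-circle Venn diagram all coincide; with many-to-many overlaps they
diverge, so the per-set member counts (`a_in_shared`, `b_in_shared`) are
retained alongside the cluster count.  The cluster count is what the
package reports as "shared" because it is the only definition that yields
one number symmetrically.

## Feature annotation

A peak is assigned exactly one category by its midpoint, in priority order
Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream > DistalIntergenic.
Using the midpoint keeps categories exclusive; whole-peak membership would
be multi-valued.  The promoter window defaults to (−2000, +500) around the
TSS in strand-oriented coordinates — a common convention, configurable,
and treated as a parameter rather than a biological claim.  Downstream
means within 3000 bp past the TES on the gene's strand.  UTR intervals are
not derivable from GTF-lite, so the UTR branches activate only when a
`GeneModel` carries explicit UTR blocks (dedicated fixtures do).  TSS
distances are signed by the anchor strand (negative = upstream) with ties
broken by smaller coordinate, then lexicographic id, so annotation is
deterministic.

Signal profiles count peak-bases per bin in a fixed window around anchors
(TSS or TES), strand-flipped so upstream is always left.  Overlapping
peaks contribute independently (per-base counting, not coverage
clamping).

## Coverage-density comparison

Per-peak densities are normalized to counts per million of the per-sample
library (CPM); the normalization method is declared, not inferred — only
"normalized" is knowable from a typical figure legend.  Comparisons
happen on `log2(density + pseudocount)` with pseudocount 1.0 by default
(guards empty peaks); the generators emit continuous, strictly positive
densities and therefore carry a 0.01 pseudocount so planted ratios are
recovered without shrinkage.

The global percent change is `100·(2^m − 1)` with `m` the mean per-peak
`log2((y+pc)/(x+pc))` — the mean of log ratios, which weights every peak
equally and is robust to peak-length composition.  The alternative
ratio-of-means estimator is exposed (`method="ratio_of_means"`) because
the two differ under heteroskedastic noise: for a planted uniform ratio
`r` with symmetric log-normal noise, the mean-of-log-ratios estimator is
unbiased for `log2 r` while the ratio of means is inflated by the noise
variance.  The OLS fit of KO on WT in log2 space reports slope, intercept
and `r`; `r²` equals the squared sample correlation of the logged vectors
by construction (asserted in tests).

## Motif analysis

PFM counts become a log2-odds PWM via
`log2(((c + pc·bg) / (N + pc)) / bg)` with pseudocount 1.0 and uniform
background.  A background pseudocount allocated proportionally to base
frequencies (`pc·bg`) keeps the uniform-PFM/uniform-background matrix
exactly zero.  Scanning scores every window on both strands; the minus
strand is scored by the reverse-complemented matrix on the forward
sequence, with positions reported in forward coordinates.  `N` bases score
zero (background-equal), which slightly favors N-containing windows over
hard-masking; synthetic genomes contain no Ns.

The hit threshold is `min + f·(max − min)` of the PWM score range with
`f = 0.8` by default — a common heuristic in the absence of per-motif
published thresholds, exposed as a parameter.  Containment counts a peak
once regardless of hit multiplicity; the condition-shift table reports
per-motif containment fractions in each condition and their difference.
Enrichment of motif-positive peaks in a foreground against a background
uses the exact hypergeometric upper tail.

The built-in motifs (`builtin_motifs()`) are *synthetic* models — sharp
28-bp consensus matrices named after the factors whose shifts this kind
of analysis tabulates (CTCF and its paralog, AP-1 family members).  They
are not measured JASPAR matrices.  Width and sharpness were chosen so a
random 200-bp peak produces a chance hit with probability below 1e-6 at
the default threshold (a 28-mer at 0.8 of the score range tolerates ≤5
mismatches; P(≥23 of 28 uniform matches) ≈ 3e-10 per window), which makes
planted containment fractions exactly recoverable.  Every recovery result
plants the consensus of the same PFM it scans with, so fidelity to real
motif databases does not enter.

## Expression dynamic range

Counts are CPM-normalized with a `log2(CPM + 1)` layer.  A gene is
*detected* in a group when CPM ≥ 1 in at least half of that group's
samples (detection rules are rarely printed; this one is declared and
configurable).

The DE classifier is deliberately simple: Welch's two-sample t test on
log2 CPM, Benjamini–Hochberg adjustment, and classification on raw
p < 0.05 with |log2FC| > 1.  It is *not* a negative-binomial GLM;
reimplementing DESeq2/edgeR is out of scope, and results on real data
will differ from those tools, mainly for low-count genes where the
normal approximation on log CPM is poorest.  The three published
threshold conventions are available as `DE_PRESETS` (raw p 0.05, raw p
0.01, FDR 0.1).  On synthetic data the classifier's contract is recovery:
≥95% of 2-log2-unit planted effects at 4 replicates per group, and a
type-I error within two points of alpha under the null.

Reference-ranked bins: detected genes are ranked by mean WT log2 CPM
(stable sort, ties by gene id) and split into K equal-count bins.  Bin
*proportions* per sample are computed, by default, by re-binning each
sample's own log2 CPM against the reference bin boundaries
(`mode="boundary"`): this is the statistic in which dynamic-range
compression appears as depleted extreme bins, because a compressed sample
has fewer genes beyond the outer boundaries of the reference scale.  The
alternative `mode="membership"` keeps reference bin membership fixed and
varies only detection; under compression it moves the bottom-bin
proportion *up* (compression lifts low genes over the detection floor),
so it cannot express the phenomenon the statistic exists to show.  Both
modes yield per-sample proportions summing to 1.

Per-quintile fold-change summaries reuse the same binning with K = 5 and
summarize KO-vs-WT log2 fold changes per quintile.  Note that CPM
normalization introduces a composition offset shared by all unaffected
genes whenever planted (or real) DE is asymmetric; tests therefore assert
the *relative* pattern across quintiles, not absolute zeros.

The within-sample variance test compares variances of log2 CPM over each
sample's detected genes with a two-sided F test, `F = var_a/var_b` with
`(n_a−1, n_b−1)` degrees of freedom.  Self-comparison gives F = 1, p = 1
exactly (the F distribution with equal dfs has median 1).

## Fork rates and rank test

Fiber track lengths in micrometers convert to kb/min as
`length × 2.59 / pulse_minutes` (stretched-fiber constant 1 μm = 2.59 kb,
20-minute pulses).  The Mann–Whitney U test uses midranks for ties; for
combined samples of at most 20 observations the two-sided p comes from
full enumeration of rank assignments (exact even under ties, since the
null U distribution is symmetric under label exchange), and above that
from the normal approximation with tie correction.  The crossover is
configurable; 20 keeps exact enumeration under ~200k assignments.

## Synthetic-data generators

Every generator is a pure function of a `SimSpec` carrying the seed;
independent substreams (`default_rng([seed, stream])`) make each product
reproducible in isolation.  Defaults are the reference conditions the
pipeline is validated against: peak totals 17,134 / 34,263 with 16,550
shared, motif planting fractions 8.49% / 31.31%, a 1.25× global density
ratio with log-normal noise (sd 0.25) over 20,000 peaks, and RNA-seq
counts with 4 replicates per group, 15,000 genes, NB dispersion 0.05
(typical bulk scale), and 2,214 up / 1,717 down planted at |log2FC| = 2.

* **Genomes** are i.i.d. uniform A/C/G/T with non-overlapping,
  strand-alternating gene models on a jittered regular pitch.  No GC
  structure, repeats, or chromatin domains are emulated — so passing
  tests say nothing about GC-bias robustness, and the uniform background
  is precisely what makes the chance-hit bound for motif scanning
  computable.
* **Peak sets** occupy disjoint slots (pitch 3× the peak length), with
  shared peaks as one-to-one pairs offset by half a peak length, so the
  planted Venn structure is exact by construction rather than
  statistical.  Promoter placement bias assigns `round(f·n)` slots onto
  gene TSSs (at most one per gene) and excludes grid slots from all
  promoter windows, so the planted promoter fraction is clean.
* **Motif planting** writes the consensus (not a PFM sample) at peak
  centers, making detection certain at any reasonable threshold; a
  sampling mode would trade that certainty for realism and is not needed
  by any recovery contract.  Exact per-set bookkeeping requires disjoint
  peak sets (`shared=0`), since a consensus written at a shared A-peak's
  center falls inside its B partner.
* **Counts** draw NB(mean, dispersion) around log-normal baselines
  (median 50 counts, log-sd 1.2).  DE labels are planted only among genes
  with baseline mean ≥ 10: a shift planted in an undetectably expressed
  gene is unrecoverable by construction and would only redefine "recovery"
  downward.  Dynamic-range compression shrinks KO log-means by γ toward
  the *library-preserving* center `c* = [lse(v) − lse(γv)]/(1−γ)` rather
  than the median: median-centered shrinkage shrinks the library, and CPM
  renormalization then shifts the whole KO profile upward, masking the
  top-decile depletion the compression is meant to produce.  The default
  is γ = 1 (no compression) so each planted effect can be studied in
  isolation; KO-only genes (silent in WT) are appended on request for
  detected-gene-count contrasts.
* **Densities** are `x ~ LogNormal(log 50, 1)` per peak with
  `y = ratio·x·e^ε`, `ε ~ N(0, sd²)` — already-normalized values with
  equal nominal library sizes, because a planted *global* ratio would be
  cancelled by per-column CPM renormalization (the real pipeline's
  library size is dominated by reads outside the changed peaks, which is
  what equal library sizes emulate).

## Problem sizes

Default test and acceptance workloads are desk-scale by design: the
full-scale Venn runs on ~52k peaks, motif recovery on 2,000 peaks per
condition over an 8 Mb genome, expression analyses on 6k–15k genes, and
brute-force oracles on ≤1,000-element random sets.  The complete test
suite runs in well under a minute on one CPU.

## Known limitations

* The DE test is a declared stand-in; external-data comparisons against
  DESeq2/edgeR outputs will disagree, most for low-count genes.
* Uniform sequence background and consensus planting make motif results
  exact but say nothing about GC-rich backgrounds or degenerate motifs.
* Annotation is midpoint-based; tools that annotate whole-peak overlap
  (multi-category) will differ near feature boundaries.
* Density ratios are per-peak; per-genomic-bin ratios (an alternative
  reading of multi-assay ratio boxplots) are not implemented.
* The printed "shared" number of a many-to-many Venn is definition-
  dependent; this package reports clusters and retains member counts, but
  other tools may print either.
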