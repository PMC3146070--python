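# Methods

This note documents the models, conventions and numerical choices
behind `mesmark`, in the order the pipeline runs.

## Coordinate and strand conventions

All internal coordinates are 0-based, half-open; converters live only
at I/O boundaries (BED/bedGraph are native; any 1-based input must be
converted on read). A gene stores `(start, end, strand)`; its TSS is
`start` on `+` and `end − 1` on `−`, and the TES is the opposite end.
This strand-awareness is what orients fragment extension, the
simulator's positional bias, and metagene windows.

## Coverage model

Single-end ChIP-seq reads are 5' ends of larger fragments, so each
mapped read is extended to the expected fragment length (default
200 bp; sonication to ~300 bp with 36-bp reads makes 200 bp a
reasonable effective fragment) in the 3' direction of its strand,
clamped at chromosome ends. Coverage is the per-base count of
overlapping extended fragments, computed with an integer
difference-array/cumulative-sum; pre-scaling arithmetic is exact, which
the mass-conservation tests rely on (Σ coverage = Σ fragment lengths).

**Median normalization.** Samples are made comparable by rescaling each
replicate so all share the same genome-wide median coverage. At
desk-scale simulation depth most bases are uncovered and the
genome-wide median is 0, which makes scaling undefined; the
normalization median is therefore the median over *covered* bases by
default, falling back to the true genome-wide median whenever at least
half the genome is covered (the regime a real experiment occupies).
Both behaviors are available (`median_mode="nonzero" | "all"`).
Scaling must precede replicate averaging; a three-state machine
(`raw → median_scaled → replicate_averaged`) enforces the order, and
averaging is the plain arithmetic mean per base.

Deliberately absent, because the quantification scheme does not use
them: duplicate removal, mappability correction, and input subtraction.

## Gene scores

A gene's score is the mean of the (scaled, averaged) track over every
base of its body — introns included, strand ignored. log10 scores are
undefined for zero-mean genes; such genes are excluded from scatter
tables with the exclusion counted, rather than imputed. An optional
pseudocount is available for users who prefer imputation, but the
default invents no data. Scores are exactly linear in the track's scale
factor, so log10 scatters are translation-equivalent under
renormalization.

"Enriched gene" calling (`classify_enriched`) is an explicit
reconstruction, not a published algorithm: a gene is called enriched
when its body mean exceeds a quantile (default 0.95) of the per-base
intergenic signal. The threshold and quantile are echoed in the output.

## Metagene profiles

Genes are aligned at a strand-aware anchor (TSS or TES) and signal is
averaged in fixed 50-bp bins across a window of 1 kb upstream / 1.5 kb
downstream of the TSS and 1.5 kb / 1 kb around the TES — 50 bins
either way. Bin *i* covers oriented offsets `[50·i, 50·(i+1))`, offset
0 at the anchor, upstream negative; on a `−`-strand gene the window is
mirrored genomically. Per-gene bin means are computed first; the
across-gene mean and a 95% CI (normal approximation, mean ± 1.96·SEM;
Student-t optional via `ci="t"`) are reported with the contributing
gene count `n`. The CI is across genes, not across replicates. The
window is anchored rather than clipped: short genes contribute all
bins; only bins extending past a chromosome end drop that gene from
that bin (its `n` decrements). With a single gene the CI half-width is
0 by convention. Profile contrasts report per-bin differences with the
pooled half-width √(h_a² + h_b²). Length-rescaled (percentile)
metagenes are out of scope — windows are fixed-bp only.

## Gene-set definitions

Tag thresholds follow SAGE-style breadth rules: expressed means ≥ 1
tag; somatic means ≥ 8 tags in at least one of muscle/nerve/gut *and*
"not expressed in germline", read strictly as germline tags < 1 (i.e.
exactly 0) — the only reading consistent with "not expressed". Raw tag
counts are used without library-size normalization. The somatic and
ubiquitous sets are disjoint by construction. External curated lists
(germline-enriched, strictly maternal) are consumed as plain gene-id
text files; the package ships only synthetic equivalents generated by
its own simulator, so published set sizes are not reproduction targets.

## Staining and qPCR statistics

Percent positive is rounded half away from zero to the nearest integer,
the only rounding rule consistent with all cells of the reference count
table bundled under `mesmark/data` (e.g. 1/40 → 2.5 → 3, 3/35 → 8.57 →
9). Wilson score intervals and two-sided Fisher exact tests are
provided as uncertainty/comparison plumbing on top of the raw counts.

Percent input is `100 · b^(−ΔCp) · (df_chip/df_input) · (f_input/100)`
with ΔCp = Cp(ChIP) − Cp(input). The trailing term is a multiplicative
fraction so that ΔCp = 0 at equal dilutions returns exactly the input
fraction — the only dimensionally consistent reading. The amplification
base defaults to `b = 2 · efficiency` with the common
`b = 1 + efficiency` convention switchable; the two agree at
efficiency 1, and a base ≤ 1 with ΔCp ≠ 0 triggers a warning as
physically implausible.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not sequencing itself: mapped 36-bp intervals only — no FASTQ, error
model, PCR duplicates or paired ends.

A sample is a mixture: with probability `background_fraction` (default
0.2) a read start is uniform over the genome; otherwise a source gene
is drawn with probability ∝ class weight × gene length, multiplied by
`x_weight_multiplier` for X-linked genes, and the fragment start is
placed in the body with a linear density — `f(u) ∝ 1 + s(1−u)` toward
the 5' end or `1 + s·u` toward the 3' end (inverse-CDF sampled),
`s = bias_strength`, u strand-oriented. Defaults, fixed once as the
study conditions: maintenance mode weights germline = ubiquitous = 1,
soma = 0, 5' bias s = 1, X multiplier 0.15; transcription-coupled mode
weights all three classes 1, 3' bias s = 1, X multiplier 0.5; pan-H3
and input are fully uniform. Effect sizes are artifact choices — the
source analyses report no quantitative effect size — picked to be
plausible for a strong chromatin mark and held fixed regardless of test
outcomes. Read strands are random (fragments sequence from either end);
truth gene assignment is the sampled source gene, not positional
overlap, so recovery tests are unambiguous.

**Gene placement.** By default each chromosome is divided into equal
slots and one gene is placed at a random offset per slot
(`placement="spaced"`), so genes never overlap. Fully uniform placement
(`placement="uniform"`) is available, but at toy-genome density it
forces pervasive overlap, which transfers signal from germline to
overlapping soma gene bodies and makes truth labels meaningless for
recovery scoring; overlap tolerance in the downstream code is tested
independently. X chromosomes can be given a germline-poor class
mixture, which is what produces the X-depletion signature under
class-weighted sampling.

Determinism: every replicate draws from its own stream derived from
`(seed, replicate index)` via `numpy.random.SeedSequence`, so outputs
are byte-identical across runs and replicates are independent but
jointly reproducible.

**What the simulator does not model** — and hence what passing recovery
tests do not show about real data: mappability and GC biases, PCR
duplicates, chromatin-accessibility background structure, antibody
efficiency differences, partial tissue composition of embryo pools, or
realistic gene-length/expression correlations. The tests demonstrate
the *pipeline* recovers planted structure, not that real embryo ChIP
would behave this cleanly.

## Problem sizes

Simulation-backed tests and the acceptance script run on a toy genome
of three 200-kb autosomes plus an X, 40 genes (1.5–4 kb) per
chromosome, two replicates of 2×10⁵ reads per sample — deep enough
(~100× mean fragment coverage) that class separation and chromosome
ratios are stable to well under the tolerances asserted, while keeping
the full suite in tens of seconds. CI calibration uses 200 repetitions
of 50 homogeneous genes with disjoint windows and iid Poisson(5)
signal; the normal-approximation CI at n = 50 genes yields empirical
coverage ≈ 94%, inside the 95% ± 3% band asserted (the t-based CI
closes most of the remaining gap at small n).

## Known limitations

* The bedGraph writer quantizes to 6 decimal places; round trips are
  exact only to 5×10⁻⁷.
* `read_bedgraph` requires intervals sorted within each chromosome (the
  package's writer always sorts); unsorted non-overlapping input is
  rejected as overlapping.
* Only BED-style read input is supported (no SAM/BAM); the pipeline
  consumes already-mapped intervals.
* The X:autosome ratio uses pooled autosome means and assumes a single
  X chromosome; genomes without an X have no defined ratio.
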