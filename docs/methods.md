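# Methods

This note documents the models and conventions implemented in `msidyn`, the
design choices made where several operationalizations were defensible, and
the scope of the synthetic data the tests rely on.

## Repeat catalog

A mononucleotide microsatellite is a maximal single-base run, called on the
plus strand. A-runs and T-runs are distinct loci sharing the `AT` group
label (a T-run is an A-run on the other strand); likewise C/G → `GC`.
Bounds default to 9–24 nt: shorter runs are too stable to be informative
and longer runs are vanishingly rare in exomes. Runs longer than the
maximum are *excluded* by default rather than truncated (`over_max_policy`
is configurable; the choice matters only for rare loci). `N` breaks runs;
soft-masked lowercase is treated as its base. Capture-region restriction
keeps loci with ≥ 1 bp overlap — partial-overlap loci are still observable
by reads, and full containment would silently drop edge loci. Coordinates
are 0-based half-open everywhere except at VCF/GTF boundaries.

## Indel ingestion and repeat assignment

Variants come from one VCF per cell plus a sample sheet
(`sample_id  genotype  vcf_path`, genotype ∈ {MMR_DEFICIENT, WILDTYPE}).
Multi-allelic records are decomposed; only length-changing alleles are
kept. Every call is left-normalized (shared-suffix trimming with leftward
reference extension, then prefix trimming to a single anchor base) so that
repeat assignment is independent of how the caller placed the indel within
a run. A blacklist BED (in the study design, a 1.8 Mb window around the
inactivated MMR locus, where the knock-out construct produces artifacts)
removes calls whose affected span intersects it.

A call becomes an *unstable-repeat event* only when its inserted or deleted
bases consist solely of the repeat's base (slippage semantics) and it
touches the run: deletions must overlap `[start, end)`; insertion points
must lie in `[start − 1, end]` (a left-normalized insertion sits on the
anchor before the run). Mixed-sequence indels overlapping a repeat count as
non-repetitive. New length = old length − size for deletions (+ for
insertions), floored at zero for deletions extending past the run — a case
that cannot arise for pure-homopolymer indels at maximal runs but is kept
for defensive completeness. If truncation policies ever allow a call to
match two repeats, the larger overlap wins, then the leftmost; multiple
events at one (repeat, cell) keep the largest |size| and are logged.

## Instability metrics

*Per-cell profile*: deletion/insertion counts at repeats and in
non-repetitive sequence, divided by catalogued repeat bp and by
(captured bp − repeat bp) respectively. Group comparisons use per-cell
values summarized as median/IQR.

*Length-stratified frequency*: f_ℓ = count_ℓ / (n_repeats_ℓ · ℓ) — the
denominator is the number of nucleotides vulnerable to slippage at that
length. Lengths absent from the catalog are reported missing, not zero.

*Shift matrix*: event counts indexed by (old length, new length); all
deletion mass lies strictly below the diagonal, insertion mass above.

*Redistribution ratio*: for each cell, the post-mutation count of loci at
each length over the reference count, on an extended range
(min − 3 … max + 3) so single steps out of the catalog window (9 → 8) stay
visible. Locus count is conserved by construction. When repeats flow to a
length with reference count zero the ratio is reported as +inf (and NaN for
0/0): the synthetic exome plants no sub-9 nt runs, so "growth at 8 nt" has
no finite denominator. After-deletion and after-insertion redistributions
are computed separately (pass a kind-filtered event table). For genotype
testing, each cell is reduced to its mean absolute deviation of the ratio
from 1 (finite lengths), and groups compared by Mann-Whitney; per-length
testing is available by filtering the long table.

*Statistics*: Mann-Whitney U uses an own exact enumeration over all
C(n+m, n) group assignments (midranks, so ties are handled) whenever both
groups have ≤ 8 values, and the normal approximation with tie and
continuity correction otherwise; p = P(|U − nm/2| ≥ |u − nm/2|). The
t-test is two-sided with pooled variance. χ² is uncorrected (no Yates), so
a balanced table gives exactly 0.

## Genic annotation and gene-level MSI

Gene models load from GTF (ensembl/UCSC attribute dialects) or BED12;
isoforms are unioned per gene, UTRs derived as exonic-minus-CDS sequence
split by strand, and the promoter spans 2000 bp upstream to 200 bp
downstream of the TSS (the common annotation-tool convention; both
distances configurable). Each repeat receives exactly one category by
precedence: intron–exon boundary (the repeat interval contains an internal
exon junction coordinate) > coding > 5′UTR > 3′UTR > promoter > intron >
intergenic. Assignment uses the full repeat interval, is deterministic
under gene-order permutation, and resolves multi-gene overlaps by category
precedence, then largest span overlap, then lexicographic gene id.

Location enrichment = pooled unstable events of a genotype per category /
catalogued repeats in that category, implemented literally (no additional
scaling to the exome-wide rate; a relative variant is a one-line division
by the global ratio). Frameshift consequence is size mod 3 for coding
events only.

Per gene × cell × kind, the MSI fraction is unstable repeats over the
gene's catalogued repeats; promoter-assigned repeats count as gene
membership by default (`include_promoter=False` to exclude). Target genes
for a kind require ≥ 1 event in ≥ 1 deficient cell and zero events in all
wildtype cells — so target rows of the gene × cell table are empty in
wildtype columns by construction. Pol II positivity is ≥ 1 bp overlap of
any peak with the gene span (promoter-only mode available). Gene length is
the genomic span of the isoform union, reported in kb. "Fraction of mutated
samples" is the share of deficient cells with ≥ 1 event of the kind in the
gene.

## Replication timing

The 16-fraction Repli-seq matrix (rows = S-phase fractions early → late,
columns = 50-kb bins) is smoothed with a 2D Gaussian (s.d. 1 in both axes,
reflect boundary) *before* column normalization, in that stated order.
Missing columns are excluded from the convolution support via normalized
convolution (smooth data ÷ smooth support weights) and restored as missing;
all-zero columns are marked missing at normalization.

Quantile timing anchors the cumulative replicated fraction at abscissa 0
with value 0 and at i/16 with the running sum after fraction i; S_q is the
first abscissa where the piecewise-linear curve reaches 100q. This places
an instantaneous first-fraction replicator at S50 = 1/32, not 0, and makes
S25 ≤ S50 ≤ S75 automatic. Sdiff = S75 − S25 is z-scored per chromosome
(sample s.d.; degenerate chromosomes get z = 0) and bins with z > 1.65 are
flagged noisy.

Feature segmentation operates on the S50 track of each contiguous
non-missing stretch; noisy bins contribute S50 context but are forced to
OTHER afterwards. With ε = 0.01 (flat-step threshold), L_ctr = 4 (minimum
plateau bins), δ = 0.02 (peak/valley prominence) and τ = chromosome median
S50: prominent local minima (plateaus ≤ 3 bins) → IZ; flat runs of
≥ L_ctr bins → CTR_EARLY/CTR_LATE by mean S50 vs τ; bins touching a steep
step (|ΔS50| > ε), including single-bin slope-sign breaks inside monotone
runs, → TTR_BREAKAGE (transitions and breakage pooled as one class);
local-maximum plateaus of ≤ 3 bins (150 kb) → TERMINATION; the rest →
OTHER. Labels are merged into segments that tile the non-missing bins
exactly. These thresholds are this package's own operationalization of the
qualitative feature definitions; they are config-exposed, and the tested
claim is recovery of planted features, not any genome-wide feature census.

Per-gene timing is the overlap-bp-weighted mean of bin S50/Sdiff over
non-missing bins (an unweighted mean over partial edge bins would bias
short genes); genes on chromosome X are excluded by default because the
Repli-seq design covers autosomes only. Correlations are Pearson r with the
two-sided t-transform p.

## Synthetic data

The generator emits every pipeline input with recorded ground truth,
deterministically per seed (one `SeedSequence`, component streams spawned
in fixed order).

*Genome*: background sequence is built from runs of 1–4 nt with consecutive
runs differing, so no accidental run reaches the 9 nt catalog floor; planted
repeats follow a length × group spectrum shaped like an exome (A/T majority,
counts decaying with length; ~1,800 loci at the default desk scale of one
5 Mb chromosome), with ≥ 2 background bases between features and flanks
differing from the run base.

*Cells*: 22 MMR-deficient + 22 wildtype cells by default. Each repeat
mutates independently per cell with probability p_del(ℓ, group, genotype) /
p_ins(...); at most one event per repeat per cell (end-point observation of
a clone, not per-division simulation). The deficient A/T deletion curve
ramps over 10–16 nt (0.03–0.125 per repeat per cell) and is 10× the
wildtype curve; insertions concentrate at 9–10 nt; G/C events concentrate
at short runs. The curve shape was designed so that expected deletion
counts decrease from 11 nt upward while the flux from 10→9 and 11→10
exceeds the outflux of 9- and 10-mers — producing the planted
redistribution direction (short classes gain, 11–16 nt lose). Steps are
single-unit with probability 0.95; the 2–3 unit tail applies to deletions
at A/T runs ≥ 16 nt only (larger losses are an A/T long-run phenomenon);
insertions are single-unit. Background indels arrive uniformly over
non-repeat positions (2 bp margins from planted repeats guarantee they can
never normalize into a catalogued run) at per-bp rates with a
genotype-dependent deletion rate and genotype-independent insertion rate.
VCFs are emitted left-normalized with anchor bases.

*Genes*: non-overlapping 2–7-exon genes with derived UTRs and promoters;
Pol II-positive genes (default 50%) get a peak at the TSS and shorter
introns (factor 0.45), planting the shorter-when-transcribed effect; an
optional coupling draws longer genes in later-replicating regions.

*Repli-seq*: a fixed 76-bin motif tiles the chromosome — early plateau,
rising transition, 2-bin termination peak, falling transition, 1-bin IZ
valley, rise onto a late plateau, descent — with plateau shoulder bins
labelled as transition in the truth (after smoothing, timing already
changes there). Per bin, mass is a discretized Gaussian over the 16
fraction centers ((i − 0.5)/16) at the planted S50 with s.d. 0.08
(0 = single-fraction mass), optional log-normal noise, and a missing-bin
fraction of 2.35% by default.

What the synthetic data does **not** emulate: single-cell amplification
artifacts (allelic dropout, chimeric reads), read-level error, calling
uncertainty, interrupted or multi-unit microsatellites, overlapping or
nested genes, and realistic chromosome-scale timing structure. Passing
tests therefore demonstrate correctness of the pipeline's bookkeeping,
statistics and recovery of planted signal under the stated generative
model — not robustness to upstream wet-lab noise, which is out of scope
(the pipeline starts at VCF).

## Problem sizes and numerics

Default desk scale — 1 × 5 Mb chromosome, ~1,800 repeats, 44 cells, 120
genes, 2,000 bins — runs the full pipeline in a few seconds; tests use a
1 Mb / 12-cell variant where study scale is not needed. Exact identities
(conservation, partition, round-trips) are asserted without tolerance;
sampled quantities use 3-SE binomial bands; convolution comparisons use
1e-8 absolute tolerance; column sums 1e-9. Degenerate inputs are defined:
empty catalogs/events yield empty tables, zero-variance chromosomes yield
z = 0, zero-denominator ratios yield missing values, and single-genotype
cohorts are rejected at validation.
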