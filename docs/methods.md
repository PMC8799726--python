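# Methods

## Overview

`splicequant` models a combined measurement of splice-form abundance at a
locus whose flanking homology prevents isoform-specific probe design: PCR
amplification of the region of interest (ROI) with internally barcoded
primers, high-throughput sequencing of the pooled amplicons, and droplet
digital PCR (ddPCR) for the one form (and the endogenous control, GUSB)
that supports a specific probe.  The two alternative exons are called M
(63 nt in the synthetic default design) and L (54 nt); splice forms are
named by inclusion pattern (`0-0`, `M-0`, `M-L`, `0-L`).

## The synthetic design and what the simulator emulates

No public sequence exists for the real assay's amplicons, so the package
ships a synthetic default design that reproduces the experiment's geometry:

* 16 internal 8-nt barcodes behind a 4-nt random quatromer on the
  reverse-primer side (the quatromer is a base-diversity spacer, not a
  UMI);
* five amplicon species whose lengths are the five synthetic calibration
  fragments of 125, 156, 210, 219 and 273 bp.  Which length belongs to
  which species is not derivable from the locus, and only one assignment
  is consistent with the exon-additivity constraint
  `len(M-L) = len(0-0) + len(M) + len(L)`: control 125, `0-0` 156, `0-L`
  210, `M-0` 219, `M-L` 273.  The design file carries this species→length
  map explicitly, so a user with the real mapping can substitute it.

The default barcode set satisfies three conditions, fixed once at design
time: pairwise edit distance ≥ 3; no barcode within edit distance 1 of any
template on either strand; and no single-substitution variant of a barcode
— including windows shifted into quatromer or amplicon context —
coinciding exactly with a different barcode.  The third condition is
stronger than pairwise distance alone and is what makes single-error
cross-assignment impossible under semi-global matching: a shifted window
borrowing one context base can otherwise reconstruct a different barcode
exactly.

The read simulator draws each pair's template from a multinomial whose
probabilities are the input proportions times a PCR amplification factor,
emits the forward read from the amplicon's 5' end and the mate as
quatromer + barcode + reverse-complemented amplicon, and applies i.i.d.
substitution errors (default 0.5%, the Illumina-like regime; an optional
indel rate exercises the fuzzy matchers).  Quality strings are constant
Q30 unless an error profile is supplied.  PCR bias is an expected-value
model — deterministic geometric amplification `(1+e)^n_cycles` (default 32
cycles) — not a stochastic branching process; the calibration stage
estimates one factor per species regardless of mechanism, so only the
induced count bias matters.  What the simulator does **not** emulate:
PCR chimeras and recombination, quality-score/error coupling, GC bias,
library-prep yield differences (handled abstractly by pool
normalisation), or polymerase indel errors under the default settings.
Passing tests therefore demonstrate correctness of the algorithms under a
clean substitution-dominated error model, not robustness to every real
sequencing artefact.

## Pipeline stages and numerical choices

**Trimming.** 3' quality trimming uses the running-sum rule (subtract the
cutoff from each quality, scan partial sums from the 3' end, cut at the
5'-most minimum when negative).  Adapter removal is an error-tolerant
semi-global alignment allowing the adapter to occur internally or to run
off the read's 3' end; allowed errors are `floor(rate × matched length)`
(default rate 0.1, minimum overlap 3), and among qualifying matches the
longest matched adapter prefix wins, then fewest errors, then leftmost
start.

**Demultiplexing.** Each read's barcode is sought by semi-global
edit-distance match (substitutions + indels, via edlib) with
`k = floor(0.15 × 8) = 1` allowed error.  The read is assigned to the
unique barcode at minimal distance ≤ k; ties and misses go to the
unassigned pool — false assignment is costlier than read loss.  Two search
modes exist: full-read, and an anchored window around the expected
quatromer+barcode prefix.  The pipeline defaults to the anchored window
(slack 2): measured on simulated 300-nt reads at 0.5% error, full-read
search loses ~1.7% of reads to spurious distance-1 ties arising elsewhere
in the amplicon, against 0.3% for the window with zero cross-assignment.
An exact-prefix fast path is used only in window mode and only after
verifying no competing barcode occurs exactly inside the window (a
distance-0 match is necessarily an exact substring, so scanning the
window's 8-mers finds every potential tie); it is therefore exactly
equivalent to the fuzzy rule, not an approximation.

**Merging.** All relative offsets of read 1 against the reverse-complement
of read 2 are scanned — including containment, since with 300-bp reads and
≤273-bp amplicons every proper pair is full read-through (barcode/quatromer
removal must precede merging for this reason, and the pipeline enforces
that order).  Match counts for all offsets come from a 4-channel one-hot
cross-correlation (`numpy.correlate`), so the scan is O(n²) in C rather
than Python.  The offset with minimal mismatch ratio wins (ties: longer
overlap, then smaller offset); pairs whose best ratio exceeds 0.25 stay
unmerged; minimum overlap is 10 (both defaults follow common practice for
overlap mergers).  Consensus: the higher-quality base wins, equal-quality
conflicts keep read 1's base; consensus quality is the maximum of the two
at agreeing positions and `max(|q1−q2|, 2)` at conflicts — downstream
stages ignore quality, so this choice is cosmetic.  Single-end input
passes through unchanged.

**Classification.** Each form is recognised by the exon junctions it alone
realises (probes of `flank`=10 nt each side, 20 nt total; the control by a
20-nt probe from the control amplicon).  A probe hits if its semi-global
edit distance anywhere in the read is ≤ `floor(0.10 × 20) = 2`.  A form is
called iff all its probes hit and no probe exclusive to another form hits;
anything else — including chimeric reads hitting junctions of two forms —
is UNASSIGNED, never majority-voted, so chimeras cannot inflate rare
forms.  Probe sets are validated at build time by classifying the five
error-free templates: the result must be the identity, otherwise the
design is rejected with the collision named.  Reads are evaluated forward
first; the first orientation with a valid call wins, and the reverse
complement is consulted only when the forward orientation yields none.

**Calibration.** Within each equimolar mixture the per-species factor is
`share × n_species`, renormalised within the mixture to geometric mean 1;
the pooled factor is the geometric mean across mixtures (factors are
ratios), renormalised to geometric mean 1 over species.  Species with zero
reads in a mixture are excluded from that mixture with a warning; a
species absent everywhere aborts estimation.  The cross-mixture
coefficient of variation per species is the QC statistic (default
threshold 0.2, spanning the 16-fold template range of the default
manifests: 200 ×2, 400, 800, 1600, 3200 molecules).  Correction is
per-species multiplicative (`count / factor`) rather than a fitted length
curve — five species give five direct factors, and a two-parameter length
model would add assumptions without need; the log-factor-vs-length
regression is reported as a diagnostic only.  UNASSIGNED rows are never
corrected.

**Quantification.** Pool normalisation divides each sample's counts by the
pool's mean per-sample total, making samples comparable across pools of
different yield.  Control normalisation reports `species / (control /
volume_fraction)`; the volume-fraction rescaling (for a control spiked at
5–10% of reaction volume) is off by default (fraction 1.0) since the
correct treatment of a partial-volume control is assay-specific.  Samples
with zero control counts are flagged undefined — never reported as zero.
The ddPCR estimator is `λ̂ = −ln(n_neg/n_total)`, concentration
`λ̂ / droplet volume` (default 0.85 nL, the common droplet generator's
nominal volume, configurable), with delta-method standard error
`√((e^λ−1)/n)`; saturated wells are rejected, zero-positive wells return 0
flagged below the limit of detection.  Fold changes default to the
geometric scale (`2^(Δ mean log2)`) because expression ratios are analysed
on the log2 scale; the arithmetic scale is provided as an alternative.
Concordance between measurement platforms is Spearman's rank correlation
with average ranks for ties and listwise deletion.  Hypothesis tests
(ANOVA, post-hoc comparisons, regression on covariates such as RIN, PMI,
age, sex) are deliberately not re-implemented: the package emits tidy
per-sample expression tables for standard statistics routines.

**GWAS odds-ratio harmonisation.** Per locus, the newest study's risk
allele fixes the reference orientation; studies tested on the opposite
allele are flipped (OR ← 1/OR), and if the reference study's OR in its own
orientation is below 1 the whole locus is flipped so the consensus OR ≥ 1.
When studies genuinely disagree in direction, consistency of orientation
takes precedence: a non-reference study may retain an OR below 1 rather
than being flipped into an inconsistent orientation.  Loci whose allele
pairs match neither orientation are excluded.  The output is sorted by
descending median OR across studies and the operation is idempotent.

## Reproducibility

Every generator takes an explicit seed; the pipeline expands one global
seed into per-stage substreams via `numpy.random.SeedSequence`, so a rerun
from the same config is byte-identical (count tables and the JSON run
manifest carry no timestamps).  The manifest records a per-stage
read-conservation ledger (input = output + discarded, asserted at run
time); no stage drops reads silently.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run the end-to-end chain on
simulated 16-plex runs of 50,000 read pairs per sample at 0.5%
substitution error, twenty seeded single-sample runs of the same depth for
the recovery-error estimate, six spike-in mixtures of 20,000 reads each
for calibration, 250 simulated wells of 20,000 droplets for the Poisson
estimator, and 1,000-instance randomised cross-checks of each fuzzy
matcher against brute-force dynamic-programming oracles written
independently of the library code.  These sizes put multinomial sampling
error well below the tolerances being checked while keeping a full run in
the minutes range on a single CPU.

## Known limitations

* Classification requires the junction-probe set to be discriminative on
  the design; heavily homologous exon boundaries could defeat it, and the
  build step rejects such designs rather than guessing.
* The bias model corrects the combined amplification + bridge-PCR effect
  per species; it cannot separate the two mechanisms, and assumes spike-in
  fragments amplify like biological cDNA of the same length.
* Raising the classification error rate does not provably increase the
  assigned fraction: extra tolerance can also create probe conflicts that
  void a previously valid call (observed to be monotone at practical
  rates).
* The partial-volume control spike makes the endogenous-control ratio
  sensitive to pooling accuracy; the volume-fraction correction is exposed
  but disabled by default.
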