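# Methods

This note documents the models behind `pamscan`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical conventions a maintainer should know about.

## 1. Assay read-out chain

The analysis follows the sequencing post-processing of the in vitro PAM
capture assay step by step:

1. **Quality trimming.** Reads are truncated 3' at the first base whose
   Phred score falls below Q13 (inclusive threshold: Q13 itself is kept).
   Trimming is a plain prefix rule, not a sliding window — the sliding
   window adds parameters the downstream perfect-match extraction does not
   need, since any flank-damaging truncation already drops the read.
2. **Demultiplexing.** A read is assigned iff its 5' end begins with
   exactly one of the sample barcodes (4–6 nt, perfect match); the barcode
   set must be unique and prefix-free, which is validated up front.  The
   barcode is stripped before extraction.
3. **PAM extraction.** The PAM is the `pam_len` bases sitting between a
   perfect 12-nt match to the left flank (the 3' end of the protospacer)
   and a perfect 12-nt match to the right flank, at exactly `pam_len`
   separation.  The forward orientation is searched first, then the reverse
   complement.  Within one orientation the leftmost valid flank pair wins;
   a read with valid matches in *both* orientations is dropped as
   ambiguous, and all drops are tallied in the QC summary.  Whether
   reverse-complement reads can occur depends on the sequencing setup, so
   the RC search is a flag (`search_rc`, default on) — with single-end
   adapter-side sequencing it simply never fires.
4. **Collapse and count.** Extracted PAMs are collapsed into like
   sequences and counted; table ordering is deterministic (descending
   count, ties lexicographic).

## 2. Library normalization and the PFM

Cleaved-sample frequencies are divided by their frequency in the starting
library and rescaled to sum to one:

    w(p) ∝ f_cleaved(p) / (f_library(p) + ε)

The ratio-then-renormalize form is the natural reading of "normalized to
its frequency in the starting library"; the exact formula is otherwise an
open choice.  The pseudocount default ε = 0.5 / (library total) only
matters for PAMs cleaved but never observed in the library control; with
ε = 0 such a PAM is an error.  Normalization is exactly invariant to
rescaling either table's counts when ε = 0 and invariant to first order
otherwise.

The position frequency matrix weights each nucleotide at each position by
the normalized frequency of the PAMs carrying it; positions are treated
independently (per-position marginals, no k-mer interactions — explicitly
out of scope).  Position indices are 1-based with position 1 the first
base 3' of the protospacer on the protospacer-containing strand.

Information content uses the WebLogo/Schneider convention with uniform
background, IC_j = 2 + Σ_b p log2 p bits (0·log 0 = 0), so IC ∈ [0, 2].
Logo export writes letter heights as TSV in either probability mode
(heights are the PFM entries; default, matching near-full-height columns
at unconstrained positions) or bits mode (height = p × IC).

**Consensus calling.** Per position, bases are retained in descending
probability until the cumulative mass reaches `support_threshold`
(default 0.9); exact ties are retained together.  The position is called N
when the retained set is all four bases or no single base exceeds
`n_floor` (default 0.30).  Both thresholds are explicit knobs because
"strong/moderate/slight preference" is qualitative in origin; the defaults
make a three-base set at roughly uniform thirds (a D/H/B/V call) stable at
the read depths the assay prescribes while near-uniform positions stay N.

**Dose comparison.** Specificity change between doses is reported as
IC_low − IC_high per position plus the total; positions exceeding a noise
floor (default 0.1 bits) are flagged.  The floor is a reporting filter
only.

**Spacer-shift extension.** Shifting the spacer s nt in the 5' direction
(default s = 3) moves the PAM frame so the randomized base r reports on
PAM position r + s.  The extended matrix takes positions 1..L from the
unshifted experiment and L+1..L+s from shifted positions L+1−s..L.  The
overlap (positions s+1..L) is measured twice; it is reported from the
unshifted experiment, and the per-position total-variation distance to the
shifted values is emitted as a concordance diagnostic (flagged above 0.1).

## 3. The simulator

The simulator is the package's source of ground truth and defines the
conditions under which everything is tested.

* **Library composition** over all 4^L PAMs is a symmetric Dirichlet draw
  with concentration 1/bias per category (bias 0 = exactly uniform).  The
  default bias 0.1 (relative SD ≈ 30 % across PAM frequencies) emulates a
  visibly non-uniform but well-covered synthesis, strong enough that
  skipping library normalization is detectable, mild enough that 5× depth
  still covers the library.
* **Cleavage.** Ground truth is a per-PAM first-order rate, either an
  explicit table or k(p) = k_max · Π_j w_j(p_j) with per-position weights
  in [0, 1].  The IUPAC constructor gives allowed bases weight 1 and
  others `mismatch_weight` (default 0.01, i.e. near-cognate PAMs retain
  1 % activity).  A digest of duration t at RNP concentration c cleaves
  with probability 1 − exp(−k · g(c) · t), g(c) = c/(c + K_half).  The
  saturating occupancy factor is a modeling choice, not a measured
  dose–response; K_half = 5 nM places 0.5 nM (g ≈ 0.09) and 50 nM
  (g ≈ 0.91) digests in the sub-saturating and saturating regimes, which
  is what produces the dose-dependent consensus broadening downstream.
  With k_max = 0.2 /min and t = 60 min a cognate PAM cleaves with
  probability ≈ 0.66 at the low dose and ≈ 1.0 at the high dose.
* **Capture and sequencing.** Tailing, ligation and PCR are collapsed into
  a single weighted draw per read (weight = library frequency × cleavage
  probability); PCR bias, duplicates and chimeras are not modeled, read
  counts are proportional to cleaved molecules.  Reads are barcode + left
  flank + PAM + right flank + adapter, padded/truncated to `read_len`
  (default 100 nt); the blunt cut 3 nt 5' of the PAM is the fragment-end
  convention.  Sequencing noise is substitution-only at a per-base rate
  (default 0.002) with Gaussian Phred qualities (mean 33, SD 3, clipped to
  [2, 41]).  Indel sequencing errors and paired-end reads are out of
  scope.  Zero RNP concentration yields an empty read stream — the no-RNP
  negative control.
* **Amplicons.** A `mutant_fraction` of reads carries one edit drawn from
  a weighted indel spectrum (every edit anchored within 5 nt of the cut);
  the reference fixture plants eleven distinct 1–3 nt indels with
  descending weights plus, in test scenarios, a PCR-artifact edit shared
  with the control run.
* **Kinetics.** SC(t) = exp(−k t) plus Gaussian noise clipped to [0, 1].

Every sampler is reproducible under a fixed seed; identical seeds yield
byte-identical FASTQ.

What passing simulator-based tests shows — and does not.  They validate
the analysis logic (extraction rules, normalization, consensus and window
rules, estimators) against exact ground truth under an idealized error
model.  They do not validate robustness to PCR jackpots/duplicates,
quality-correlated or indel sequencing errors, adapter read-through, or
library cross-contamination, none of which the simulator produces.

## 4. Indel calling

Reads are gated on a perfect barcode+primer prefix and an accepted length
range (after Q13 trimming); only gated reads enter the mutant-percentage
denominator.  Gated reads are globally aligned to the amplicon reference
(match +2, mismatch −2, gap open −6, gap extend −1 per base, via
Biopython's PairwiseAligner); alignments scoring below 40 % of the
perfect-match score are rejected and tallied.  Gap placements are then
left-normalized, so equal-scoring placements in repeats collapse to a
canonical leftmost anchor.

A read is a mutant iff it has ≥ 1 indel (substitutions never count) whose
left-normalized anchor lies in the half-open window
[cut − 5, cut + 5) around the expected cut (window = 10 nt, symmetric,
configurable), and that indel is not in the negative-control variant set.
Control variants are collected by running the identical gate/align/window
scan on reads from a no-guide run, and exclusion is by exact edit identity
(operation, position, length, inserted bases); a ±1 nt positional slack is
available but off by default.  "Visual confirmation" of top mutations is
operationalized as the automated window rule plus an emitted audit
alignment per record ('-' for deletions, lowercase for insertions).
Identical mutations are collapsed and ranked by descending read count,
ties by anchor position then lexicographic edit description; the top 10
are reported with the full table retained.

Known limitation: because control subtraction is by exact identity, a
sequencing-error-induced realignment in the control sample can add a
variant to the exclusion set; if that variant coincides with a genuine
low-frequency mutation, those reads are (conservatively) suppressed.  The
control variant set is part of the report so such collisions are
auditable.

## 5. Kinetics

The supercoiled fraction is modeled as SC(t) = exp(−k t) with amplitude
fixed at 1 (the substrate starts fully supercoiled; an amplitude-free
variant is deliberately not the default since it absorbs loading error
into the rate).  k is fitted by bounded nonlinear least squares seeded
with the closed-form through-origin slope of ln SC versus t; replicates
are pooled.  A series that never leaves SC = 1 returns k = 0 with a
warning.  Reported: k, its standard error from the fit covariance, R²,
and the pooled point count.  Fold changes between a reference and a
mutant PAM are k_ref/k_mut with first-order error propagation; a mutant
rate not significantly above zero (within 2 SE, configurable) is reported
as "abolished" rather than as an unbounded ratio.  Detecting very slow
cleavage is limited by the observation window: decay amplitudes below the
measurement noise over the sampled times are indistinguishable from zero.

## 6. Problem sizes and defaults used in validation

Validation runs use the assay's own prescriptions: 5× the library
diversity in reads (5,120 for the 5-bp and 81,920 for the 7-bp window),
digests at 0.5 and 50 nM RNP for 60 min of a 5.6 nM library, amplicon runs
of 20,000 reads at 25 % mutant fraction with a 20 % sized no-guide
control, and kinetics time courses of six points × three replicates at 2 %
measurement noise (longer time bases for slow mutants, so the decay is
actually sampled).  Dose-broadening checks use five independent replicate
simulations of 10,240 reads per dose.
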