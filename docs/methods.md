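# Methods

`mpracal` implements two bespoke analyses for a study of enhancer function
and calcium handling in cardiomyocytes: quantification of barcoded enhancer
reporter assays (MPRAs, genomically integrated or episomal), and analysis of
paced cardiomyocyte calcium transients with an emphasis on beat-to-beat
amplitude anomalies. This note records the models, the defaults and why they
were chosen, and what the synthetic-data generators do and do not emulate.

## MPRA quantification

### Model

Each candidate enhancer (400 bp element) is linked to a unique DNA barcode.
Amplicon sequencing of reporter RNA and of DNA (genomic DNA for the
integrated assay; vector DNA for the episomal assay) yields per-barcode
counts. The analysis chain is:

1. **Barcode extraction.** Each read is searched for a constant priming
   site ("anchor") that sits between the enhancer and the barcode; the
   barcode is the fixed-length window starting at a declared offset after
   the anchor end (0-based, half-open). Anchor matching is exact substring
   search by default, with an optional 1+-mismatch mode; if the anchor
   occurs twice, the first occurrence is used. Reads are discarded — with
   separate tallies — when the anchor is absent, when the extracted barcode
   is not on the library whitelist, or when the barcode window runs past
   the read end. Matched plus discarded always equals reads processed.
2. **Depth normalization.** Counts are converted to reads per million
   (RPM; called CPM for the episomal DNA counts — same arithmetic) over the
   matched-barcode total of each sample.
3. **Activity.** activity_i = mean RNA RPM_i / mean DNA RPM_i. Replicate
   columns are averaged *before* the ratio; averaging frequencies first is
   stabler for low-count barcodes than averaging per-replicate ratios.
   With a zero pseudocount (the default), zero-DNA rows are flagged
   (`dna_zero`) and excluded rather than reported as infinite; a
   configurable `pseudocount_rpm` is available for robustness studies.
4. **Reference-class normalization.** All activities in a stratum are
   multiplied by one scalar so that the endothelial (endocardial)
   negative-control class averages exactly 1. For the integrated assay
   there is a single stratum; for the episomal assay the factor is computed
   per minimal-promoter stratum, making activities comparable across
   promoters. Because normalization is a single scalar multiply, it is
   idempotent and preserves within-stratum activity ratios (to one IEEE
   rounding ulp).
5. **Episomal DNA filter.** Promoter–enhancer pairs are analyzed only when
   present at strictly more than 30 CPM in *every* DNA replicate.
6. **Summaries.** Replicate agreement as squared Pearson correlation of
   per-barcode frequencies; class fold-change as the ratio of class mean
   (normalized) activities; cross-assay comparison as an inner join on
   enhancer with r² and an ordinary least-squares fit.

### Synthetic MPRA data

The generator emulates the study design: a 55-element library (25
cardiomyocyte enhancers, 25 endothelial negative controls, 5 ESC negative
controls) with unique random barcodes (uniform over {A,C,G,T}^L, rejection
on duplicates; minimum pairwise Hamming distance is *not* enforced).
Ground truth consists of per-element activities — log-normal within class
(sigma 0.5), rescaled so class means are exactly 4.5 (cardiomyocyte) and
1.0 (endothelial, ESC), matching the integrated assay's observed ~4.5-fold
class separation — and a log-normal DNA representation (sigma 0.5,
renormalized), mimicking realistic library skew. DNA reads are drawn
multinomially from the DNA frequencies; RNA reads from frequencies
proportional to DNA frequency × activity. Optional features: per-element
dropout (a synthesis failure), a fixed fraction of anchorless junk reads,
and a uniform per-base substitution error rate (default 0 — no error model
is imposed unless asked for). Reads are emitted in a seeded shuffled order
and written as 4-line FASTQ with constant Q40 qualities.

Not emulated: PCR amplification bias chemistry, position-dependent
sequencing error profiles, UMI structure, or chimeric reads. Passing tests
therefore demonstrate correctness of the quantification arithmetic and its
behavior under multinomial sampling noise and library skew — not robustness
to amplification artifacts.

## Calcium-transient analysis

### Pipeline

Per cell, on a uniformly sampled fluorescence trace paced at a known rate:

1. **QC.** Cells are excluded when the recording covers fewer than five
   full pacing cycles (to within one sample) or contains non-finite values.
2. **Preprocessing.** (a) Photobleach removal: the diastolic baseline is
   estimated as the minimum over the *late* 40% of each pacing cycle
   (late diastole, where the transient has relaxed furthest — this avoids
   the pre-pacing first-cycle minimum, which is not in periodic steady
   state); a linear (default) or exponential trend is fitted through these
   nodes and divided out, photobleaching being multiplicative on
   fluorescence. (b) A median filter (default window 5 samples) removes
   impulse noise. (c) Subtracting 1 puts the trace in dF/F0 units with the
   diastolic baseline at 0. Note that F0 is the *late-diastolic* level; at
   2 Hz pacing with a 0.2 s decay constant the transient does not fully
   relax between beats, so dF/F0 amplitudes are systematically somewhat
   below the generator's programmed amplitude. This is a property of the
   physiology, not an artifact, and cancels in all ratio-based statistics.
3. **Peak detection** via prominence-based local-maximum search
   (`scipy.signal.find_peaks`); defaults: prominence 20% of the cell's
   maximal dF/F0, minimum separation 0.6 pacing periods. Both are
   configurable; peak height is the dF/F0 value at the maximum.
4. **Transient metrics** per beat: amplitude (= peak height); maximal
   upstroke and downstroke velocities as the extrema of the first
   difference divided by the sample interval, within a beat window running
   from the midpoint after the previous peak to the midpoint before the
   next; time from peak to 50% decay (t50) by linear interpolation between
   the bracketing samples. Beats whose decay never reaches 50% before the
   next beat window are flagged and excluded from the t50 mean. For a
   single-exponential decay, t50 = tau·ln 2, which the tests verify.
5. **Low-peak classification.** A peak is "low" when its height is between
   10% and 94% (inclusive) of the cell's reference height — by default the
   cell's maximum peak (a median option exists). Cells with three or more
   low peaks are flagged. Peaks below the 10% floor are not counted.
6. **Peak-amplitude variation.** An ordinary least-squares line is fitted
   to the peak (time, height) coordinates; each peak's deviation is its
   absolute distance from the line normalized to its own height, and the
   per-cell score is the mean deviation (the per-cell aggregate is this
   package's convention; the per-peak deviations are also reported). The
   line absorbs slow monotone trends (residual bleaching, run-down), so
   the score isolates beat-to-beat variability: it is exactly zero when
   heights are an affine function of time, and is invariant to rescaling
   all heights. It needs at least three peaks — a line through two points
   has zero residual — and returns not-a-value with a reason otherwise.

### Synthetic calcium data

Each simulated cell is 5 cycles of 2 Hz pacing sampled at 100 Hz (the study
recorded the last 5 of 30 paced cycles): baseline 1.0; per beat a linear
upstroke (50 ms) from the instantaneous value to baseline + amplitude,
then single-exponential decay (tau = 0.2 s — t50 ≈ 139 ms, typical of adult
mouse cardiomyocytes at this rate, and deliberately leaving incomplete
relaxation between beats as observed at 2 Hz). Additive drift (default
linear, −0.04 F/s, ~10% photobleach over a recording) and Gaussian noise
(sd 0.02, i.e. 2% of the transient amplitude) are applied afterward.
Alternans is modeled by scaling every second beat — the even-indexed beats
0, 2, 4 — by `alternans_ratio`; with 5 recorded cycles this yields three
attenuated beats, the phase under which a pure-alternans cell can satisfy
the ≥3-low-peaks rule. Per-cell seeds derive from the master seed by a
(group index, cell index) spawn key, so any subset regenerates
independently; optional log-normal jitter on amplitude and tau is recorded
in the manifest.

Not emulated: spontaneous (unpaced) calcium release events, early/delayed
afterdepolarization-like waveforms, motion artifacts, cell-segmentation
noise, or missed stimulus capture. The power property the tests check —
higher variation score and more multi-low-peak flags under alternans — is
therefore a statement about the statistic's sensitivity to programmed
amplitude alternation under realistic noise and bleach, not a claim about
any particular biological effect size.

## Reporting statistics

Dunnett's many-to-one comparison and Tukey's all-pairs HSD are delegated to
`scipy.stats` (`dunnett`, `tukey_hsd`); the package adds input validation,
tidy-table interfaces and reporting. The tests validate the Dunnett
adjustment against a seeded max-|t| permutation oracle on a small instance
and check ~5% type-I error calibration (familywise for the
multiple-comparison procedures) over 1000 seeded null repetitions. The
t-test is the classical equal-variance Student's t by default, with Welch's
variant behind a flag; multiplicity is handled exactly as each analysis
specifies, with no additional global FDR layer.

## Numerical conventions and edge cases

- All sequence coordinates are 0-based, half-open. Reverse-complement
  amplicon layouts reverse-complement the read before the anchor search;
  there is no mixed-orientation autodetection.
- RPM columns sum to 10^6 by construction (verified to 1e-6 relative);
  an all-zero sample column is an explicit error naming the sample.
- Replicate r² on zero-variance input returns NaN with a warning rather
  than raising.
- The reference-class mean after normalization equals 1 to 1e-9 (exactly,
  up to floating-point summation order).
- t50 crossings are found by linear interpolation between bracketing
  samples; peak times snap to the nearest sample of the trace grid.
- Low-peak band endpoints are inclusive; the reference height must be
  positive.
- Deterministic throughout: every stochastic function takes or derives a
  seed; fixed seeds give bit-identical outputs.

## Problem sizes used in the shipped analyses

The acceptance computation simulates the 55-element library at one million
reads per analyte (enough that multinomial sampling error on class means is
well under the 10% recovery tolerance), 50 cells per group for the
alternans comparison, and 1000 repetitions for the null-calibration rates
(Monte-Carlo SD ≈ 0.7 percentage points at the 5% level). Unit tests use
smaller instances chosen so that documented statistical bounds (3-SD
multinomial bands, binomial variance) still hold with margin.

## Known limitations

- Dividing out a trend fitted to an *additively* drifting trace rescales
  transient peaks slightly against the drift; the best-fit-line variation
  statistic absorbs this, but per-beat amplitudes late in a strongly
  bleaching recording are biased by the ratio of drift to baseline.
- dF/F0 amplitude is measured against the late-diastolic level, which at
  fast pacing includes an amplitude-dependent relaxation residual;
  absolute amplitudes are therefore comparable within a pacing regime, not
  across regimes.
- The barcode extractor is exact-match on the whole barcode; sequencing
  errors inside the barcode discard the read (no error-correcting
  within-Hamming-distance rescue).
- `group_fold_change` compares arithmetic class means, matching the
  upstream definition of activity as a frequency ratio; heavy-tailed
  activity distributions make it sensitive to single strong enhancers.
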