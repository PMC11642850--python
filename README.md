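# mpracal

Quantification of barcoded enhancer reporter assays (MPRAs) and analysis of
paced cardiomyocyte calcium transients, with synthetic-data generators for
both, in one tested Python package.

## What it is for

Two analyses that often travel together in cardiac functional genomics:

**1. MPRA quantification.** A pool of candidate enhancers — here 25
validated cardiomyocyte enhancers, 25 endothelial/endocardial negative
controls and 5 ESC negative controls — is delivered as a barcoded reporter
library, either integrated into a native 3' UTR (STARR-seq style) or on an
episomal AAV vector with an assortment of minimal promoters. Amplicon
sequencing of reporter RNA and of DNA yields per-barcode counts, and the
activity of element *i* is the ratio of its barcode frequency in RNA to its
frequency in DNA:

    activity_i = (RNA RPM_i) / (DNA RPM_i)

Normalized activity multiplies all activities in a stratum by one scalar so
that the endothelial negative-control class averages exactly 1. Episomal
data are filtered to promoter–enhancer pairs present at >30 CPM in every
DNA replicate. The package covers barcode extraction from FASTQ (anchor
search, whitelist matching, discard accounting), RPM/CPM, activity,
normalization, replicate r², class fold-changes and cross-assay comparison.

**2. Calcium-transient analysis.** Per-cell fluorescence traces from 2
Hz-paced cardiomyocytes (5 recorded cycles) are cleaned (photobleach
removal, median filter, dF/F0 normalization), peaks are detected, and each
beat yields amplitude, maximal upstroke/downstroke velocity and time to 50%
decay. Two anomaly statistics target beat-to-beat amplitude variation
(calcium alternans): the count of "low peaks" — peaks at 10–94% of the
cell's reference height, with cells flagged at ≥3 — and a peak-amplitude
variation score: peak (time, height) coordinates are fitted with a best-fit
line, and each peak's distance from the line, normalized to its height, is
averaged per cell.

The `synthetic_data` module generates both kinds of raw data with known
ground truth (programmed activities and DNA skew; programmed transient
shape, drift, noise and alternans), so the entire pipeline is testable at
desk scale. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from mpracal import *
from mpracal.mpra_quant import concat_counts

# --- MPRA: simulate the 55-element library and recover the fold-change ---
library = make_library(25, 25, 5, barcode_length=16, seed=1)
truth = make_ground_truth(library, seed=1)        # CM:endothelial class means 4.5 : 1
layout = AmpliconLayout(barcode_length=16)
sim = simulate_reads(library, truth, layout, 200_000, 200_000)
tables = [extract_barcodes(sim.iter_reads(a), library, layout, sample_id=a)
          for a in ("RNA", "DNA")]
rpm = counts_to_rpm(concat_counts(tables))
activity = normalize_activity(compute_activity(rpm[["RNA"]], rpm[["DNA"]], library))
fold = group_fold_change(activity, "cardiomyocyte", "endothelial")
print(f"cardiomyocyte : endothelial fold-change = {fold:.2f}")

# --- Calcium: alternans versus control cells ---
pop = simulate_cell_population(
    20,
    {"control": TraceSpec(), "alternans": TraceSpec(alternans_ratio=0.6)},
    seed=1,
)
print(analyze_population(pop).summary.round(3).to_string(index=False))
```

Output:

```
cardiomyocyte : endothelial fold-change = 4.45
    group  n_cells  amplitude  max_upstroke_velocity  max_downstroke_velocity  t50_decay  mean_n_low_peaks  multi_low_fraction  variation_score
  control       20      0.770                 20.015                    7.121      0.128              1.55                 0.2            0.013
alternans       20      0.605                 16.199                    5.970      0.132              3.20                 1.0            0.285
```

The recovered fold-change (4.45) matches the programmed 4.5-fold
cardiomyocyte : endothelial separation to within multinomial sampling error
at this depth. In the calcium comparison, every alternans cell (beat-to-beat
amplitude ratio 0.6) is flagged for multiple low peaks and the group's mean
peak-amplitude variation score is ~20× the control group's; amplitudes are
in dF/F0 units against the late-diastolic baseline, velocities in dF/F0 per
second, t50 in seconds (≈ tau·ln 2 = 0.139 s for the programmed 0.2 s decay
constant).

A command-line interface mirrors the library:

```
mpracal simulate mpra --config mpra.yaml --seed 1 --outdir sim/
mpracal mpra count --fastq rna=sim/rna.fastq.gz --fastq dna=sim/dna.fastq.gz \
        --library sim/library.tsv --out run
mpracal mpra activity --counts run.counts.tsv --library sim/library.tsv \
        --samples sim/samples.csv --mode integrated --out run
mpracal simulate calcium --config calcium.yaml --seed 1 --outdir sim/
mpracal calcium analyze --traces sim/traces.csv --groups sim/groups.csv --outdir out/
mpracal stats compare --data values.csv --method tukey --out report
```

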