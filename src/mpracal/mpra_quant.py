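"""Quantification of barcoded enhancer reporter assays (MPRAs).

From amplicon reads (or pre-made count tables) to per-enhancer activities:

* :func:`extract_barcodes` — trim each read at a constant priming site
  (anchor) and count whitelist barcode occurrences, tallying discarded
  reads (no anchor / off-whitelist barcode / barcode running past the read
  end).
* :func:`counts_to_rpm` — reads-per-million depth normalization (CPM for
  episomal DNA counts; same arithmetic).
* :func:`compute_activity` — per-element activity as the ratio of mean RNA
  frequency to mean DNA frequency (replicates averaged before the ratio).
* :func:`normalize_activity` — one scalar adjustment factor per
  (promoter) stratum so the reference class (endothelial negative
  controls) averages exactly 1.
* :func:`filter_episomal` — keep promoter–enhancer pairs present above a
  CPM floor (strictly > 30 by default) in every DNA replicate.
* :func:`replicate_correlation`, :func:`group_fold_change`,
  :func:`compare_assays` — the replicate-QC, class fold-change and
  cross-assay summaries.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from mpracal.synthetic_data import AmpliconLayout, EnhancerLibrary, _revcomp

__all__ = [
    "BarcodeCountTable",
    "AssayComparison",
    "extract_barcodes",
    "concat_counts",
    "counts_to_rpm",
    "compute_activity",
    "normalize_activity",
    "filter_episomal",
    "replicate_correlation",
    "group_fold_change",
    "compare_assays",
    "load_sample_manifest",
]

DISCARD_KEYS = ("no_anchor", "unmatched_barcode", "truncated")


@dataclass
class BarcodeCountTable:
    """Barcode x sample matrix of nonnegative integer counts.

    ``discarded`` tallies, per sample, reads without the anchor
    (``no_anchor``), reads whose extracted barcode is off-whitelist
    (``unmatched_barcode``), and reads where the barcode would extend past
    the read end (``truncated``, a distinct no-anchor-class tally).
    Matched + discarded equals the number of reads processed.
    """

    counts: pd.DataFrame
    discarded: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        for sample in self.counts.columns:
            self.discarded.setdefault(
                sample, {k: 0 for k in DISCARD_KEYS}
            )

    def total_processed(self, sample: str) -> int:
        return int(self.counts[sample].sum()) + sum(self.discarded[sample].values())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("barcode").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeCountTable":
        df = pd.read_csv(path, sep="\t", index_col="barcode")
        return cls(df)

    def qc_json(self, path: str | Path | None = None) -> dict:
        payload = {}
        for sample in self.counts.columns:
            total = self.total_processed(sample)
            matched = int(self.counts[sample].sum())
            payload[sample] = {
                "reads_processed": total,
                "matched": matched,
                **self.discarded[sample],
                "discard_rate": (total - matched) / total if total else 0.0,
            }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return payload


def _iter_sequences(reads) -> Iterator[str]:
    """Accept a FASTQ(.gz) path, SeqRecords, (id, seq, qual) tuples or strings."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    yield str(rec.seq)
        else:
            for rec in SeqIO.parse(str(path), "fastq"):
                yield str(rec.seq)
        return
    for item in reads:
        if isinstance(item, str):
            yield item
        elif isinstance(item, tuple):
            yield item[1]
        else:  # SeqRecord
            yield str(item.seq)


def _find_with_mismatches(seq: str, anchor: str, max_mm: int) -> int:
    """Leftmost position of anchor allowing up to max_mm substitutions."""
    n, m = len(seq), len(anchor)
    for start in range(n - m + 1):
        mm = 0
        for a, b in zip(seq[start : start + m], anchor):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start
    return -1


def extract_barcodes(
    reads,
    library: EnhancerLibrary,
    layout: AmpliconLayout,
    sample_id: str = "sample",
    max_anchor_mismatches: int = 0,
) -> BarcodeCountTable:
    """Count whitelist barcodes in one sample's reads.

    For each read: locate the anchor (exact substring match by default; the
    first occurrence wins if it appears twice), take ``barcode_length``
    bases starting ``barcode_offset`` bases after the anchor end, and match
    against the library whitelist.  Reads in ``reverse_complement`` layouts
    are reverse-complemented before the search.  An empty read stream
    yields an all-zero table (not an error).
    """
    if len(library) and layout.barcode_length != library.barcode_length:
        raise ValueError("layout barcode_length does not match the library")
    whitelist = set(library.entries["barcode"])
    counts: dict[str, int] = {}
    no_anchor = unmatched = truncated = 0
    anchor = layout.anchor
    alen = len(anchor)
    off = layout.barcode_offset
    blen = layout.barcode_length
    rc = layout.orientation == "reverse_complement"

    for seq in _iter_sequences(reads):
        if rc:
            seq = _revcomp(seq)
        pos = seq.find(anchor)
        if pos < 0 and max_anchor_mismatches > 0:
            pos = _find_with_mismatches(seq, anchor, max_anchor_mismatches)
        if pos < 0:
            no_anchor += 1
            continue
        start = pos + alen + off
        end = start + blen
        if end > len(seq):
            truncated += 1
            continue
        bc = seq[start:end]
        if bc in whitelist:
            counts[bc] = counts.get(bc, 0) + 1
        else:
            unmatched += 1

    col = pd.Series(
        [counts.get(bc, 0) for bc in library.entries["barcode"]],
        index=pd.Index(library.entries["barcode"], name="barcode"),
        name=sample_id,
        dtype=int,
    )
    return BarcodeCountTable(
        counts=col.to_frame(),
        discarded={
            sample_id: {
                "no_anchor": no_anchor,
                "unmatched_barcode": unmatched,
                "truncated": truncated,
            }
        },
    )


def concat_counts(tables: Iterable[BarcodeCountTable]) -> BarcodeCountTable:
    """Combine single-sample count tables sharing a barcode index."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to combine")
    counts = pd.concat([t.counts for t in tables], axis=1)
    if counts.isna().any().any():
        raise ValueError("tables do not share a common barcode index")
    discarded: dict[str, dict[str, int]] = {}
    for t in tables:
        for sample, tallies in t.discarded.items():
            if sample in discarded:
                raise ValueError(f"duplicate sample_id {sample!r}")
            discarded[sample] = dict(tallies)
    return BarcodeCountTable(counts=counts.astype(int), discarded=discarded)


def counts_to_rpm(table: BarcodeCountTable | pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization of each sample column.

    Depth is the matched-barcode total of the column.  An all-zero column is
    an explicit error naming the sample.
    """
    counts = table.counts if isinstance(table, BarcodeCountTable) else table
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero matched reads: {list(zero.index)}")
    return counts / totals * 1e6


def compute_activity(
    rna_rpm: pd.DataFrame,
    dna_rpm: pd.DataFrame,
    library: EnhancerLibrary,
    pseudocount_rpm: float = 0.0,
) -> pd.DataFrame:
    """Per-element activity: mean RNA RPM / mean DNA RPM.

    Replicate columns within each analyte are averaged first, then the
    ratio is taken (documented order; averaging frequencies first is
    stabler at low counts).  With a zero pseudocount, rows with zero DNA
    are flagged ``dna_zero`` and carry NaN activity rather than infinity;
    with a positive pseudocount, rows where it changed a zero numerator or
    denominator are flagged ``pseudocounted``.
    """
    if pseudocount_rpm < 0:
        raise ValueError("pseudocount_rpm must be >= 0")
    shared = rna_rpm.index.intersection(dna_rpm.index)
    if len(shared) == 0:
        raise ValueError("RNA and DNA tables have disjoint barcode indices")
    mean_rna = rna_rpm.loc[shared].mean(axis=1)
    mean_dna = dna_rpm.loc[shared].mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        activity = (mean_rna + pseudocount_rpm) / (mean_dna + pseudocount_rpm)

    meta = library.entries.set_index("barcode")
    missing = shared.difference(meta.index)
    if len(missing):
        raise ValueError(f"{len(missing)} barcodes absent from the library manifest")
    meta = meta.loc[shared]

    flags = []
    for bc in shared:
        row_flags = []
        if mean_dna[bc] == 0 and pseudocount_rpm == 0:
            row_flags.append("dna_zero")
        elif pseudocount_rpm > 0 and (mean_dna[bc] == 0 or mean_rna[bc] == 0):
            row_flags.append("pseudocounted")
        flags.append(";".join(row_flags))

    out = pd.DataFrame(
        {
            "enhancer_id": meta["enhancer_id"].to_numpy(),
            "class": meta["class"].to_numpy(),
            "activity": activity.to_numpy(),
            "normalized_activity": np.nan,
            "flags": flags,
        },
        index=shared,
    )
    if "promoter_id" in meta.columns:
        out.insert(2, "promoter_id", meta["promoter_id"].to_numpy())
    out.loc[out["flags"].str.contains("dna_zero"), "activity"] = np.nan
    return out


def _strata(table: pd.DataFrame) -> Iterator[tuple[str, pd.Index]]:
    if "promoter_id" in table.columns:
        for promoter, sub in table.groupby("promoter_id", sort=False):
            yield str(promoter), sub.index
    else:
        yield "", table.index


def normalize_activity(
    table: pd.DataFrame, reference_class: str = "endothelial"
) -> pd.DataFrame:
    """Rescale activities so the reference class averages exactly 1.

    One scalar adjustment factor per promoter stratum (a single stratum for
    integrated assays); within-stratum activity ratios are preserved
    bit-for-bit.  Idempotent: the factor is recomputed from the raw
    activity column each call.
    """
    out = table.copy()
    for stratum, idx in _strata(table):
        sub = table.loc[idx]
        ref = sub[(sub["class"] == reference_class) & (sub["flags"] == "")]
        ref_activities = ref["activity"].dropna()
        if len(ref_activities) == 0:
            name = f"stratum {stratum!r}" if stratum else "the table"
            raise ValueError(f"no unflagged {reference_class} rows in {name}")
        factor = 1.0 / ref_activities.mean()
        out.loc[idx, "normalized_activity"] = table.loc[idx, "activity"] * factor
    return out


def filter_episomal(dna_cpm: pd.DataFrame, min_cpm: float = 30.0) -> pd.Series:
    """Keep-mask over promoter–enhancer pairs: CPM strictly above the floor
    in every DNA replicate (default > 30 CPM in all replicates)."""
    if dna_cpm.shape[1] < 1:
        raise ValueError("at least one DNA replicate column is required")
    return (dna_cpm > min_cpm).all(axis=1)


def replicate_correlation(freq_a: pd.Series, freq_b: pd.Series) -> float:
    """Squared Pearson correlation of paired per-barcode frequencies."""
    joined = pd.concat([freq_a, freq_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("replicate_correlation requires >= 3 shared barcodes")
    a = joined.iloc[:, 0].to_numpy(float)
    b = joined.iloc[:, 1].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance in a replicate; r^2 undefined", stacklevel=2)
        return float("nan")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def group_fold_change(
    table: pd.DataFrame,
    class_a: str = "cardiomyocyte",
    class_b: str = "endothelial",
) -> float:
    """Ratio of class mean activities (normalized scale; the ratio is
    identical on the raw scale within a stratum)."""
    col = (
        "normalized_activity"
        if table["normalized_activity"].notna().any()
        else "activity"
    )
    ok = table[table["flags"] == ""]
    means = {}
    for klass in (class_a, class_b):
        values = ok.loc[ok["class"] == klass, col].dropna()
        if len(values) == 0:
            raise ValueError(f"no usable rows of class {klass!r}")
        means[klass] = values.mean()
    return float(means[class_a] / means[class_b])


@dataclass
class AssayComparison:
    r_squared: float
    slope: float
    intercept: float
    table: pd.DataFrame


def compare_assays(a: pd.DataFrame, b: pd.DataFrame) -> AssayComparison:
    """Enhancer-level comparison of two activity tables.

    Inner-joins unflagged rows on enhancer_id and reports the squared
    Pearson correlation plus the ordinary least-squares fit of assay B's
    activity on assay A's (normalized scale where available).
    """
    def _col(t: pd.DataFrame) -> pd.Series:
        c = "normalized_activity" if t["normalized_activity"].notna().any() else "activity"
        ok = t[t["flags"] == ""]
        return ok.set_index("enhancer_id")[c].dropna()

    joined = pd.concat(
        [_col(a).rename("activity_a"), _col(b).rename("activity_b")],
        axis=1,
        join="inner",
    )
    if len(joined) < 3:
        raise ValueError("fewer than 3 shared unflagged enhancers")
    fit = stats.linregress(joined["activity_a"], joined["activity_b"])
    return AssayComparison(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        table=joined.reset_index(),
    )


def load_sample_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample manifest CSV.

    Columns: sample_id, analyte (RNA|DNA), assay (integrated|episomal),
    replicate (int >= 1), optional subject_id.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "analyte", "assay", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample_ids must be unique")
    if set(df["analyte"]) - {"RNA", "DNA"}:
        raise ValueError("analyte must be RNA or DNA")
    if set(df["assay"]) - {"integrated", "episomal"}:
        raise ValueError("assay must be integrated or episomal")
    if (df["replicate"] < 1).any():
        raise ValueError("replicate numbers must be >= 1")
    if (df["assay"] == "episomal").any() and not (
        (df["assay"] == "episomal") & (df["analyte"] == "DNA")
    ).any():
        raise ValueError("episomal analyses need at least one DNA sample")
    return df
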