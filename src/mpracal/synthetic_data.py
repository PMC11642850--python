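"""Synthetic data generators for the MPRA and calcium pipelines.

Two families of generators:

* **MPRA**: a barcoded enhancer library with class labels
  (cardiomyocyte / endothelial / esc), programmed per-element activities
  (ground truth RNA:DNA ratios) and a skewed DNA representation, from which
  amplicon reads are drawn multinomially for an RNA and a DNA sample.  The
  default library emulates a 55-element pool: 25 cardiomyocyte enhancers,
  25 endothelial (endocardial) negative controls and 5 ESC negative
  controls.
* **Calcium**: per-cell fluorescence traces of electrically paced
  cardiomyocytes (default 2 Hz pacing, 5 recorded cycles) with a linear
  upstroke, single-exponential decay, additive photobleaching drift,
  Gaussian noise and optional beat-to-beat amplitude alternation
  (alternans).

Every generator is bit-reproducible for a fixed seed; per-cell and
per-analyte seeds are derived from the master seed via a documented
spawn-key scheme (:mod:`mpracal._rng`) so subsets regenerate independently.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from mpracal._rng import child_rng
from mpracal.calcium_analysis import CalciumTrace

__all__ = [
    "CLASSES",
    "DEFAULT_ANCHOR",
    "AmpliconLayout",
    "EnhancerLibrary",
    "GroundTruth",
    "TraceSpec",
    "TraceCollection",
    "ReadSimulation",
    "make_library",
    "make_ground_truth",
    "simulate_reads",
    "simulate_trace",
    "simulate_cell_population",
]

CLASSES = ("cardiomyocyte", "endothelial", "esc")

#: Constant priming site placed between the enhancer and the barcode in the
#: simulated amplicon.  Arbitrary 16-mer; any >= 8 bp sequence works.
DEFAULT_ANCHOR = "CTACGAGTCCGGAACT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n random DNA strings of the given length (vectorized)."""
    if n == 0 or length == 0:
        return [""] * n
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [s.decode("ascii") for s in arr.view(f"S{length}").ravel()]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconLayout:
    """Geometry of the barcode within an amplicon read.

    The forward priming site (``anchor``) sits between the enhancer and the
    barcode; the barcode starts ``barcode_offset`` bases after the anchor
    ends (0-based, half-open coordinates).  If ``orientation`` is
    ``"reverse_complement"``, reads are reverse-complemented before the
    anchor search.
    """

    anchor: str = DEFAULT_ANCHOR
    barcode_offset: int = 0
    barcode_length: int = 16
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if len(self.anchor) < 8:
            raise ValueError("anchor must be at least 8 bases")
        if set(self.anchor) - set("ACGT"):
            raise ValueError("anchor must be an ACGT string")
        if self.barcode_offset < 0:
            raise ValueError("barcode_offset must be >= 0")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if self.orientation not in ("forward", "reverse_complement"):
            raise ValueError("orientation must be 'forward' or 'reverse_complement'")


@dataclass
class EnhancerLibrary:
    """Enhancer <-> barcode manifest with class labels.

    ``entries`` has columns ``enhancer_id``, ``class``, ``barcode`` and
    optionally ``promoter_id`` (episomal mode: one row per
    promoter–enhancer pair) and ``sequence``.  Barcodes are unique across
    the library and all have the same length.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries.reset_index(drop=True)
        required = {"enhancer_id", "class", "barcode"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"library manifest missing columns: {sorted(missing)}")
        if len(df):
            bad = set(df["class"]) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown enhancer classes: {sorted(bad)}")
            if df["barcode"].duplicated().any():
                raise ValueError("barcodes must be unique across the library")
            if df["barcode"].str.len().nunique() > 1:
                raise ValueError("all barcodes must have the same length")
            if "promoter_id" in df.columns and df["promoter_id"].isna().any():
                if not df["promoter_id"].isna().all():
                    raise ValueError("promoter_id must be present for all entries or none")
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcode_length(self) -> int:
        if not len(self.entries):
            raise ValueError("empty library has no barcode length")
        return len(self.entries["barcode"].iloc[0])

    @property
    def episomal(self) -> bool:
        return "promoter_id" in self.entries.columns and len(self.entries) > 0

    @property
    def entry_ids(self) -> pd.Series:
        """Unique key per entry: enhancer_id, or promoter:enhancer in episomal mode."""
        if self.episomal:
            return self.entries["promoter_id"] + ":" + self.entries["enhancer_id"]
        return self.entries["enhancer_id"]

    def barcode_map(self) -> dict[str, str]:
        """barcode -> entry id."""
        return dict(zip(self.entries["barcode"], self.entry_ids))

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnhancerLibrary":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class GroundTruth:
    """Programmed simulation truth for an MPRA library.

    ``activity`` maps entry id -> programmed RNA:DNA ratio (> 0);
    ``dna_frequency`` maps entry id -> probability (sums to 1).
    """

    activity: dict[str, float]
    dna_frequency: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.activity) != set(self.dna_frequency):
            raise ValueError("activity and dna_frequency must share the same entry ids")
        if any(a <= 0 for a in self.activity.values()):
            raise ValueError("all programmed activities must be > 0")
        total = sum(self.dna_frequency.values())
        if self.dna_frequency and abs(total - 1.0) > 1e-9:
            raise ValueError(f"dna_frequency must sum to 1 (got {total!r})")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "activity": self.activity,
            "dna_frequency": self.dna_frequency,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(payload["activity"], payload["dna_frequency"], payload.get("seed", 0))


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a simulated paced calcium transient recording.

    Defaults emulate the study conditions: 2 Hz field pacing with the last
    five cycles recorded, sampled at 100 Hz.  Amplitude is in dF/F0 units
    above a diastolic baseline of 1.0; ``decay_tau`` is the
    single-exponential decay constant (0.2 s gives a peak-to-50%-decay time
    of tau*ln 2 ~ 0.139 s, typical of adult mouse cardiomyocytes at 2 Hz);
    ``drift_magnitude`` is an additive drift slope in F units per second
    (negative = photobleaching); ``alternans_ratio`` scales every second
    beat (even-indexed beats 0, 2, 4, ...), 1.0 meaning no alternans.
    """

    pacing_hz: float = 2.0
    n_cycles: int = 5
    sample_rate: float = 100.0
    amplitude: float = 1.0
    decay_tau: float = 0.2
    upstroke_time: float = 0.05
    drift_kind: str = "linear"
    drift_magnitude: float = -0.04
    noise_sd: float = 0.02
    alternans_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pacing_hz <= 0:
            raise ValueError("pacing_hz must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sample_rate <= 2 * self.pacing_hz:
            raise ValueError("sample_rate must exceed twice the pacing rate")
        if not (0 < self.alternans_ratio <= 1):
            raise ValueError("alternans_ratio must be in (0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if not (0 < self.upstroke_time < 1.0 / self.pacing_hz):
            raise ValueError("upstroke_time must lie within one pacing period")
        if self.drift_kind not in ("linear", "exponential", "none"):
            raise ValueError("drift_kind must be linear, exponential or none")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Library and ground truth
# ---------------------------------------------------------------------------


def make_library(
    n_cm: int,
    n_endo: int,
    n_esc: int,
    barcode_length: int = 16,
    seed: int = 0,
    promoters: Sequence[str] | None = None,
    with_sequences: bool = False,
) -> EnhancerLibrary:
    """Random barcoded enhancer library with class labels.

    Barcodes are uniform random over {A,C,G,T}^L with rejection of
    duplicates.  With ``promoters`` given (episomal mode) every enhancer is
    paired with every promoter and each pair receives its own barcode.

    Raises
    ------
    ValueError
        If the barcode space cannot accommodate the library (duplicate
        collisions persist after bounded retries).
    """
    for name, n in (("n_cm", n_cm), ("n_endo", n_endo), ("n_esc", n_esc)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    if barcode_length < 6:
        raise ValueError("barcode_length must be >= 6")

    ids: list[str] = []
    classes: list[str] = []
    for prefix, klass, n in (
        ("CM", "cardiomyocyte", n_cm),
        ("EC", "endothelial", n_endo),
        ("ESC", "esc", n_esc),
    ):
        ids.extend(f"{prefix}{i + 1:02d}" for i in range(n))
        classes.extend([klass] * n)

    if promoters is not None:
        pairs = [(p, e, k) for p in promoters for e, k in zip(ids, classes)]
    else:
        pairs = [(None, e, k) for e, k in zip(ids, classes)]

    n_entries = len(pairs)
    if n_entries > 4**barcode_length:
        raise ValueError(
            f"barcode space 4^{barcode_length} too small for {n_entries} entries"
        )

    rng = child_rng(seed, "library")
    barcodes: list[str] = []
    seen: set[str] = set()
    max_attempts = 10 * n_entries + 100
    attempts = 0
    while len(barcodes) < n_entries:
        if attempts >= max_attempts:
            raise ValueError(
                "could not generate unique barcodes: barcode space too small "
                f"for {n_entries} entries of length {barcode_length}"
            )
        # draw in batches; rejected duplicates count as attempts
        batch = _random_seqs(rng, n_entries - len(barcodes), barcode_length)
        for bc in batch:
            attempts += 1
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)

    df = pd.DataFrame(
        {
            "enhancer_id": [e for _, e, _ in pairs],
            "class": [k for _, _, k in pairs],
            "barcode": barcodes,
        }
    )
    if promoters is not None:
        df.insert(2, "promoter_id", [p for p, _, _ in pairs])
    if with_sequences:
        df["sequence"] = _random_seqs(rng, n_entries, 400)
    return EnhancerLibrary(df)


def make_ground_truth(
    library: EnhancerLibrary,
    seed: int = 0,
    class_mean_activity: Mapping[str, float] | None = None,
    activity_sigma: float = 0.5,
    dna_freq_sigma: float = 0.5,
) -> GroundTruth:
    """Programmed activities and DNA frequencies for a library.

    Per-entry activities are log-normal within each class and then rescaled
    so that each class's arithmetic mean equals ``class_mean_activity``
    exactly (default cardiomyocyte 4.5, endothelial 1.0, esc 1.0 — a
    4.5-fold cardiomyocyte : endothelial class-mean ratio).  DNA
    frequencies are log-normal across entries (realistic library skew) and
    renormalized to sum to 1.
    """
    if not len(library):
        raise ValueError("cannot build ground truth for an empty library")
    means = {"cardiomyocyte": 4.5, "endothelial": 1.0, "esc": 1.0}
    if class_mean_activity:
        means.update(class_mean_activity)

    rng = child_rng(seed, "truth")
    ids = library.entry_ids.to_numpy()
    classes = library.entries["class"].to_numpy()

    raw = rng.lognormal(mean=0.0, sigma=activity_sigma, size=len(ids))
    activity = np.empty_like(raw)
    for klass in CLASSES:
        mask = classes == klass
        if mask.any():
            activity[mask] = raw[mask] * (means[klass] / raw[mask].mean())

    freq = rng.lognormal(mean=0.0, sigma=dna_freq_sigma, size=len(ids))
    freq /= freq.sum()

    return GroundTruth(
        activity=dict(zip(ids, activity.tolist())),
        dna_frequency=dict(zip(ids, freq.tolist())),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


class ReadSimulation:
    """Lazily generated RNA and DNA amplicon read sets with known truth.

    Reads for each analyte are drawn multinomially (DNA from the programmed
    DNA frequencies, RNA from frequencies proportional to DNA frequency x
    activity), plus ``round(anchorless_fraction * depth)`` junk reads that
    contain no anchor.  Read order is shuffled.  Iteration and FASTQ output
    are chunked so that arbitrarily deep simulations stay in constant
    memory, and regenerate identically on every pass.
    """

    _CHUNK = 100_000

    def __init__(
        self,
        library: EnhancerLibrary,
        truth: GroundTruth,
        layout: AmpliconLayout,
        depth_rna: int,
        depth_dna: int,
        dropout: Iterable[str] = (),
        anchorless_fraction: float = 0.0,
        read_length: int | None = None,
        error_rate: float = 0.0,
        seed: int | None = None,
    ) -> None:
        if depth_rna <= 0 or depth_dna <= 0:
            raise ValueError("read depths must be positive")
        if not (0 <= anchorless_fraction < 1):
            raise ValueError("anchorless_fraction must be in [0, 1)")
        if not (0 <= error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if layout.barcode_length != library.barcode_length:
            raise ValueError("layout barcode_length does not match the library")
        dropout = frozenset(dropout)
        known = set(library.entry_ids)
        if dropout - known:
            raise ValueError(f"dropout ids not in library: {sorted(dropout - known)}")

        self.library = library
        self.truth = truth
        self.layout = layout
        self.dropout = dropout
        self.anchorless_fraction = float(anchorless_fraction)
        self.error_rate = float(error_rate)
        self.seed = truth.seed if seed is None else int(seed)

        min_len = len(layout.anchor) + layout.barcode_offset + layout.barcode_length
        self.read_length = min_len + 10 if read_length is None else int(read_length)
        if self.read_length < min_len:
            raise ValueError(f"read_length must be >= {min_len} for this layout")

        ids = library.entry_ids.to_numpy()
        dna_p = np.array([truth.dna_frequency[i] for i in ids])
        dna_p[np.isin(ids, list(dropout))] = 0.0
        if dna_p.sum() <= 0:
            raise ValueError("dropout removes all DNA mass")
        act = np.array([truth.activity[i] for i in ids])
        rna_p = dna_p * act
        self._ids = ids
        self._barcodes = library.entries["barcode"].to_numpy()
        self._p = {"DNA": dna_p / dna_p.sum(), "RNA": rna_p / rna_p.sum()}
        self._depth = {"RNA": int(depth_rna), "DNA": int(depth_dna)}

        self._counts: dict[str, np.ndarray] = {}
        self._n_junk: dict[str, int] = {}
        for analyte in ("RNA", "DNA"):
            depth = self._depth[analyte]
            n_junk = int(round(self.anchorless_fraction * depth))
            rng = child_rng(self.seed, "counts", analyte)
            self._counts[analyte] = rng.multinomial(depth - n_junk, self._p[analyte])
            self._n_junk[analyte] = n_junk

    # -- ground truth accessors -------------------------------------------

    def true_counts(self, analyte: str) -> pd.Series:
        """Multinomially drawn barcode counts for one analyte (per entry id)."""
        return pd.Series(self._counts[analyte], index=self._ids, name=analyte)

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for analyte in ("RNA", "DNA"):
            rows.append(
                {
                    "sample_id": analyte.lower(),
                    "analyte": analyte,
                    "n_reads": self._depth[analyte],
                    "n_anchorless": self._n_junk[analyte],
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)

    # -- read generation ---------------------------------------------------

    def _assemble(self, rng: np.random.Generator, entry_idx: np.ndarray) -> list[str]:
        """Build reads for a chunk of entry indices (-1 = anchorless junk)."""
        n = len(entry_idx)
        lay = self.layout
        n_pad = self.read_length - (
            len(lay.anchor) + lay.barcode_offset + lay.barcode_length
        )
        fillers = _random_seqs(rng, n, lay.barcode_offset)
        pads = _random_seqs(rng, n, n_pad)
        junk_needed = int((entry_idx < 0).sum())
        junk = _random_seqs(rng, junk_needed, self.read_length)
        # junk must genuinely lack the anchor in the searched orientation
        for k, seq in enumerate(junk):
            while lay.anchor in seq or lay.anchor in _revcomp(seq):
                seq = _random_seqs(rng, 1, self.read_length)[0]
            junk[k] = seq
        out: list[str] = []
        j = 0
        for k, idx in enumerate(entry_idx):
            if idx < 0:
                out.append(junk[j])
                j += 1
                continue
            read = lay.anchor + fillers[k] + self._barcodes[idx] + pads[k]
            if lay.orientation == "reverse_complement":
                read = _revcomp(read)
            out.append(read)
        if self.error_rate > 0:
            out = self._mutate(rng, out)
        return out

    def _mutate(self, rng: np.random.Generator, reads: list[str]) -> list[str]:
        arr = np.frombuffer("".join(reads).encode("ascii"), dtype="S1").reshape(
            len(reads), self.read_length
        ).copy()
        mask = rng.random(arr.shape) < self.error_rate
        if mask.any():
            # shift by 1..3 in base space so the substituted base always differs
            code = np.zeros(arr.shape, dtype=np.int8)
            for i, b in enumerate(b"ACGT"):
                code[arr == bytes([b])] = i
            shift = rng.integers(1, 4, size=arr.shape)
            code = np.where(mask, (code + shift) % 4, code)
            arr = _BASES[code]
        w = self.read_length
        return [s.decode("ascii") for s in arr.view(f"S{w}").ravel()]

    def iter_reads(self, analyte: str) -> Iterator[tuple[str, str, str]]:
        """Yield (read_id, sequence, quality) in a seeded shuffled order."""
        counts = self._counts[analyte]
        n_junk = self._n_junk[analyte]
        order_rng = child_rng(self.seed, "order", analyte)
        entry_idx = np.repeat(np.arange(len(counts)), counts)
        entry_idx = np.concatenate([entry_idx, np.full(n_junk, -1, dtype=entry_idx.dtype)])
        entry_idx = order_rng.permutation(entry_idx)
        seq_rng = child_rng(self.seed, "seq", analyte)
        qual = "I" * self.read_length
        for start in range(0, len(entry_idx), self._CHUNK):
            chunk = entry_idx[start : start + self._CHUNK]
            for offset, seq in enumerate(self._assemble(seq_rng, chunk)):
                yield f"{analyte}_{start + offset}", seq, qual

    def write_fastq(self, path: str | Path, analyte: str) -> None:
        """Write one analyte as 4-line FASTQ (gzipped if path ends in .gz)."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for read_id, seq, qual in self.iter_reads(analyte):
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def simulate_reads(
    library: EnhancerLibrary,
    truth: GroundTruth,
    layout: AmpliconLayout,
    depth_rna: int,
    depth_dna: int,
    dropout: Iterable[str] = (),
    anchorless_fraction: float = 0.0,
    read_length: int | None = None,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> ReadSimulation:
    """Simulate paired RNA/DNA amplicon read sets for a barcoded library.

    See :class:`ReadSimulation` for the sampling model.  ``dropout`` entries
    (e.g. an enhancer lost to failed synthesis) receive zero reads in both
    analytes; ``anchorless_fraction`` of each analyte's depth is emitted as
    junk reads without the priming site.
    """
    return ReadSimulation(
        library,
        truth,
        layout,
        depth_rna,
        depth_dna,
        dropout=dropout,
        anchorless_fraction=anchorless_fraction,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Calcium trace simulation
# ---------------------------------------------------------------------------


def simulate_trace(spec: TraceSpec, cell_id: str = "cell", group: str = "") -> CalciumTrace:
    """Simulate one paced calcium transient recording.

    The noiseless signal has diastolic baseline 1.0 and, per beat ``k``
    starting at ``k / pacing_hz``, a linear upstroke of duration
    ``upstroke_time`` from the instantaneous value to
    ``1 + amplitude * a_k`` followed by exponential relaxation toward
    baseline with time constant ``decay_tau``; ``a_k`` is
    ``alternans_ratio`` for even-indexed beats and 1 otherwise.  Additive
    drift and Gaussian noise are applied afterward.
    """
    dt = 1.0 / spec.sample_rate
    period = 1.0 / spec.pacing_hz
    duration = spec.n_cycles * period
    t = np.arange(0.0, duration - dt / 2, dt)
    y = np.full_like(t, 1.0)

    v_start = 1.0
    for k in range(spec.n_cycles):
        factor = spec.alternans_ratio if k % 2 == 0 else 1.0
        apex = 1.0 + spec.amplitude * factor
        t0 = k * period
        t_apex = t0 + spec.upstroke_time
        up = (t >= t0) & (t < t_apex)
        if spec.upstroke_time > 0:
            y[up] = v_start + (apex - v_start) * (t[up] - t0) / spec.upstroke_time
        decay = (t >= t_apex) & (t < t0 + period)
        y[decay] = 1.0 + (apex - 1.0) * np.exp(-(t[decay] - t_apex) / spec.decay_tau)
        v_start = 1.0 + (apex - 1.0) * math.exp(
            -(period - spec.upstroke_time) / spec.decay_tau
        )

    if spec.drift_kind == "linear" and spec.drift_magnitude != 0.0:
        y = y + spec.drift_magnitude * t
    elif spec.drift_kind == "exponential" and spec.drift_magnitude != 0.0:
        # saturating drift with initial slope = drift_magnitude
        tau_d = duration
        y = y + spec.drift_magnitude * tau_d * (1.0 - np.exp(-t / tau_d))

    if spec.noise_sd > 0:
        rng = child_rng(spec.seed, "trace")
        y = y + rng.normal(0.0, spec.noise_sd, size=len(t))

    return CalciumTrace(
        time=t, intensity=y, pacing_hz=spec.pacing_hz, cell_id=cell_id, group=group
    )


@dataclass
class TraceCollection:
    """Labelled collection of per-cell traces plus a parameter manifest."""

    traces: list[CalciumTrace]
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __iter__(self) -> Iterator[CalciumTrace]:
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def to_csv(self, traces_path: str | Path, groups_path: str | Path | None = None) -> None:
        """Write wide trace CSV (time column + one column per cell) and a group map."""
        if not self.traces:
            raise ValueError("empty trace collection")
        t0 = self.traces[0].time
        data = {"time": t0}
        for tr in self.traces:
            if len(tr.time) != len(t0):
                raise ValueError("traces of unequal length cannot share one CSV grid")
            data[tr.cell_id] = tr.intensity
        pd.DataFrame(data).to_csv(traces_path, index=False)
        if groups_path is not None:
            pd.DataFrame(
                {
                    "cell_id": [tr.cell_id for tr in self.traces],
                    "group": [tr.group for tr in self.traces],
                }
            ).to_csv(groups_path, index=False)

    @classmethod
    def from_csv(
        cls,
        traces_path: str | Path,
        groups_path: str | Path | None = None,
        pacing_hz: float = 2.0,
    ) -> "TraceCollection":
        wide = pd.read_csv(traces_path)
        if "time" not in wide.columns:
            raise ValueError("trace CSV must have a 'time' column")
        groups: dict[str, str] = {}
        if groups_path is not None:
            gdf = pd.read_csv(groups_path, dtype=str)
            groups = dict(zip(gdf["cell_id"], gdf["group"]))
        t = wide["time"].to_numpy(float)
        traces = [
            CalciumTrace(
                time=t,
                intensity=wide[c].to_numpy(float),
                pacing_hz=pacing_hz,
                cell_id=str(c),
                group=groups.get(str(c), ""),
            )
            for c in wide.columns
            if c != "time"
        ]
        return cls(traces, pd.DataFrame())


def simulate_cell_population(
    n_cells_per_group: int,
    group_specs: Mapping[str, TraceSpec],
    seed: int = 0,
    jitter: float = 0.0,
) -> TraceCollection:
    """Simulate a labelled population of cells, one TraceSpec per group.

    Each cell receives an independent seed derived from the master seed via
    the (group index, cell index) spawn key, so any single cell regenerates
    identically in isolation.  With ``jitter`` > 0 the per-cell amplitude
    and decay constant are multiplied by log-normal factors with that
    coefficient of variation; realized parameters are recorded in the
    manifest.
    """
    if n_cells_per_group < 1:
        raise ValueError("n_cells_per_group must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    traces: list[CalciumTrace] = []
    rows = []
    for gi, (group, spec) in enumerate(group_specs.items()):
        for ci in range(n_cells_per_group):
            cell_seed = int(
                child_rng(seed, "cell", gi, ci).integers(0, 2**31 - 1)
            )
            cell_spec = replace(spec, seed=cell_seed)
            if jitter > 0:
                jrng = child_rng(seed, "jitter", gi, ci)
                amp_f, tau_f = jrng.lognormal(0.0, jitter, size=2)
                cell_spec = replace(
                    cell_spec,
                    amplitude=spec.amplitude * amp_f,
                    decay_tau=spec.decay_tau * tau_f,
                )
            cell_id = f"{group}_c{ci + 1:03d}"
            traces.append(simulate_trace(cell_spec, cell_id=cell_id, group=group))
            rows.append(
                {
                    "cell_id": cell_id,
                    "group": group,
                    "seed": cell_seed,
                    "amplitude": cell_spec.amplitude,
                    "decay_tau": cell_spec.decay_tau,
                    "alternans_ratio": cell_spec.alternans_ratio,
                    "noise_sd": cell_spec.noise_sd,
                    "drift_kind": cell_spec.drift_kind,
                    "drift_magnitude": cell_spec.drift_magnitude,
                }
            )
    return TraceCollection(traces, pd.DataFrame(rows))
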