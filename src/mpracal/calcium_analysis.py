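"""Cardiomyocyte calcium-transient analysis.

Per-cell pipeline for paced calcium-indicator fluorescence traces:

1. :func:`qc_admit` — exclude cells whose recording terminated before the
   required number of full pacing cycles, or that contain non-finite data.
2. :func:`preprocess` — remove photobleaching by fitting a trend to
   late-diastolic baseline estimates and dividing it out, apply a median
   filter, and normalize to dF/F0 (diastolic baseline = 0).
3. :func:`detect_peaks` — prominence-based local-maximum detection.
4. :func:`transient_metrics` — per-beat amplitude, maximal upstroke and
   downstroke velocities, and time from peak to 50% decay.
5. :func:`classify_low_peaks` — count peaks whose height falls within a
   fractional band (default 10–94%) of the cell's reference peak height;
   cells with >= 3 such "low peaks" are flagged (a stringent definition
   under which beat-to-beat amplitude alternation stands out).
6. :func:`peak_variation` — fit a straight line to the peak (time, height)
   coordinates and report each peak's distance from the line normalized to
   its height; the per-cell score is the mean normalized deviation.  The
   line absorbs slow monotone trends (residual bleaching, run-down), so the
   score isolates genuine beat-to-beat variability such as alternans.

:func:`analyze_population` orchestrates the pipeline over a labelled
collection of cells and emits tidy per-cell and group-level tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

__all__ = [
    "CalciumTrace",
    "QCResult",
    "PeakSet",
    "AnomalyReport",
    "AnalysisConfig",
    "PopulationResult",
    "qc_admit",
    "preprocess",
    "detect_peaks",
    "transient_metrics",
    "classify_low_peaks",
    "peak_variation",
    "anomaly_report",
    "analyze_population",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CalciumTrace:
    """Uniformly sampled fluorescence time series for one cell."""

    time: np.ndarray
    intensity: np.ndarray
    pacing_hz: float
    cell_id: str = "cell"
    group: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("time and intensity must be 1-D")
        if len(self.time) != len(self.intensity):
            raise ValueError("time and intensity must have equal length")
        if len(self.time) < 2:
            raise ValueError("a trace needs at least 2 samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > 1e-6 * max(dt, 1.0)):
            raise ValueError("time must be uniformly spaced")
        if self.pacing_hz <= 0:
            raise ValueError("pacing_hz must be > 0")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Span covered by the samples, inclusive of the last interval."""
        return float(self.time[-1] - self.time[0]) + self.dt


@dataclass(frozen=True)
class QCResult:
    admitted: bool
    reason: str | None = None


@dataclass
class PeakSet:
    """Detected peak coordinates on a preprocessed (dF/F0) trace."""

    times: np.ndarray
    heights: np.ndarray
    baseline_value: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.times) != len(self.heights):
            raise ValueError("times and heights must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AnomalyReport:
    """Low-peak classification plus peak-amplitude-variation statistic."""

    n_low_peaks: int
    multi_low_flag: bool
    low_band: tuple[float, float]
    per_peak_deviation: np.ndarray
    variation_score: float
    reference_height: float = float("nan")
    reason: str | None = None


@dataclass
class AnalysisConfig:
    """Knobs of the per-cell pipeline.

    ``min_prominence``/``min_separation`` of None resolve per cell to 20% of
    the cell's maximal dF/F0 and 0.6 pacing periods respectively.
    """

    min_cycles: int = 5
    median_window: int = 5
    detrend: str = "linear"
    min_prominence: float | None = None
    min_separation: float | None = None
    low_band: tuple[float, float] = (0.10, 0.94)
    reference: str = "max"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.low_band = tuple(cfg.low_band)  # YAML lists -> tuple
        return cfg


@dataclass
class PopulationResult:
    per_cell: pd.DataFrame
    summary: pd.DataFrame
    rejected: pd.DataFrame


# ---------------------------------------------------------------------------
# QC and preprocessing
# ---------------------------------------------------------------------------


def qc_admit(trace: CalciumTrace, min_cycles: int = 5) -> QCResult:
    """Admit a trace only if it covers ``min_cycles`` full pacing cycles.

    Cells whose recording terminated early, or that contain non-finite
    samples, are rejected (a result, not an error).
    """
    if not np.all(np.isfinite(trace.intensity)):
        return QCResult(False, "non_finite")
    needed = min_cycles / trace.pacing_hz
    if trace.duration < needed - trace.dt:  # within one sample
        return QCResult(False, "too_few_cycles")
    return QCResult(True, None)


def _baseline_nodes(trace: CalciumTrace, late_fraction: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Late-diastolic baseline estimates: one (time, min value) per cycle.

    The minimum over the last ``late_fraction`` of each pacing period
    approximates the diastolic level just before the next upstroke, where
    the transient has relaxed furthest.
    """
    n = len(trace.time)
    period_samples = max(2, int(round(trace.pacing_hz**-1 / trace.dt)))
    t_nodes, v_nodes = [], []
    for start in range(0, n - period_samples + 1, period_samples):
        lo = start + int(math.ceil((1.0 - late_fraction) * period_samples))
        hi = start + period_samples
        window = trace.intensity[lo:hi]
        if len(window) == 0:
            continue
        k = lo + int(np.argmin(window))
        t_nodes.append(trace.time[k])
        v_nodes.append(trace.intensity[k])
    if not t_nodes:  # trace shorter than one period: fall back to global minimum
        k = int(np.argmin(trace.intensity))
        t_nodes, v_nodes = [trace.time[k]], [trace.intensity[k]]
    return np.asarray(t_nodes), np.asarray(v_nodes)


def preprocess(
    trace: CalciumTrace,
    median_window: int = 5,
    detrend: str = "linear",
) -> CalciumTrace:
    """Photobleach removal, median filtering and dF/F0 normalization.

    Order of operations: (1) fit the chosen trend (``linear`` or
    ``exponential``; ``none`` = constant) to the late-diastolic baseline
    estimates and divide it out (photobleaching acts multiplicatively on
    fluorescence), (2) median-filter, (3) subtract 1 so the diastolic
    baseline sits at 0 and values are dF/F0.
    """
    if median_window < 1 or median_window % 2 == 0:
        raise ValueError("median_window must be an odd integer >= 1")
    if median_window >= len(trace.time):
        raise ValueError("median_window must be smaller than the trace length")
    if detrend not in ("linear", "exponential", "none"):
        raise ValueError("detrend must be 'linear', 'exponential' or 'none'")

    t_nodes, v_nodes = _baseline_nodes(trace)
    if detrend == "linear" and len(t_nodes) >= 2:
        coef = np.polyfit(t_nodes, v_nodes, 1)
        baseline = np.polyval(coef, trace.time)
    elif detrend == "exponential" and len(t_nodes) >= 2:
        if np.any(v_nodes <= 0):
            raise ValueError("exponential detrend requires positive baseline values")
        coef = np.polyfit(t_nodes, np.log(v_nodes), 1)
        baseline = np.exp(np.polyval(coef, trace.time))
    else:
        baseline = np.full_like(trace.time, float(np.min(v_nodes)))
    if np.any(baseline <= 0):
        raise ValueError("fitted baseline is non-positive; cannot normalize")

    y = trace.intensity / baseline
    if median_window > 1:
        y = median_filter(y, size=median_window, mode="nearest")
    y = y - 1.0
    return CalciumTrace(
        time=trace.time,
        intensity=y,
        pacing_hz=trace.pacing_hz,
        cell_id=trace.cell_id,
        group=trace.group,
    )


# ---------------------------------------------------------------------------
# Peaks and per-beat metrics
# ---------------------------------------------------------------------------


def detect_peaks(
    trace: CalciumTrace,
    min_prominence: float | None = None,
    min_separation: float | None = None,
) -> PeakSet:
    """Prominence-based peak detection on a preprocessed trace.

    Defaults: prominence 20% of the trace maximum, separation 0.6 pacing
    periods.  Peak height is the dF/F0 value at the maximum (baseline is 0
    after preprocessing); maxima that do not rise above baseline are not
    peaks.
    """
    y = trace.intensity
    period = 1.0 / trace.pacing_hz
    if min_separation is None:
        min_separation = 0.6 * period
    if min_separation >= period:
        raise ValueError("min_separation must be below one pacing period")
    if min_prominence is None:
        ymax = float(np.max(y))
        if ymax <= 0:
            return PeakSet(np.empty(0), np.empty(0))
        min_prominence = 0.2 * ymax
    distance = max(1, int(round(min_separation / trace.dt)))
    idx, _ = find_peaks(y, prominence=min_prominence, distance=distance)
    idx = idx[y[idx] > 0]
    return PeakSet(times=trace.time[idx], heights=y[idx])


def transient_metrics(
    trace: CalciumTrace, peaks: PeakSet
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-beat transient metrics and their per-cell means.

    Per beat: amplitude = peak height; maximal upstroke and downstroke
    velocities = extrema of the first difference divided by the sample
    interval within the beat window (midpoint after the previous peak to
    the midpoint before the next); t50 = linearly interpolated time from
    the peak to the first crossing of half the peak height.  Beats whose
    decay never reaches 50% before the next beat window are flagged
    (``reached_50`` False) and excluded from the t50 mean.
    """
    if len(peaks) == 0:
        raise ValueError("transient_metrics requires at least one peak")
    y = trace.intensity
    t = trace.time
    dt = trace.dt
    peak_idx = np.searchsorted(t, peaks.times)
    peak_idx = np.clip(peak_idx, 0, len(t) - 1)
    # snap to the closer sample (searchsorted returns the right neighbour)
    for j, pi in enumerate(peak_idx):
        if pi > 0 and abs(t[pi - 1] - peaks.times[j]) < abs(t[pi] - peaks.times[j]):
            peak_idx[j] = pi - 1

    bounds = [0]
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        bounds.append(int((a + b) // 2))
    bounds.append(len(t))

    rows = []
    for j, pi in enumerate(peak_idx):
        w0, w1 = bounds[j], bounds[j + 1]
        seg = y[w0:w1]
        dy = np.diff(seg) / dt
        up = float(np.max(dy)) if len(dy) else float("nan")
        down = float(abs(np.min(dy))) if len(dy) else float("nan")
        height = peaks.heights[j]
        target = peaks.baseline_value + 0.5 * (height - peaks.baseline_value)
        t50 = float("nan")
        reached = False
        for i in range(pi + 1, w1):
            if y[i] <= target:
                if y[i - 1] == y[i]:
                    t_cross = t[i]
                else:
                    frac = (y[i - 1] - target) / (y[i - 1] - y[i])
                    t_cross = t[i - 1] + frac * dt
                t50 = float(t_cross - t[pi])
                reached = True
                break
        rows.append(
            {
                "beat": j,
                "t_peak": float(t[pi]),
                "amplitude": float(height),
                "max_upstroke_velocity": up,
                "max_downstroke_velocity": down,
                "t50_decay": t50,
                "reached_50": reached,
            }
        )
    per_beat = pd.DataFrame(rows)
    reached = per_beat[per_beat["reached_50"]]
    means = {
        "amplitude": float(per_beat["amplitude"].mean()),
        "max_upstroke_velocity": float(per_beat["max_upstroke_velocity"].mean()),
        "max_downstroke_velocity": float(per_beat["max_downstroke_velocity"].mean()),
        "t50_decay": float(reached["t50_decay"].mean()) if len(reached) else float("nan"),
    }
    return per_beat, means


# ---------------------------------------------------------------------------
# Anomalies
# ---------------------------------------------------------------------------


def _reference_height(peaks: PeakSet, reference: str) -> float:
    if reference == "max":
        ref = float(np.max(peaks.heights))
    elif reference == "median":
        ref = float(np.median(peaks.heights))
    else:
        raise ValueError("reference must be 'max' or 'median'")
    if ref == 0:
        raise ValueError("reference peak height is zero")
    return ref


def classify_low_peaks(
    peaks: PeakSet,
    low_band: tuple[float, float] = (0.10, 0.94),
    reference: str = "max",
) -> tuple[int, bool, float]:
    """Count "low peaks" and flag cells with three or more.

    A peak is low iff its height, as a fraction of the cell's reference
    height (default: the cell's maximum peak), lies within ``low_band``
    (endpoints inclusive).  Peaks below the band floor are not counted:
    they are failures of detection or quiescence, not the stringent
    "slightly short of normal" events of interest.

    Returns ``(n_low_peaks, multi_low_flag, reference_height)``.
    """
    if len(peaks) == 0:
        raise ValueError("classify_low_peaks requires at least one peak")
    lo, hi = low_band
    if not (0 <= lo < hi <= 1):
        raise ValueError("low_band must satisfy 0 <= lower < upper <= 1")
    ref = _reference_height(peaks, reference)
    ratio = peaks.heights / ref
    n_low = int(np.sum((ratio >= lo) & (ratio <= hi)))
    return n_low, n_low >= 3, ref


def peak_variation(peaks: PeakSet) -> tuple[np.ndarray, float, str | None]:
    """Peak-amplitude variation about the best-fit line.

    Fits an ordinary least-squares line to the (time, height) peak
    coordinates; each peak's deviation is its absolute vertical distance
    from the line normalized to its own height, and the per-cell score is
    the mean of those deviations.  With fewer than 3 peaks the line is not
    identifiable (zero residual by construction): returns NaN with a
    reason.

    Returns ``(per_peak_deviation, variation_score, reason)``.
    """
    if len(peaks) < 3:
        return np.full(len(peaks), np.nan), float("nan"), "fewer_than_3_peaks"
    if np.any(peaks.heights <= 0):
        return np.full(len(peaks), np.nan), float("nan"), "non_positive_height"
    coef = np.polyfit(peaks.times, peaks.heights, 1)
    fit = np.polyval(coef, peaks.times)
    dev = np.abs(peaks.heights - fit) / peaks.heights
    return dev, float(np.mean(dev)), None


def anomaly_report(
    peaks: PeakSet,
    low_band: tuple[float, float] = (0.10, 0.94),
    reference: str = "max",
) -> AnomalyReport:
    """Combined low-peak classification and variation statistic."""
    n_low, flag, ref = classify_low_peaks(peaks, low_band=low_band, reference=reference)
    dev, score, reason = peak_variation(peaks)
    return AnomalyReport(
        n_low_peaks=n_low,
        multi_low_flag=flag,
        low_band=tuple(low_band),
        per_peak_deviation=dev,
        variation_score=score,
        reference_height=ref,
        reason=reason,
    )


# ---------------------------------------------------------------------------
# Population orchestration
# ---------------------------------------------------------------------------


def analyze_population(
    traces: Iterable[CalciumTrace],
    config: AnalysisConfig | None = None,
) -> PopulationResult:
    """Run the full per-cell pipeline over a labelled trace collection.

    Each cell passes qc_admit -> preprocess -> detect_peaks ->
    transient_metrics -> anomaly_report; rejected cells (including cells
    with no detectable peaks) are listed with reasons.  The summary gives
    per-group means, the fraction of cells flagged for multiple low peaks,
    and cell counts.

    Raises
    ------
    ValueError
        If every cell of some group is rejected.
    """
    config = config or AnalysisConfig()
    cell_rows, reject_rows = [], []
    groups_seen: dict[str, int] = {}
    for trace in traces:
        groups_seen.setdefault(trace.group, 0)
        qc = qc_admit(trace, min_cycles=config.min_cycles)
        if not qc.admitted:
            reject_rows.append(
                {"cell_id": trace.cell_id, "group": trace.group, "reason": qc.reason}
            )
            continue
        pre = preprocess(
            trace, median_window=config.median_window, detrend=config.detrend
        )
        peaks = detect_peaks(
            pre,
            min_prominence=config.min_prominence,
            min_separation=config.min_separation,
        )
        if len(peaks) == 0:
            reject_rows.append(
                {"cell_id": trace.cell_id, "group": trace.group, "reason": "no_peaks"}
            )
            continue
        _, means = transient_metrics(pre, peaks)
        report = anomaly_report(
            peaks, low_band=config.low_band, reference=config.reference
        )
        groups_seen[trace.group] += 1
        cell_rows.append(
            {
                "cell_id": trace.cell_id,
                "group": trace.group,
                "n_peaks": len(peaks),
                **means,
                "n_low_peaks": report.n_low_peaks,
                "multi_low_flag": report.multi_low_flag,
                "variation_score": report.variation_score,
            }
        )

    for group, n_ok in groups_seen.items():
        if n_ok == 0:
            raise ValueError(f"all cells of group {group!r} were rejected")

    per_cell = pd.DataFrame(cell_rows)
    rejected = pd.DataFrame(reject_rows, columns=["cell_id", "group", "reason"])
    agg = per_cell.groupby("group", sort=False)
    summary = agg.agg(
        n_cells=("cell_id", "count"),
        amplitude=("amplitude", "mean"),
        max_upstroke_velocity=("max_upstroke_velocity", "mean"),
        max_downstroke_velocity=("max_downstroke_velocity", "mean"),
        t50_decay=("t50_decay", "mean"),
        mean_n_low_peaks=("n_low_peaks", "mean"),
        multi_low_fraction=("multi_low_flag", "mean"),
        variation_score=("variation_score", "mean"),
    ).reset_index()
    return PopulationResult(per_cell=per_cell, summary=summary, rejected=rejected)
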