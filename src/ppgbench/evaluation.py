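"""Peak-detection scoring, heart-rate error metrics and Poincaré descriptors.

Detected systolic peaks are matched one-to-one against ground truth within
a ±50 ms tolerance; sensitivity = TP/(TP+FN) and precision = TP/(TP+FP).
Heart rate is derived from inter-peak intervals (instantaneous HR =
60 / IBI); the automatic-vs-truth comparison reports the absolute mean-HR
difference in BPM and the percent error, with 5% the conventional clinical
acceptability bound.  Beat-interval variability is summarized by the
Poincaré descriptors SD1 (short-term) and SD2 (long-term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import PeakSet

__all__ = [
    "MatchResult",
    "HRReport",
    "PoincareDescriptors",
    "InsufficientPeaksError",
    "match_peaks",
    "hr_from_peaks",
    "hr_error",
    "poincare",
    "benchmark_report",
    "CLINICAL_ERROR_PCT",
]

CLINICAL_ERROR_PCT = 5.0  # conventional acceptability bound for HR devices


class InsufficientPeaksError(ValueError):
    """Too few peaks for the requested statistic."""


@dataclass
class MatchResult:
    """Confusion counts of detected vs ground-truth peaks.

    ``precision`` is NaN (flagged, not 0) when there are no detections.
    """

    tp: int
    fp: int
    fn: int
    tolerance_s: float
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else math.nan

    @property
    def precision(self) -> float:
        total = self.tp + self.fp
        return self.tp / total if total else math.nan


@dataclass
class HRReport:
    """Instantaneous-HR series and its summary for one peak set."""

    hr_series_bpm: np.ndarray
    mean_hr_bpm: float
    sd_hr_bpm: float
    mean_hr_diff_bpm: float | None = None
    percent_error: float | None = None


@dataclass(frozen=True)
class PoincareDescriptors:
    """SD1/SD2 of the (RR_i, RR_{i+1}) scatter, in milliseconds."""

    sd1_ms: float
    sd2_ms: float
    n_points: int


def match_peaks(truth: PeakSet, detected: PeakSet,
                tolerance_s: float = 0.05) -> MatchResult:
    """One-to-one greedy matching of detected peaks to ground truth.

    Truth peaks are visited in increasing time order; each takes the
    nearest unmatched detected peak within ``±tolerance_s`` (inclusive).
    Unmatched truth peaks are false negatives, unmatched detections false
    positives, so ``tp + fn == |truth|`` and ``tp + fp == |detected|``.
    """
    t_truth = truth.times_s
    t_det = detected.times_s
    used = np.zeros(t_det.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, t in enumerate(t_truth):
        if t_det.size == 0:
            break
        dist = np.abs(t_det - t)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tolerance_s + 1e-12:
            used[j] = True
            pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=int(t_det.size - tp),
                       fn=int(t_truth.size - tp),
                       tolerance_s=tolerance_s, pairs=pairs)


def hr_from_peaks(peaks: PeakSet) -> HRReport:
    """Instantaneous heart rate from consecutive inter-peak intervals."""
    if len(peaks) < 2:
        raise InsufficientPeaksError(
            f"need at least 2 peaks for HR, got {len(peaks)}"
        )
    ibi = np.diff(peaks.times_s)
    hr = 60.0 / ibi
    return HRReport(hr_series_bpm=hr, mean_hr_bpm=float(hr.mean()),
                    sd_hr_bpm=float(hr.std(ddof=0)))


def hr_error(auto: HRReport, truth: HRReport) -> tuple[float, float]:
    """Absolute mean-HR difference (BPM) and percent error vs ground truth.

    ``percent = 100 * |mean_auto - mean_truth| / mean_truth``.
    """
    if truth.mean_hr_bpm == 0:
        raise ValueError("ground-truth mean HR is zero: error undefined")
    diff = abs(auto.mean_hr_bpm - truth.mean_hr_bpm)
    return diff, 100.0 * diff / truth.mean_hr_bpm


def poincare(peaks: PeakSet) -> PoincareDescriptors:
    """Poincaré SD1/SD2 of the beat-interval scatter.

    SD1 is the population SD of ``(RR_{i+1} - RR_i) / sqrt(2)`` (dispersion
    perpendicular to the identity line), SD2 of
    ``(RR_{i+1} + RR_i) / sqrt(2)`` (along it); both in ms.  For i.i.d.
    intervals SD1 equals the interval SD.
    """
    if len(peaks) < 3:
        raise InsufficientPeaksError(
            f"need at least 3 peaks for a Poincare plot, got {len(peaks)}"
        )
    rr = np.diff(peaks.times_s)
    x, y = rr[:-1], rr[1:]
    sd1 = float(((y - x) / np.sqrt(2)).std(ddof=0)) * 1000.0
    sd2 = float(((y + x) / np.sqrt(2)).std(ddof=0)) * 1000.0
    return PoincareDescriptors(sd1_ms=sd1, sd2_ms=sd2, n_points=x.size)


REPORT_COLUMNS = [
    "sensor", "segment", "pct_saturated", "mean_se", "mean_se_no_sat",
    "pcc", "cs", "ned", "sensitivity", "precision",
    "hr_diff_bpm", "pct_error", "error_flag",
]


def benchmark_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-sensor, per-segment benchmark rows into one table.

    Each row is a dict with any subset of ``REPORT_COLUMNS``; missing
    metrics stay NaN (stage failures are recorded in ``error_flag``
    instead of aborting the whole report).  An empty list yields an empty
    table with the standard columns.
    """
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df
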