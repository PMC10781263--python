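"""Preprocessing filter and two-moving-average systolic-peak detection.

The detector follows Elgendi's two-event-related-moving-average scheme:
the bandpass-filtered signal is half-wave rectified and squared, a short
"peak" moving average (window W1, sized to one systolic peak) is compared
against a long "beat" moving average (window W2, sized to one beat) plus a
small offset proportional to the signal energy, and each sufficiently wide
block where the peak average wins yields one systolic peak at the local
maximum of the filtered signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Signal

__all__ = [
    "FilterSpec",
    "ElgendiParams",
    "PeakSet",
    "bandpass",
    "elgendi_peaks",
    "find_onsets",
    "detect_peaks",
]


@dataclass(frozen=True)
class FilterSpec:
    """4th-order Butterworth bandpass, [1, 8] Hz, zero-phase by default."""

    order: int = 4
    band: tuple[float, float] = (1.0, 8.0)
    zero_phase: bool = True

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")


@dataclass(frozen=True)
class ElgendiParams:
    """Two-moving-average detector parameters.

    ``w1_s`` — peak moving-average window (seconds), sized to a systolic
    peak; ``w2_s`` — beat moving-average window; ``beta`` — offset fraction
    multiplying the mean of the squared signal in the dynamic threshold.
    """

    w1_s: float = 0.18
    w2_s: float = 0.69
    beta: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.w1_s < self.w2_s:
            raise ValueError("require 0 < w1_s < w2_s")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class PeakSet:
    """Systolic-peak sample indices with provenance."""

    indices: np.ndarray
    fs: float
    provenance: str = "automatic"  # automatic | manual | ground_truth

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    @classmethod
    def from_times(cls, times_s: np.ndarray, fs: float,
                   provenance: str = "ground_truth") -> "PeakSet":
        return cls(indices=np.rint(np.asarray(times_s) * fs).astype(np.int64),
                   fs=fs, provenance=provenance)


def bandpass(signal: Signal, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Bandpass-filter a signal; output length equals input length.

    Zero-phase (forward-backward) application by default so peak positions
    are not phase-shifted; this doubles the effective filter order.
    """
    low, high = spec.band
    if high >= signal.fs / 2:
        raise ValueError(
            f"band {spec.band} requires fs > {2 * high} Hz, got {signal.fs}"
        )
    sos = sps.butter(spec.order, spec.band, btype="bandpass",
                     fs=signal.fs, output="sos")
    x = np.asarray(signal.samples, float)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def _odd_window(seconds: float, fs: float) -> int:
    n = max(1, int(round(seconds * fs)))
    return n if n % 2 == 1 else n + 1


def _centered_ma(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with reflect padding of half the window."""
    half = width // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def interest_blocks(filtered: np.ndarray, fs: float,
                    params: ElgendiParams = ElgendiParams()
                    ) -> list[tuple[int, int]]:
    """Candidate systolic blocks of the two-moving-average scheme.

    Half-wave rectify and square the filtered signal; compare the centered
    W1 moving average against the W2 moving average plus
    ``beta * mean(squared)``; return the maximal runs where the peak
    average wins, keeping only runs at least W1 samples wide.  Runs are
    half-open ``(start, end)`` index pairs.
    """
    if filtered.size == 0:
        return []
    clipped = np.maximum(filtered, 0.0)
    squared = clipped ** 2
    w1 = _odd_window(params.w1_s, fs)
    w2 = _odd_window(params.w2_s, fs)
    ma_peak = _centered_ma(squared, w1)
    ma_beat = _centered_ma(squared, w2)
    thr1 = ma_beat + params.beta * squared.mean()
    active = ma_peak > thr1
    blocks: list[tuple[int, int]] = []
    min_width = max(1, int(round(params.w1_s * fs)))
    edges = np.diff(np.concatenate([[0], active.astype(np.int8), [0]]))
    for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        if e - s >= min_width:
            blocks.append((int(s), int(e)))
    return blocks


def elgendi_peaks(filtered: np.ndarray, fs: float,
                  params: ElgendiParams = ElgendiParams()) -> PeakSet:
    """Systolic peaks of a bandpass-filtered PPG signal.

    One peak per surviving interest block, at the argmax of the filtered
    signal within the block.
    """
    filtered = np.asarray(filtered, float)
    idx = [int(s + np.argmax(filtered[s:e]))
           for s, e in interest_blocks(filtered, fs, params)]
    return PeakSet(indices=np.asarray(idx, dtype=np.int64), fs=fs,
                   provenance="automatic")


def detect_peaks(signal: Signal, filter_spec: FilterSpec = FilterSpec(),
                 params: ElgendiParams = ElgendiParams()
                 ) -> tuple[PeakSet, np.ndarray]:
    """Convenience: bandpass then detect; returns (peaks, filtered)."""
    filtered = bandpass(signal, filter_spec)
    return elgendi_peaks(filtered, signal.fs, params), filtered


def find_onsets(filtered: np.ndarray, peaks: PeakSet,
                w2_s: float = 0.69) -> np.ndarray:
    """Pulse onsets (feet): the minimum preceding each systolic peak.

    For each peak the onset is the index of the minimum of the filtered
    signal in ``(previous peak, current peak]``; the first peak is searched
    within ``w2_s`` seconds before it.
    """
    filtered = np.asarray(filtered, float)
    if len(peaks) == 0:
        return np.asarray([], dtype=np.int64)
    onsets = []
    prev = None
    for pk in peaks.indices:
        if prev is None:
            start = max(0, int(pk - round(w2_s * peaks.fs)))
        else:
            start = int(prev) + 1
        seg = filtered[start:pk + 1]
        onsets.append(start + int(np.argmin(seg)))
        prev = pk
    return np.asarray(onsets, dtype=np.int64)
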