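"""Pulse-pair extraction, normalization, re-alignment and similarity metrics.

Pulse-wave morphology is compared one beat at a time: the beat is cut
onset-to-onset from each of two simultaneously recorded channels, min-max
normalized to [0, 1], resampled to a common length, re-synchronized by
cross-correlation (small residual lags arise from pulse transit between
measurement sites) and scored with three similarity metrics — Pearson
correlation, cosine similarity and the (unnormalized-by-length) Euclidean
distance between the normalized pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import PeakSet, find_onsets
from .quality import QualitySpec, spectral_entropy
from .signal_io import Signal

__all__ = [
    "PulsePair",
    "MorphologyResult",
    "DegeneratePulseError",
    "extract_pulse",
    "minmax_normalize",
    "align_lag",
    "pcc",
    "cosine_similarity",
    "ned",
    "compare_pulses",
]


class DegeneratePulseError(ValueError):
    """Constant (zero-range or zero-variance) pulse; metric undefined."""


@dataclass
class PulsePair:
    """A prepared (normalized, aligned, equal-length) pulse pair."""

    x: np.ndarray
    y: np.ndarray
    fs: float
    lag_applied_s: float


@dataclass(frozen=True)
class MorphologyResult:
    """Similarity of one aligned pulse pair."""

    pcc: float
    cs: float
    ned: float
    beat_index: int | None = None
    lag_s: float = 0.0


def extract_pulse(signal_or_samples: Signal | np.ndarray, peaks: PeakSet,
                  beat_index: int, onsets: np.ndarray | None = None
                  ) -> np.ndarray:
    """Samples of one beat, from its onset up to (excluding) the next onset.

    ``beat_index`` refers to the peak of that ordinal; it must have onsets
    on both sides, so the last beat is not extractable.
    """
    x = (np.asarray(signal_or_samples.samples, float)
         if isinstance(signal_or_samples, Signal)
         else np.asarray(signal_or_samples, float))
    if onsets is None:
        onsets = find_onsets(x, peaks)
    if not 0 <= beat_index < len(onsets) - 1:
        raise IndexError(
            f"beat {beat_index} lacks flanking onsets "
            f"(have {len(onsets)} onsets)"
        )
    return x[onsets[beat_index]:onsets[beat_index + 1]]


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; affine-invariant for positive scalings."""
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegeneratePulseError("constant sequence cannot be normalized")
    return (x - lo) / (hi - lo)


def _resample_to(x: np.ndarray, n: int) -> np.ndarray:
    if x.size == n:
        return x
    return np.interp(np.linspace(0, x.size - 1, n), np.arange(x.size), x)


def align_lag(x: np.ndarray, y: np.ndarray, fs: float,
              max_lag_s: float = 0.25) -> tuple[np.ndarray, np.ndarray, float]:
    """Re-synchronize two pulses by cross-correlation.

    The lag maximizing the cross-correlation of the mean-removed sequences
    within ``±max_lag_s`` is applied to ``y``; both are cropped to their
    common support (equal lengths).  Returns ``(x_aligned, y_aligned,
    lag_s)`` with positive lag meaning y trails x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = min(x.size, y.size)
    x = _resample_to(x, n)
    y = _resample_to(y, n)
    max_lag = min(int(round(max_lag_s * fs)), n - 2)

    def crop(k: int) -> tuple[np.ndarray, np.ndarray]:
        if k > 0:
            return x[:n - k], y[k:]
        if k < 0:
            return x[-k:], y[:n + k]
        return x, y

    # Pearson correlation of the overlapping parts at each candidate lag
    # (mean removed per overlap); positive lag means y is delayed relative
    # to x.  Ties break toward the smallest |lag|.
    best, best_score = 0, -np.inf
    for k in sorted(range(-max_lag, max_lag + 1), key=abs):
        xs, ys = crop(k)
        xc = xs - xs.mean()
        yc = ys - ys.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        if denom <= 0:
            continue
        score = float((xc * yc).sum() / denom)
        if score > best_score + 1e-12:
            best, best_score = k, score
    xa, ya = crop(best)
    return xa, ya, best / fs


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient: cov(x, y) / (sigma_x * sigma_y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise DegeneratePulseError("zero variance: PCC undefined")
    return float((xc * yc).sum() / denom)


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity: x . y / (||x|| ||y||)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        raise DegeneratePulseError("zero vector: cosine similarity undefined")
    return float(np.dot(x, y) / denom)


def ned(x_norm: np.ndarray, y_norm: np.ndarray) -> float:
    """Euclidean distance between min-max-normalized pulses.

    ``sqrt(sum((x' - y')**2))`` with no division by length, so the
    magnitude grows as sqrt(n); compare equal-length pulses only.
    """
    x_norm = np.asarray(x_norm, float)
    y_norm = np.asarray(y_norm, float)
    if x_norm.size != y_norm.size:
        raise ValueError("sequences must have equal length")
    return float(np.sqrt(((x_norm - y_norm) ** 2).sum()))


def _beat_quality(samples: np.ndarray, fs: float, peak_idx: int,
                  spec: QualitySpec) -> float:
    """Spectral entropy of the analysis window containing a peak (lower is
    more periodic); used to pick the best-quality shared beat."""
    win = int(round(spec.window_s * fs))
    w = peak_idx // win
    seg = samples[w * win:(w + 1) * win]
    if seg.size < win:  # trailing partial window: fall back to a centered one
        start = max(0, min(peak_idx - win // 2, samples.size - win))
        seg = samples[start:start + win]
    try:
        return spectral_entropy(seg, fs, spec.band)
    except ValueError:
        return np.inf


def compare_pulses(a: Signal | np.ndarray, peaks_a: PeakSet,
                   b: Signal | np.ndarray, peaks_b: PeakSet,
                   beat_index: int | None = None,
                   max_lag_s: float = 0.25,
                   quality_spec: QualitySpec = QualitySpec()
                   ) -> MorphologyResult:
    """Extract, normalize, re-align and score one pulse pair.

    When ``beat_index`` is None the beat whose containing analysis windows
    have the lowest combined spectral entropy (best periodic quality) among
    beats extractable from both channels is selected.
    """
    xa = (np.asarray(a.samples, float) if isinstance(a, Signal)
          else np.asarray(a, float))
    xb = (np.asarray(b.samples, float) if isinstance(b, Signal)
          else np.asarray(b, float))
    fs = peaks_a.fs
    onsets_a = find_onsets(xa, peaks_a)
    onsets_b = find_onsets(xb, peaks_b)
    n_shared = min(len(onsets_a), len(onsets_b)) - 1
    if n_shared < 1:
        raise IndexError("no beat with flanking onsets in both channels")
    if beat_index is None:
        scores = [
            _beat_quality(xa, fs, int(peaks_a.indices[k]), quality_spec)
            + _beat_quality(xb, fs, int(peaks_b.indices[k]), quality_spec)
            for k in range(n_shared)
        ]
        beat_index = int(np.argmin(scores))
    px = minmax_normalize(extract_pulse(xa, peaks_a, beat_index, onsets_a))
    py = minmax_normalize(extract_pulse(xb, peaks_b, beat_index, onsets_b))
    ax, ay, lag = align_lag(px, py, fs, max_lag_s)
    return MorphologyResult(pcc=pcc(ax, ay), cs=cosine_similarity(ax, ay),
                            ned=ned(ax, ay), beat_index=beat_index, lag_s=lag)
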