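"""Spectral-entropy signal-quality scoring.

A clean PPG signal is strongly periodic: its power in the cardiac band
concentrates in a few spectral lines, giving low Shannon entropy of the
normalized in-band spectrum.  Noise spreads power across the band and
drives the entropy toward 1.  Quality is scored per consecutive 4 s
window over the 1-3 Hz band (covering heart rates of 60-180 BPM) and a
signal whose mean spectral entropy exceeds 0.8 is flagged poor quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import Signal

__all__ = [
    "QualitySpec",
    "QualityReport",
    "UndefinedEntropyError",
    "InsufficientDataError",
    "normalized_entropy",
    "spectral_entropy",
    "quality_profile",
    "is_poor_quality",
]


class UndefinedEntropyError(ValueError):
    """No in-band power: spectral entropy is undefined for this window."""


class InsufficientDataError(ValueError):
    """Signal shorter than one analysis window (or all windows excluded)."""


@dataclass(frozen=True)
class QualitySpec:
    """Windowing and band for spectral-entropy quality scoring.

    Defaults: consecutive non-overlapping 4 s windows, 1-3 Hz band,
    poor-quality cut-off 0.8 (strictly greater than).  Within each window
    the power spectral density is a Welch average of 2 s rectangular
    segments with 75% overlap (0.5 Hz resolution, five bins in the default
    band); the averaging keeps the entropy of broadband noise near 1
    where a single raw periodogram would bias it low.
    """

    window_s: float = 4.0
    band: tuple[float, float] = (1.0, 3.0)
    poor_threshold: float = 0.8
    segment_s: float = 2.0
    segment_overlap: float = 0.75

    def __post_init__(self) -> None:
        f1, f2 = self.band
        if not 0 < f1 < f2:
            raise ValueError(f"band must satisfy 0 < f1 < f2, got {self.band}")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 < self.segment_s <= self.window_s:
            raise ValueError("segment_s must be in (0, window_s]")
        if not 0 <= self.segment_overlap < 1:
            raise ValueError("segment_overlap must be in [0, 1)")


@dataclass
class QualityReport:
    """Per-window spectral entropies and their aggregates for one signal."""

    window_se: np.ndarray
    mean_se: float
    mean_se_excluding_saturated: float | None
    n_windows: int
    n_excluded: int
    undefined_windows: list[int] = field(default_factory=list)


def normalized_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a discrete distribution, scaled to [0, 1].

    ``-sum(p * log2(p)) / log2(len(p))``; zero-probability bins contribute
    nothing.  Equals 0 for a point mass and 1 for the uniform distribution.
    """
    p = np.asarray(p, float)
    if p.size < 2:
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(p.size))


def spectral_entropy(window: np.ndarray, fs: float,
                     band: tuple[float, float] = (1.0, 3.0),
                     segment_s: float = 2.0,
                     segment_overlap: float = 0.75) -> float:
    """Spectral entropy of one window restricted to ``band``.

    The power spectral density is a Welch estimate (rectangular segments
    of ``segment_s`` seconds with fractional overlap ``segment_overlap``,
    mean removed); the PSD bins with ``f1 <= f <= f2`` (inclusive on both
    edges) are renormalized to sum to one and the Shannon entropy of that
    distribution, divided by ``log2`` of the number of in-band bins, is
    returned.  2 s segments give 0.5 Hz resolution, hence five bins for
    the default 1-3 Hz band.  ``segment_s`` longer than the window is
    capped at the window length (single-periodogram limit).
    """
    from scipy import signal as sps

    x = np.asarray(window, float)
    if x.size < 8:
        raise ValueError("window must contain at least 8 samples")
    f1, f2 = band
    if f2 > fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist frequency {fs / 2}")
    x = x - x.mean()
    nper = min(int(round(segment_s * fs)), x.size)
    freqs, psd = sps.welch(x, fs=fs, window="boxcar", nperseg=nper,
                           noverlap=int(nper * segment_overlap),
                           detrend="constant")
    # tolerance absorbs float round-off on the bin grid
    eps = 1e-9 * fs
    in_band = (freqs >= f1 - eps) & (freqs <= f2 + eps)
    power = psd[in_band]
    total = power.sum()
    if power.size == 0 or total <= 0:
        raise UndefinedEntropyError("no spectral power in the analysis band")
    return normalized_entropy(power / total)


def quality_profile(signal: Signal, spec: QualitySpec = QualitySpec(),
                    exclusion_mask: np.ndarray | None = None
                    ) -> QualityReport:
    """Spectral-entropy profile over consecutive non-overlapping windows.

    The trailing partial window is discarded.  Windows with undefined
    entropy (no in-band power) are flagged and excluded from both means.
    When ``exclusion_mask`` (per-window booleans, True = excluded, e.g.
    saturated windows) is given, ``mean_se_excluding_saturated`` is the
    mean over the remaining windows.
    """
    win = int(round(spec.window_s * signal.fs))
    x = np.asarray(signal.samples, float)
    n_windows = x.size // win
    if n_windows == 0:
        raise InsufficientDataError(
            f"signal ({x.size} samples) shorter than one {spec.window_s} s window"
        )
    if exclusion_mask is not None and len(exclusion_mask) != n_windows:
        raise ValueError(
            f"exclusion mask has {len(exclusion_mask)} entries, "
            f"expected {n_windows}"
        )
    se = np.full(n_windows, np.nan)
    undefined: list[int] = []
    for w in range(n_windows):
        try:
            se[w] = spectral_entropy(x[w * win:(w + 1) * win], signal.fs,
                                     spec.band, spec.segment_s,
                                     spec.segment_overlap)
        except UndefinedEntropyError:
            undefined.append(w)
    defined = ~np.isnan(se)
    if not defined.any():
        raise InsufficientDataError("every window has undefined entropy")
    mean_se = float(se[defined].mean())
    mean_excl: float | None = None
    n_excluded = 0
    if exclusion_mask is not None:
        keep = defined & ~np.asarray(exclusion_mask, bool)
        n_excluded = int(np.count_nonzero(exclusion_mask))
        if not keep.any():
            raise InsufficientDataError("all windows excluded by the mask")
        mean_excl = float(se[keep].mean())
    return QualityReport(
        window_se=se,
        mean_se=mean_se,
        mean_se_excluding_saturated=mean_excl,
        n_windows=n_windows,
        n_excluded=n_excluded,
        undefined_windows=undefined,
    )


def is_poor_quality(report: QualityReport,
                    spec: QualitySpec = QualitySpec()) -> bool:
    """True iff the signal's mean spectral entropy strictly exceeds the
    poor-quality cut-off (0.8 by default)."""
    return report.mean_se > spec.poor_threshold
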