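"""Saturation-threshold calibration and per-signal saturation quantification.

Sensor saturation at the ADC ceiling is gradual, not instantaneous: during
a driven calibration run the samples above a manually chosen initial
threshold spread well below their mean.  The calibrated ceiling is
therefore taken as the mean of those samples minus one standard deviation
(mu - 1*sigma), a deliberately conservative threshold that captures the
onset of the saturated regime.  Signals are then scored by the percentage
of samples at or above this final threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Signal

__all__ = [
    "SaturationProfile",
    "SaturationReport",
    "CalibrationError",
    "calibrate_threshold",
    "classify_saturation",
    "remove_saturated_windows",
]


class CalibrationError(ValueError):
    """Calibration signal contains no sample above the initial threshold."""


@dataclass(frozen=True)
class SaturationProfile:
    """Calibrated saturation ceiling plus the statistics that produced it.

    ``final_threshold = mean_above - sd_above`` with the population
    standard deviation (ddof=0) of the calibration samples strictly above
    ``initial_threshold``.
    """

    initial_threshold: float
    mean_above: float
    sd_above: float
    min_above: float
    max_above: float
    median_above: float
    final_threshold: float
    n_samples_above: int


@dataclass
class SaturationReport:
    """Per-signal saturation quantification against a calibrated profile."""

    percent_saturated: float
    mask: np.ndarray
    runs: list[tuple[int, int]]


def calibrate_threshold(calibration: Signal,
                        initial_threshold: float,
                        ddof: int = 0) -> SaturationProfile:
    """Apply the mu - 1*sigma rule to a driven calibration signal.

    Statistics are computed over the samples strictly above the manual
    ``initial_threshold``.  ``ddof=0`` (population SD) is the default;
    pass ``ddof=1`` for the sample convention.
    """
    x = np.asarray(calibration.samples, float)
    above = x[x > initial_threshold]
    if above.size == 0:
        raise CalibrationError(
            f"no calibration sample above initial threshold {initial_threshold}"
        )
    mean = float(above.mean())
    sd = float(above.std(ddof=ddof)) if above.size > ddof else 0.0
    return SaturationProfile(
        initial_threshold=float(initial_threshold),
        mean_above=mean,
        sd_above=sd,
        min_above=float(above.min()),
        max_above=float(above.max()),
        median_above=float(np.median(above)),
        final_threshold=mean - sd,
        n_samples_above=int(above.size),
    )


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True intervals as half-open (start, end) pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def classify_saturation(signal: Signal,
                        profile: SaturationProfile) -> SaturationReport:
    """Mark every sample at or above the calibrated final threshold.

    The comparison is inclusive (>=): the threshold is itself a saturation
    value.  ``percent_saturated`` is exactly ``100 * count / length``.
    """
    x = np.asarray(signal.samples, float)
    mask = x >= profile.final_threshold
    return SaturationReport(
        percent_saturated=100.0 * float(mask.sum()) / mask.size,
        mask=mask,
        runs=_runs_from_mask(mask),
    )


def remove_saturated_windows(signal: Signal, report: SaturationReport,
                             window_s: float) -> np.ndarray:
    """Per-window exclusion mask for saturation-free quality analysis.

    The signal is divided into consecutive non-overlapping windows of
    ``window_s`` seconds (trailing partial window dropped, matching the
    quality module's grid); a window is excluded when it contains at least
    one saturated sample.  Samples themselves are left untouched — windows
    are excluded rather than spliced out to avoid discontinuities.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * signal.fs))
    n_windows = len(signal) // win
    excluded = np.zeros(n_windows, dtype=bool)
    for w in range(n_windows):
        excluded[w] = report.mask[w * win:(w + 1) * win].any()
    return excluded
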