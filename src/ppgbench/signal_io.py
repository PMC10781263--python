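"""Recording data model, CSV I/O and cross-device optical synchronization.

A recording session involves one or more PPG channels sampled at a common
rate, optionally accompanied by an auxiliary light-sync channel: a brief
LED pulse fired by one acquisition device and picked up by a light sensor
on the other, so that the two devices' clocks can be aligned after the
fact.  Signals are stored as two-column CSV (``time_s,value``) with a JSON
sidecar carrying the acquisition metadata (sampling rate, ADC bit depth,
sensor label, anatomical site, device, segment labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Signal",
    "Recording",
    "SyncResult",
    "FormatError",
    "RangeError",
    "SyncError",
    "read_signal",
    "write_signal",
    "label_segments",
    "detect_sync_pulse",
    "align_recordings",
]

AT_REST = "at_rest"
MOVEMENT = "movement"


class FormatError(ValueError):
    """Malformed signal file (missing columns, non-monotonic time)."""


class RangeError(ValueError):
    """Sample value outside the declared ADC range."""


class SyncError(RuntimeError):
    """Synchronization pulse missing or undetectable."""


@dataclass
class Signal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Sample values (ADC codes or arbitrary physiological units).
    fs
        Sampling rate in Hz; must be positive.
    adc_bits
        ADC bit depth; when set, samples must lie in ``[0, 2**adc_bits - 1]``.
    sensor_label, site, device
        Free-text acquisition metadata.
    t0
        Start-time offset in seconds relative to the session origin.
    """

    samples: np.ndarray
    fs: float
    adc_bits: int | None = None
    sensor_label: str | None = None
    site: str | None = None
    device: str | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if self.adc_bits is not None:
            _check_adc_range(self.samples, self.adc_bits)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (``t0`` included)."""
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def adc_max(self) -> int | None:
        return None if self.adc_bits is None else (1 << self.adc_bits) - 1


@dataclass
class Recording:
    """A set of synchronously sampled channels plus sync channel and labels.

    ``labels`` is a list of half-open ``(start_s, end_s, label)`` intervals
    with label either ``"at_rest"`` or ``"movement"``.
    """

    signals: dict[str, Signal]
    aux_sync: Signal | None = None
    labels: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def fs(self) -> float:
        return next(iter(self.signals.values())).fs

    @property
    def duration_s(self) -> float:
        return max(s.duration_s for s in self.signals.values())


@dataclass(frozen=True)
class SyncResult:
    """Sample shift aligning device B onto device A's timebase."""

    offset_samples: int
    edge_a_s: float
    edge_b_s: float


def _check_adc_range(samples: np.ndarray, adc_bits: int) -> None:
    hi = (1 << adc_bits) - 1
    bad = np.flatnonzero((samples < 0) | (samples > hi))
    if bad.size:
        i = int(bad[0])
        raise RangeError(
            f"sample {i} = {samples[i]} outside ADC range [0, {hi}] "
            f"({adc_bits}-bit)"
        )


def read_signal(path: str | Path, sidecar: str | Path | None = None) -> Signal:
    """Read a ``time_s,value`` CSV plus JSON sidecar into a :class:`Signal`.

    If ``sidecar`` is omitted, ``<path stem>.json`` next to the CSV is used.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time_s column is not strictly increasing")
    meta = json.loads(Path(sidecar).read_text())
    values = df["value"].to_numpy()
    # integer ADC codes survive the round-trip bit-exactly
    if meta.get("adc_bits") is not None and np.allclose(values, np.round(values)):
        values = values.astype(np.int64)
    return Signal(
        samples=values,
        fs=float(meta["fs"]),
        adc_bits=meta.get("adc_bits"),
        sensor_label=meta.get("sensor_label"),
        site=meta.get("site"),
        device=meta.get("device"),
        t0=float(t[0]) if t.size else 0.0,
    )


def write_signal(signal: Signal, path: str | Path,
                 sidecar: str | Path | None = None) -> None:
    """Write ``signal`` as CSV + JSON sidecar; inverse of :func:`read_signal`."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    df = pd.DataFrame({"time_s": signal.times, "value": signal.samples})
    df.to_csv(path, index=False)
    meta = {
        "fs": signal.fs,
        "adc_bits": signal.adc_bits,
        "sensor_label": signal.sensor_label,
        "site": signal.site,
        "device": signal.device,
        "labels": None,
    }
    Path(sidecar).write_text(json.dumps(meta, indent=1))


def label_segments(recording: Recording, rest_duration_s: float) -> Recording:
    """Label the first ``rest_duration_s`` seconds at-rest, the rest movement.

    A recording shorter than the rest duration is labeled at-rest in full;
    ``rest_duration_s == 0`` labels everything movement.  Intervals are
    half-open ``[start, end)`` and partition the duration exactly.
    """
    if rest_duration_s < 0:
        raise ValueError("rest_duration_s must be non-negative")
    dur = recording.duration_s
    labels: list[tuple[float, float, str]] = []
    split = min(rest_duration_s, dur)
    if split > 0:
        labels.append((0.0, split, AT_REST))
    if split < dur:
        labels.append((split, dur, MOVEMENT))
    return replace(recording, labels=labels)


def detect_sync_pulse(aux: Signal, threshold_fraction: float = 0.5) -> float:
    """Time (s) of the first rising crossing of the sync pulse.

    The threshold is ``threshold_fraction`` of the channel's min-to-max
    excursion above its minimum, so the result is invariant to baseline
    offset and pulse amplitude.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    x = np.asarray(aux.samples, float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise SyncError("flat auxiliary channel: no sync pulse present")
    thr = lo + threshold_fraction * (hi - lo)
    above = x >= thr
    if not above.any():
        raise SyncError("no excursion above the sync threshold")
    idx = int(np.argmax(above))
    return aux.t0 + idx / aux.fs


def align_recordings(a: Recording, b: Recording,
                     threshold_fraction: float = 0.5) -> SyncResult:
    """Recover the sample offset between two devices from their sync pulses.

    The returned ``offset_samples = round((edge_b - edge_a) * fs)`` is the
    shift to subtract from device B's sample indices so the shared optical
    pulse coincides in both timebases.  Antisymmetric in its arguments.
    """
    if a.aux_sync is None or b.aux_sync is None:
        raise SyncError("both recordings need an aux_sync channel to align")
    edge_a = detect_sync_pulse(a.aux_sync, threshold_fraction)
    edge_b = detect_sync_pulse(b.aux_sync, threshold_fraction)
    fs = a.aux_sync.fs
    offset = int(np.rint((edge_b - edge_a) * fs))
    shorter = min(len(s) for r in (a, b) for s in r.signals.values())
    if abs(offset) >= shorter:
        raise SyncError(
            f"recovered offset {offset} exceeds the shorter recording length"
        )
    return SyncResult(offset_samples=offset, edge_a_s=edge_a, edge_b_s=edge_b)


def segment_slices(recording: Recording, fs: float | None = None
                   ) -> dict[str, slice]:
    """Sample-index slices for each labeled segment (helper for reporting)."""
    fs = fs or recording.fs
    return {
        lab: slice(int(round(s * fs)), int(round(e * fs)))
        for s, e, lab in recording.labels
    }
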