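"""Reading, writing and light preprocessing of three-channel biosensor traces.

A recording session produces three simultaneously sampled current traces
(pA, typically at 1,000 Hz): the GABA channel (GABASE + GOx coating, which
responds to both GABA and GLU), the GLU channel (GOx only) and an
enzyme-free sentinel channel that sees only electroactive interferents.
This module defines the in-memory containers for traces, stimulation /
behaviour event tables and calibration protocols, plus their canonical
on-disk forms (trace CSV, event and protocol JSON) and the moving-average
downsampling used for visualisation-scale analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesTrace",
    "StimEvent",
    "Epoch",
    "EventTable",
    "Addition",
    "CalibrationProtocol",
    "read_trace",
    "write_trace",
    "downsample_smooth",
    "moving_average",
]

#: Canonical channel order and CSV column names.
CHANNELS = ("gaba_raw", "glu_raw", "sentinel")
_COLUMNS = {
    "gaba_raw": "i_gaba_pA",
    "glu_raw": "i_glu_pA",
    "sentinel": "i_sentinel_pA",
}

#: Relative tolerance on sampling uniformity.
_UNIFORM_RTOL = 1e-6

STIM_KINDS = ("control_100ms", "train")


class FormatError(ValueError):
    """Malformed input file (missing column, non-uniform sampling, ...)."""


@dataclass
class TimeSeriesTrace:
    """Uniformly sampled three-channel current recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz). The acquisition system records at 1,000 Hz.
    channels : dict
        Maps each of ``gaba_raw``, ``glu_raw``, ``sentinel`` to a float
        array of currents in pA. All arrays share one length.
    t0 : float
        Time of the first sample in seconds.
    metadata : dict
        Free-form provenance (sensor id, session id, simulation seed...).
    """

    sampling_rate: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise FormatError(f"missing channel(s): {missing}")
        self.channels = {c: np.asarray(self.channels[c], dtype=float) for c in CHANNELS}
        n = {len(v) for v in self.channels.values()}
        if len(n) != 1 or min(n) < 1:
            raise ValueError("channel series must share one length >= 1")
        for name, v in self.channels.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite current in channel {name!r}")

    def __len__(self) -> int:
        return len(self.channels["gaba_raw"])

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at t0."""
        return self.t0 + np.arange(len(self)) / self.sampling_rate

    def slice(self, start: float, end: float) -> "TimeSeriesTrace":
        """Sub-trace covering [start, end] seconds (inclusive of edges)."""
        i0 = max(0, int(np.ceil((start - self.t0) * self.sampling_rate - 1e-9)))
        i1 = min(len(self), int(np.floor((end - self.t0) * self.sampling_rate + 1e-9)) + 1)
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end}]")
        return TimeSeriesTrace(
            sampling_rate=self.sampling_rate,
            channels={c: v[i0:i1] for c, v in self.channels.items()},
            t0=self.t0 + i0 / self.sampling_rate,
            metadata=dict(self.metadata),
        )


@dataclass
class StimEvent:
    """One stimulation: a single 100-ms control pulse or a pulse train."""

    time: float  # onset, s
    kind: str  # control_100ms | train
    frequency: float = 0.0  # Hz, trains only
    amplitude: float = 100.0  # µA
    train_duration: float = 0.0  # s (0.1 for control pulses)
    pulse_width: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.kind not in STIM_KINDS:
            raise ValueError(f"stim kind must be one of {STIM_KINDS}, got {self.kind!r}")
        if self.time < 0:
            raise ValueError("stimulation time must be non-negative")
        if self.kind == "control_100ms" and self.train_duration == 0.0:
            self.train_duration = 0.1


@dataclass
class Epoch:
    """Labelled behaviour interval (walking, grooming, sleep, interictal...)."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"degenerate epoch [{self.start}, {self.end}]")


@dataclass
class EventTable:
    stim_events: list[StimEvent] = field(default_factory=list)
    epochs: list[Epoch] = field(default_factory=list)

    def validate_against(self, trace: TimeSeriesTrace) -> None:
        t_end = trace.t0 + trace.duration
        for ev in self.stim_events:
            if not (trace.t0 <= ev.time <= t_end):
                raise ValueError(f"stimulation at {ev.time} s outside trace span")
        for ep in self.epochs:
            if ep.start < trace.t0 or ep.end > t_end + 1.0 / trace.sampling_rate:
                raise ValueError(f"epoch [{ep.start}, {ep.end}] outside trace span")

    def to_json(self, path) -> None:
        doc = {
            "stim_events": [vars(e) for e in self.stim_events],
            "epochs": [vars(e) for e in self.epochs],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EventTable":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            stim_events=[StimEvent(**e) for e in doc.get("stim_events", [])],
            epochs=[Epoch(**e) for e in doc.get("epochs", [])],
        )


@dataclass
class Addition:
    """One stepwise analyte addition during a calibration run."""

    time: float  # s
    analyte: str  # GLU | GABA | AA | H2O2
    target_concentration: float  # cumulative bath concentration, µM

    _ANALYTES = ("GLU", "GABA", "AA", "H2O2")

    def __post_init__(self) -> None:
        if self.analyte not in self._ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.target_concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class CalibrationProtocol:
    """Stepwise-addition schedule for a stirred-bath calibration session."""

    additions: list[Addition]
    temperature: float = 37.0  # °C
    stir_rpm: float = 200.0

    def __post_init__(self) -> None:
        times = [a.time for a in self.additions]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("addition times must be strictly increasing")
        per: dict[str, float] = {}
        for a in self.additions:
            if a.analyte in per and a.target_concentration <= per[a.analyte]:
                raise ValueError(
                    f"{a.analyte} concentrations must increase stepwise "
                    f"({a.target_concentration} after {per[a.analyte]})"
                )
            per[a.analyte] = a.target_concentration

    def to_json(self, path) -> None:
        doc = {
            "additions": [vars(a) for a in self.additions],
            "bath": {"temperature": self.temperature, "stir_rpm": self.stir_rpm},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationProtocol":
        with open(path) as fh:
            doc = json.load(fh)
        bath = doc.get("bath", {})
        return cls(
            additions=[Addition(**a) for a in doc["additions"]],
            temperature=bath.get("temperature", 37.0),
            stir_rpm=bath.get("stir_rpm", 200.0),
        )


def read_trace(path, dialect: dict | None = None) -> TimeSeriesTrace:
    """Read a canonical trace CSV.

    Expected columns: ``time_s, i_gaba_pA, i_glu_pA, i_sentinel_pA``
    (header mandatory). Sampling rate is inferred from the time column and
    uniformity is enforced to a relative tolerance of 1e-6. ``dialect`` may
    override pandas ``read_csv`` options (e.g. ``{"sep": "\\t"}``).
    """
    df = pd.read_csv(path, **(dialect or {}))
    required = ["time_s", *_COLUMNS.values()]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 1:
        raise FormatError(f"{path}: empty trace")
    if len(t) == 1:
        rate = 1000.0
    else:
        dt = np.diff(t)
        dt0 = np.median(dt)
        if dt0 <= 0 or np.any(np.abs(dt - dt0) > _UNIFORM_RTOL * dt0 + 1e-12):
            raise FormatError(f"{path}: non-uniform sampling")
        rate = 1.0 / dt0
    return TimeSeriesTrace(
        sampling_rate=rate,
        channels={ch: df[col].to_numpy(dtype=float) for ch, col in _COLUMNS.items()},
        t0=float(t[0]),
    )


def write_trace(trace: TimeSeriesTrace, path) -> None:
    """Write the canonical trace CSV (lossless round-trip to < 1e-9)."""
    df = pd.DataFrame({"time_s": trace.time})
    for ch, col in _COLUMNS.items():
        df[col] = trace.channels[ch]
    df.to_csv(path, index=False, float_format="%.12g")


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrink-window edge handling.

    At the boundaries the window shrinks to the available samples, so no
    NaN padding is introduced and constants are preserved exactly.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(x):
        raise ValueError("window longer than series")
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    h = window // 2
    c = np.concatenate(([0.0], np.cumsum(np.asarray(x, dtype=float))))
    n = len(x)
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def downsample_smooth(trace: TimeSeriesTrace, factor: int = 1, window: int = 1) -> TimeSeriesTrace:
    """Moving-average smooth then decimate, as used for behaviour-scale plots.

    The raw 1,000-Hz trace is kept for peak-level analysis; this is a
    visualisation-scale convenience. ``window`` is an odd sample count,
    ``factor`` a positive decimation step. Both are recorded in metadata.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = {c: moving_average(v, window)[::factor] for c, v in trace.channels.items()}
    meta = dict(trace.metadata)
    meta.update(smooth_window=window, downsample_factor=int(factor))
    return TimeSeriesTrace(
        sampling_rate=trace.sampling_rate / factor,
        channels=smoothed,
        t0=trace.t0,
        metadata=meta,
    )
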