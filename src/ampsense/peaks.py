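"""Response isolation, peak kinetics and quality control.

Each stimulation response is analysed against its own baseline (the mean
of the last 10 s of the response segment, by which time the current has
returned to rest). Peak kinetics follow the 10/50/90% threshold
convention: rise time T_R is the interval between the 10% and 90% upward
crossings, decay time T_D between the 90% and 10% downward crossings, and
FDHM the full duration at half maximum (between the two 50% crossings).
Crossing times are refined by linear interpolation between the bracketing
samples, taking the nearest crossings flanking the global maximum.

QC discards responses whose amplitude is below twice the baseline noise,
responses where the sentinel peak exceeds the raw GLU peak, and -- at the
slice level -- every response after a control pulse falls to 80% or less
of the mean of the first three control responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deconvolution import ConcentrationTrace
from .trace_io import EventTable, StimEvent, TimeSeriesTrace

__all__ = [
    "PeakMetrics",
    "SpikeEvent",
    "ResponseSegment",
    "estimate_baseline",
    "peak_metrics",
    "qc_response",
    "slice_health",
    "detect_interictal_spikes",
    "segment_responses",
    "response_peak_metrics",
    "count_fluctuations",
]

QC_OK = "ok"
QC_BELOW_2X_NOISE = "below_2x_noise"
QC_SENTINEL_EXCEEDS_GLU = "sentinel_exceeds_glu"
QC_NO_RETURN = "no_return_to_baseline"


@dataclass
class PeakMetrics:
    """Kinetic parameters of one response peak."""

    baseline: float  # pA (or µM for concentration traces)
    peak_amplitude: float  # above baseline
    t_peak: float  # s, within the segment
    t_r: float  # s, 10 -> 90% rise
    t_d: float  # s, 90 -> 10% decay
    fdhm: float  # s
    noise_sd: float = float("nan")
    qc: str = QC_OK


@dataclass
class SpikeEvent:
    """One interictal-like excursion, departure to return to baseline."""

    t_start: float
    t_end: float
    polarity: str  # negative | positive
    channels: tuple = ()

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("spike must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def estimate_baseline(
    segment: np.ndarray,
    rate: float,
    window: float = 10.0,
    allow_short: bool = False,
) -> float:
    """Baseline current: mean of the last ``window`` seconds of the segment."""
    segment = np.asarray(segment, dtype=float)
    n_win = int(round(window * rate))
    finite = segment[np.isfinite(segment)]
    if len(finite) < n_win:
        if not allow_short:
            raise ValueError(
                f"segment of {len(finite)} samples shorter than {window} s window"
            )
        n_win = len(finite)
    return float(np.mean(finite[-n_win:]))


def _cross_time(t1, v1, t2, v2, thr):
    """Linear interpolation of a threshold crossing between two samples."""
    if v2 == v1:
        return t1
    return t1 + (thr - v1) * (t2 - t1) / (v2 - v1)


def peak_metrics(segment: np.ndarray, rate: float, noise_sd: float = float("nan")) -> PeakMetrics:
    """Threshold-crossing kinetics of a baseline-subtracted response.

    The segment may contain NaNs (masked artifact samples); crossings are
    interpolated between the nearest finite samples. A missing downward
    crossing (the response never relaxes back below a threshold) sets the
    ``no_return_to_baseline`` QC flag and NaN durations where undefined.
    """
    segment = np.asarray(segment, dtype=float)
    finite = np.flatnonzero(np.isfinite(segment))
    if finite.size < 3:
        raise ValueError("segment has fewer than 3 finite samples")
    vals = segment[finite]
    times = finite / rate
    i_max = int(np.argmax(vals))
    peak = vals[i_max]
    if not peak > 0:
        raise ValueError("segment contains no positive maximum")
    t_peak = times[i_max]

    def rising(thr):
        # last upward crossing before the peak
        for j in range(i_max, 0, -1):
            if vals[j - 1] < thr <= vals[j]:
                return _cross_time(times[j - 1], vals[j - 1], times[j], vals[j], thr)
        return times[0] if vals[0] >= thr else None

    def falling(thr):
        # first downward crossing after the peak
        for j in range(i_max, len(vals) - 1):
            if vals[j] >= thr > vals[j + 1]:
                return _cross_time(times[j], vals[j], times[j + 1], vals[j + 1], thr)
        return None

    t10u, t50u, t90u = (rising(f * peak) for f in (0.1, 0.5, 0.9))
    t90d, t50d, t10d = (falling(f * peak) for f in (0.9, 0.5, 0.1))
    qc = QC_OK
    if any(v is None for v in (t90d, t50d, t10d)):
        qc = QC_NO_RETURN
    t_r = t90u - t10u if None not in (t10u, t90u) else float("nan")
    t_d = t10d - t90d if None not in (t90d, t10d) else float("nan")
    fdhm = t50d - t50u if None not in (t50u, t50d) else float("nan")
    return PeakMetrics(
        baseline=0.0,
        peak_amplitude=float(peak),
        t_peak=float(t_peak),
        t_r=float(t_r),
        t_d=float(t_d),
        fdhm=float(fdhm),
        noise_sd=noise_sd,
        qc=qc,
    )


def qc_response(peak: PeakMetrics, sentinel_peak: float, glu_raw_peak: float) -> str:
    """Retain/discard decision for one response.

    Discards when the amplitude is indistinguishable from noise (below
    2x the pre-stimulus noise SD) or when the sentinel peak rises above
    the raw GLU peak (interferent-dominated response).
    """
    if np.isfinite(peak.noise_sd) and peak.peak_amplitude < 2.0 * peak.noise_sd:
        return QC_BELOW_2X_NOISE
    if sentinel_peak > glu_raw_peak:
        return QC_SENTINEL_EXCEEDS_GLU
    return peak.qc


def slice_health(control_responses) -> list[str]:
    """Per-response health of a slice from its control-pulse amplitudes.

    The reference is the mean of the first three control responses; from
    the first subsequent response at 80% or less of that reference the
    slice counts as discarded (that response and all later ones).
    """
    amps = [float(a) for a in control_responses]
    if len(amps) < 3:
        raise ValueError("need >= 3 control responses")
    ref = float(np.mean(amps[:3]))
    status, dead = [], False
    for i, a in enumerate(amps):
        if i >= 3 and not dead and a <= 0.80 * ref:
            dead = True
        status.append("discarded" if dead else "ok")
    return status


@dataclass
class ResponseSegment:
    """One stimulation's stretch of trace, artifact samples masked to NaN."""

    event: StimEvent
    sampling_rate: float
    t0: float  # s, segment start (stimulation onset)
    channels: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(next(iter(self.channels.values())))


def _pulse_times(ev: StimEvent) -> np.ndarray:
    if ev.kind == "control_100ms":
        return np.array([ev.time])
    n = max(1, int(round(ev.frequency * ev.train_duration)))
    return ev.time + np.arange(n) / ev.frequency


def segment_responses(
    trace: TimeSeriesTrace,
    events: EventTable,
    artifact_blank: float = 0.0,
) -> list[ResponseSegment]:
    """Split a recording into per-stimulation response segments.

    Each segment runs from one stimulation onset to the next (or to the
    trace end). Samples within ``artifact_blank`` seconds after any
    individual stimulation pulse are masked (NaN) so artifact transients
    cannot contaminate peak analysis; ``artifact_blank=0`` masks nothing.
    """
    events.validate_against(trace)
    stims = sorted(events.stim_events, key=lambda e: e.time)
    for e1, e2 in zip(stims, stims[1:]):
        if e2.time < e1.time + e1.train_duration:
            raise ValueError(f"stimulations at {e1.time} and {e2.time} s overlap")
    t_end = trace.t0 + trace.duration
    segments = []
    half_dt = 0.5 / trace.sampling_rate
    for i, ev in enumerate(stims):
        seg_end = stims[i + 1].time if i + 1 < len(stims) else t_end
        sub = trace.slice(ev.time, seg_end)
        chans = {c: v.astype(float).copy() for c, v in sub.channels.items()}
        if i + 1 < len(stims) and sub.time[-1] >= seg_end - half_dt:
            # half-open segments: the boundary sample belongs to the next one
            chans = {c: v[:-1] for c, v in chans.items()}
        if artifact_blank > 0:
            t = sub.time[: len(next(iter(chans.values())))]
            mask = np.zeros(len(t), dtype=bool)
            for p in _pulse_times(ev):
                # half-sample guard absorbs float rounding of pulse times
                mask |= (t >= p - half_dt) & (t < p + artifact_blank - half_dt)
            for v in chans.values():
                v[mask] = np.nan
        segments.append(
            ResponseSegment(event=ev, sampling_rate=sub.sampling_rate, t0=sub.t0, channels=chans)
        )
    return segments


def response_peak_metrics(
    seg: ResponseSegment,
    channel: str = "glu_raw",
    baseline_window: float = 10.0,
) -> PeakMetrics:
    """Baseline-subtract one segment channel and extract its peak kinetics.

    Baseline and noise SD come from the last ``baseline_window`` seconds
    of the segment (the response has returned to rest by then).
    """
    x = seg.channels[channel]
    rate = seg.sampling_rate
    base = estimate_baseline(x, rate, baseline_window)
    finite = x[np.isfinite(x)]
    n_win = int(round(baseline_window * rate))
    noise_sd = float(np.std(finite[-n_win:], ddof=1))
    m = peak_metrics(x - base, rate, noise_sd=noise_sd)
    m.baseline = base
    return m


def _block_baseline(x: np.ndarray, rate: float, window: float) -> np.ndarray:
    """Slowly varying local baseline: per-block medians, linearly interpolated."""
    n = len(x)
    block = max(1, int(round(window * rate)))
    edges = np.arange(0, n, block)
    centers = np.minimum(edges + block / 2.0, n - 1)
    meds = np.array([np.median(x[e : min(e + block, n)]) for e in edges])
    return np.interp(np.arange(n), centers, meds)


def detect_interictal_spikes(
    conc: ConcentrationTrace,
    baseline_window: float = 10.0,
    depart_threshold: float = 0.3,
    analytes: tuple = ("glu", "gaba"),
    merge_gap: float = 0.05,
    smooth_window: int = 25,
) -> tuple[list[SpikeEvent], dict]:
    """Find brief synchronized excursions from baseline (interictal-like).

    A spike is a contiguous excursion whose deviation from the local
    baseline exceeds ``depart_threshold`` (as a fraction of that
    baseline); its duration runs from departure to return. The trace is
    lightly smoothed first (``smooth_window`` samples, ~25 ms at 1 kHz)
    because the GABA inversion amplifies channel noise when [GLU] is low;
    sub-second events tolerate this without biasing durations. Excursions
    on different analytes overlapping within ``merge_gap`` seconds merge
    into one synchronized event. Excursions still open at the segment end
    are excluded (no return to baseline) and counted in the summary.
    """
    from .trace_io import moving_average

    rate = conc.sampling_rate
    raw_events = []
    truncated = 0
    for name in analytes:
        x = np.asarray(getattr(conc, name), dtype=float)
        w = min(smooth_window, len(x))
        if w > 1:
            x = moving_average(x, w if w % 2 == 1 else w - 1)
        base = _block_baseline(x, rate, baseline_window)
        dev = x - base
        thr = depart_threshold * np.abs(base)
        excur = np.abs(dev) > thr
        if not excur.any():
            continue
        d = np.diff(excur.astype(int))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if excur[0]:
            starts = np.r_[0, starts]
        if excur[-1]:
            truncated += 1
            starts = starts[:-1] if len(starts) > len(ends) else starts
        for s, e in zip(starts, ends):
            polarity = "negative" if dev[s : e + 1].sum() < 0 else "positive"
            raw_events.append(
                SpikeEvent(
                    t_start=conc.t0 + s / rate,
                    t_end=conc.t0 + e / rate,
                    polarity=polarity,
                    channels=(name,),
                )
            )
    # merge synchronized events across analytes
    raw_events.sort(key=lambda ev: ev.t_start)
    merged: list[SpikeEvent] = []
    for ev in raw_events:
        if merged and ev.t_start <= merged[-1].t_end + merge_gap:
            prev = merged[-1]
            merged[-1] = SpikeEvent(
                t_start=min(prev.t_start, ev.t_start),
                t_end=max(prev.t_end, ev.t_end),
                polarity=prev.polarity,
                channels=tuple(sorted(set(prev.channels) | set(ev.channels))),
            )
        else:
            merged.append(ev)
    span = len(conc) / rate
    durations = [ev.duration for ev in merged]
    summary = {
        "count": len(merged),
        "mean_duration": float(np.mean(durations)) if durations else float("nan"),
        "frequency": len(merged) / span if span > 0 else float("nan"),
        "truncated": truncated,
    }
    return merged, summary


def count_fluctuations(x: np.ndarray, rate: float, smooth_window: int = 11) -> float:
    """Fluctuation rate (Hz) as zero-crossings of the mean-subtracted,
    lightly smoothed trace, halved (one fluctuation = one up-down cycle).

    Provided for exploratory parity with reported per-behaviour
    fluctuation counts; no particular counting convention is claimed.
    """
    from .trace_io import moving_average

    x = np.asarray(x, dtype=float)
    s = moving_average(x, smooth_window) - np.mean(x)
    crossings = np.sum(np.diff(np.signbit(s)) != 0)
    return crossings / 2.0 / (len(x) / rate)
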