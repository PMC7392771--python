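"""Forward simulation of three-channel microwire biosensor recordings.

The generator emulates the statistical structure the downstream analysis
assumes, phenomenologically rather than as enzyme-layer reaction--diffusion
kinetics:

* the GLU channel responds linearly to [GLU] (sensitivity ``ss_glu``,
  pA/µM) within its linear range and saturates smoothly above it;
* the GABA channel carries a GLU crosstalk term (``ss_glu_in_gaba``) plus a
  GABA-attributable current described by a family of lines -- current
  density versus [GLU], one line per GABA level -- because the GABASE
  pathway needs the α-ketoglutarate produced by the GOx/GLU reaction and
  therefore yields no signal without GLU;
* the enzyme-free sentinel channel sees only interferent current
  (ascorbic-acid-like), which also appears with unit gain on the two
  enzymatic channels so that sentinel subtraction can remove it;
* diffusion-limited response kinetics are a first-order exponential
  approach with separate rise and decay time constants; the unstirred
  preset lengthens the rise time constant by a factor between 7 and 10,
  mimicking the loss of convective transport in still solution;
* measurement noise is white Gaussian per sample plus optional linear
  drift, and stimulation artifacts are brief large square transients on
  the enzymatic channels.

Every session takes a mandatory integer seed; identical seed and
configuration give bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trace_io import (
    Addition,
    CalibrationProtocol,
    Epoch,
    EventTable,
    StimEvent,
    TimeSeriesTrace,
)

__all__ = [
    "SensorParams",
    "KineticsParams",
    "GroundTruth",
    "InterferentEvent",
    "ArtifactEvent",
    "Segment",
    "simulate_channels",
    "make_calibration_session",
    "make_invivo_session",
    "make_slice_session",
    "first_order_response",
    "DEFAULT_GABA_FAMILY",
]

#: Pt microwire electrode area, cm².
DEFAULT_AREA = 1.27e-4

#: Anchor lines of the GABA-channel response family: (GABA level µM,
#: slope of current density vs [GLU] in nA/(µM·cm²), intercept nA/cm²).
DEFAULT_GABA_FAMILY = (
    (50.0, 14.0, 0.0),
    (100.0, 28.0, 0.0),
    (300.0, 55.0, 0.0),
    (500.0, 89.0, 0.0),
    (1000.0, 146.0, 0.0),
)


def density_to_slope(density: float, area: float) -> float:
    """nA/(µM·cm²) -> pA/µM for an electrode of ``area`` cm²."""
    return density * area * 1000.0


@dataclass
class SensorParams:
    """Effective sensitivities and ranges of one three-wire sensor.

    Defaults reproduce a typical device: GLU sensitivity 128 nA/(µM·cm²)
    on the GLU channel and 144 nA/(µM·cm²) on the GABA channel, electrode
    area 1.27e-4 cm², linear ranges 0-300 µM GLU and 0-500 µM GABA, and
    AA selectivity ss_glu/ss_aa = 123.
    """

    ss_glu: float = density_to_slope(128.0, DEFAULT_AREA)  # pA/µM
    ss_glu_in_gaba: float = density_to_slope(144.0, DEFAULT_AREA)  # pA/µM
    gaba_family: tuple = DEFAULT_GABA_FAMILY
    ss_aa: float = density_to_slope(128.0, DEFAULT_AREA) / 123.0  # pA/µM
    sentinel_interferent_gain: float = 1.0
    area: float = DEFAULT_AREA  # cm²
    linear_range_glu: float = 300.0  # µM
    linear_range_gaba: float = 500.0  # µM
    # enzymatic response rolls off sharply above the linear range (the
    # asymptote sits ~25% above the range endpoint)
    saturation_constant_glu: float = 80.0  # µM
    saturation_constant_gaba: float = 150.0  # µM

    def __post_init__(self) -> None:
        if self.ss_glu <= 0 or self.ss_glu_in_gaba <= 0:
            raise ValueError("sensitivities must be positive")
        if self.area <= 0:
            raise ValueError("electrode area must be positive")
        fam = sorted(self.gaba_family)
        slopes = [s for _, s, _ in fam]
        if any(s2 <= s1 for s1, s2 in zip(slopes, slopes[1:])):
            raise ValueError("gaba_family slopes must increase with gaba_level")
        self.gaba_family = tuple((float(g), float(s), float(b)) for g, s, b in fam)

    # -- forward pieces ----------------------------------------------------

    def saturate(self, conc: np.ndarray, analyte: str) -> np.ndarray:
        """Effective concentration after sensor saturation.

        Exactly the identity within the linear range L; above it the
        response bends over as ``L + K·(1 - exp(-(C - L)/K))``, a smooth
        concave roll-off toward an asymptote at L + K.
        """
        if analyte == "GLU":
            L, K = self.linear_range_glu, self.saturation_constant_glu
        elif analyte == "GABA":
            L, K = self.linear_range_gaba, self.saturation_constant_gaba
        else:
            raise ValueError(f"no saturation model for {analyte!r}")
        c = np.asarray(conc, dtype=float)
        out = c.copy()
        over = c > L
        out[over] = L + K * (1.0 - np.exp(-(c[over] - L) / K))
        return out

    def family_coeffs(self, gaba_conc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Slope and intercept of the GABA-family line at given GABA levels.

        Piecewise-linear interpolation between the anchor levels, with a
        zero line prepended at GABA = 0 (no α-keto shuttle, no signal) and
        a clamp at the top anchor.
        """
        levels = np.array([0.0] + [g for g, _, _ in self.gaba_family])
        slopes = np.array([0.0] + [s for _, s, _ in self.gaba_family])
        intercepts = np.array([0.0] + [b for _, _, b in self.gaba_family])
        g = np.clip(np.asarray(gaba_conc, dtype=float), 0.0, levels[-1])
        return np.interp(g, levels, slopes), np.interp(g, levels, intercepts)

    def gaba_channel_density(self, gaba_conc: np.ndarray, glu_conc: np.ndarray) -> np.ndarray:
        """GABA-attributable current density, nA/cm², for given [GABA], [GLU].

        The family interpolation itself encodes the sub-linear growth of
        the response with GABA level (anchor slopes rise less than
        proportionally), so no extra saturation is applied to GABA; the
        top anchor clamps the response.
        """
        slope, intercept = self.family_coeffs(gaba_conc)
        return slope * self.saturate(glu_conc, "GLU") + intercept


#: Multiplier applied to tau_rise in still (unstirred) solution; the
#: diffusion-limited rise is seven to ten times slower without stirring.
UNSTIRRED_FACTOR_RANGE = (7.0, 10.0)


@dataclass
class KineticsParams:
    """First-order response kinetics of the enzyme/electrode assembly.

    ``tau_rise``/``tau_decay`` are the exponential time constants of the
    approach to and relaxation from a concentration step, in seconds.
    ``tau = 0`` means instantaneous response (used for idealised checks).
    ``diffusion_mode='unstirred'`` multiplies the rise constant by
    ``unstirred_factor`` (must lie in [7, 10]).
    """

    tau_rise: float = 0.8  # s, stirred
    tau_decay: float = 2.0  # s
    diffusion_mode: str = "stirred"
    unstirred_factor: float = 8.5

    def __post_init__(self) -> None:
        if self.tau_rise < 0 or self.tau_decay < 0:
            raise ValueError("time constants must be >= 0")
        if self.diffusion_mode not in ("stirred", "unstirred"):
            raise ValueError(f"unknown diffusion_mode {self.diffusion_mode!r}")
        lo, hi = UNSTIRRED_FACTOR_RANGE
        if not (lo <= self.unstirred_factor <= hi):
            raise ValueError(f"unstirred_factor must lie in [{lo}, {hi}]")

    @property
    def effective_tau_rise(self) -> float:
        if self.diffusion_mode == "unstirred":
            return self.tau_rise * self.unstirred_factor
        return self.tau_rise


def first_order_response(x: np.ndarray, rate: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Causal first-order tracking filter with separate rise/decay constants.

    dy/dt = (x - y)/tau, with tau = tau_rise while the drive exceeds the
    state and tau_decay while it relaxes. Zero taus reduce to the identity.
    """
    x = np.asarray(x, dtype=float)
    if tau_rise == 0.0 and tau_decay == 0.0:
        return x.copy()
    dt = 1.0 / rate
    a_r = 1.0 if tau_rise == 0.0 else -math.expm1(-dt / tau_rise)
    a_d = 1.0 if tau_decay == 0.0 else -math.expm1(-dt / tau_decay)
    y = np.empty_like(x)
    acc = x[0]
    y[0] = acc
    for i in range(1, len(x)):
        a = a_r if x[i] > acc else a_d
        acc += a * (x[i] - acc)
        y[i] = acc
    return y


@dataclass
class InterferentEvent:
    """Transient interferent bolus (half-sine pulse of current)."""

    time: float  # s, onset
    amplitude: float  # pA at pulse apex, on unit-gain channels
    duration: float  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("interferent duration must be positive")


@dataclass
class ArtifactEvent:
    """Brief square stimulation-artifact transient."""

    time: float  # s
    amplitude: float  # pA
    duration: float = 0.005  # s


@dataclass
class GroundTruth:
    """True concentration scripts plus nuisance model for one session.

    ``glu_conc``/``gaba_conc`` may be scalars (µM), arrays on the session
    time grid, or callables t -> µM; after simulation they are stored as
    evaluated arrays. A seed is mandatory.
    """

    glu_conc: object = 0.0
    gaba_conc: object = 0.0
    interferent_events: list = field(default_factory=list)
    interferent_conc: object = 0.0  # sustained interferent, µM (AA-like)
    artifact_events: list = field(default_factory=list)
    artifact_gains: tuple = (1.0, 1.0, 0.3)  # gaba, glu, sentinel channels
    drift: float = 0.0  # pA/s, common mode on all channels
    noise_sd: float = 0.0  # pA per sample per channel
    seed: int = None
    epochs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def _evaluate(self, script, t: np.ndarray, name: str) -> np.ndarray:
        if callable(script):
            v = np.asarray(script(t), dtype=float)
        else:
            v = np.asarray(script, dtype=float)
            if v.ndim == 0:
                v = np.full_like(t, float(v))
        if v.shape != t.shape:
            raise ValueError(f"{name} script length {v.shape} != time grid {t.shape}")
        if np.any(v < 0):
            raise ValueError(f"negative concentration in {name} script")
        return v


def _pulse_waveform(events, t: np.ndarray, shape: str) -> np.ndarray:
    w = np.zeros_like(t)
    for ev in events:
        inside = (t >= ev.time) & (t < ev.time + ev.duration)
        if shape == "halfsine":
            w[inside] += ev.amplitude * np.sin(np.pi * (t[inside] - ev.time) / ev.duration)
        else:  # square
            w[inside] += ev.amplitude
    return w


def simulate_channels(
    sensor: SensorParams,
    kinetics: KineticsParams,
    truth: GroundTruth,
    duration: float,
    rate: float = 1000.0,
) -> tuple[TimeSeriesTrace, GroundTruth]:
    """Render a three-channel current trace from a ground-truth script.

    Enzymatic response currents (analyte terms) pass through the
    first-order kinetics filter; interferent, drift, artifacts and noise
    add directly. Identical seed and configuration give bit-identical
    output.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    glu = truth._evaluate(truth.glu_conc, t, "glu_conc")
    gaba = truth._evaluate(truth.gaba_conc, t, "gaba_conc")
    interferent_conc = truth._evaluate(truth.interferent_conc, t, "interferent_conc")

    tau_r, tau_d = kinetics.effective_tau_rise, kinetics.tau_decay
    i_glu_drive = sensor.ss_glu * sensor.saturate(glu, "GLU")
    i_gaba_drive = (
        sensor.gaba_channel_density(gaba, glu) * sensor.area * 1000.0
        + sensor.ss_glu_in_gaba * sensor.saturate(glu, "GLU")
    )
    i_glu = first_order_response(i_glu_drive, rate, tau_r, tau_d)
    i_gaba = first_order_response(i_gaba_drive, rate, tau_r, tau_d)

    interferent = sensor.ss_aa * interferent_conc
    interferent = interferent + _pulse_waveform(truth.interferent_events, t, "halfsine")
    artifact = _pulse_waveform(truth.artifact_events, t, "square")
    drift = truth.drift * t

    rng = np.random.default_rng(truth.seed)
    g_a, g_g, g_s = truth.artifact_gains
    channels = {
        "gaba_raw": i_gaba + interferent + g_a * artifact + drift,
        "glu_raw": i_glu + interferent + g_g * artifact + drift,
        "sentinel": sensor.sentinel_interferent_gain * interferent + g_s * artifact + drift,
    }
    if truth.noise_sd > 0:
        for name in ("gaba_raw", "glu_raw", "sentinel"):
            channels[name] = channels[name] + rng.normal(0.0, truth.noise_sd, n)

    trace = TimeSeriesTrace(
        sampling_rate=rate,
        channels=channels,
        metadata={"seed": truth.seed, "simulated": True},
    )
    truth_out = replace(truth, glu_conc=glu, gaba_conc=gaba, interferent_conc=interferent_conc)
    return trace, truth_out


# -- calibration sessions --------------------------------------------------


def make_calibration_session(
    protocol: CalibrationProtocol,
    sensor: SensorParams,
    kinetics: KineticsParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate: float = 1000.0,
    tail: float = 120.0,
    baseline: float = 120.0,
) -> tuple[TimeSeriesTrace, CalibrationProtocol]:
    """Simulate a stirred-bath stepwise-addition calibration run.

    Each addition raises the bath concentration of its analyte to the
    protocol's target; currents form stepwise plateaus (proportional to
    concentration within the linear range, bending below the linear
    prediction above it). ``baseline`` seconds of analyte-free recording
    precede the first addition and ``tail`` seconds follow the last one.
    """
    if not protocol.additions:
        raise ValueError("protocol has no additions")
    t_last = protocol.additions[-1].time
    duration = t_last + tail
    for a in protocol.additions:
        if a.time >= duration or a.time < baseline:
            raise ValueError(
                f"addition at {a.time} s outside usable window [{baseline}, {duration})"
            )

    def step_script(analyte):
        steps = [(a.time, a.target_concentration) for a in protocol.additions if a.analyte == analyte]

        def conc(t):
            v = np.zeros_like(t)
            for when, level in steps:
                v = np.where(t >= when, level, v)
            return v

        return conc

    truth = GroundTruth(
        glu_conc=step_script("GLU"),
        gaba_conc=step_script("GABA"),
        interferent_conc=step_script("AA"),
        noise_sd=noise_sd,
        seed=seed,
    )
    trace, _ = simulate_channels(sensor, kinetics, truth, duration, rate)
    trace.metadata["session"] = "calibration"
    return trace, protocol


# -- stimulated-slice sessions ---------------------------------------------

#: Default evoked peak concentrations (µM) per stimulation condition,
#: (GLU, GABA): GABA release grows linearly with train frequency while GLU
#: grows concavely, so the E/I ratio falls as frequency rises.
DEFAULT_SLICE_RELEASE = {
    "control_100ms": (90.0, 140.0),
    10.0: (50.0, 72.0),
    50.0: (166.0, 296.0),
    140.0: (264.0, 793.0),
}


def make_slice_session(
    stim_plan,
    sensor: SensorParams,
    kinetics: KineticsParams,
    seed: int = 0,
    release=None,
    release_duration: float = 6.0,
    inter_stim: float = 60.0,
    noise_sd: float = 0.0,
    rate: float = 1000.0,
    artifact_amplitude: float = 0.0,
    release_jitter: float = 0.0,
) -> tuple[TimeSeriesTrace, GroundTruth, EventTable]:
    """Simulate an electrically stimulated slice recording.

    ``stim_plan`` is a sequence of conditions (``"control_100ms"`` or a
    train frequency in Hz); stimulations are spaced ``inter_stim`` seconds
    apart so responses return to baseline. Each stimulation releases a
    concentration plateau of ``release_duration`` seconds whose amplitude
    comes from ``release`` (optionally jittered multiplicatively by a
    lognormal factor with sigma ``release_jitter``). ``artifact_amplitude``
    adds a square artifact at each pulse of the train.
    """
    release = dict(DEFAULT_SLICE_RELEASE if release is None else release)
    rng = np.random.default_rng(seed)
    events, pulses = [], []
    t_cursor = inter_stim / 2.0
    segments = []  # (onset, glu_amp, gaba_amp)
    for cond in stim_plan:
        if cond == "control_100ms":
            ev = StimEvent(time=t_cursor, kind="control_100ms")
        else:
            ev = StimEvent(time=t_cursor, kind="train", frequency=float(cond), train_duration=5.0)
        glu_a, gaba_a = release[cond]
        if release_jitter > 0:
            glu_a *= rng.lognormal(0.0, release_jitter)
            gaba_a *= rng.lognormal(0.0, release_jitter)
        segments.append((t_cursor, glu_a, gaba_a))
        if artifact_amplitude > 0:
            if ev.kind == "train":
                for k in range(int(ev.frequency * ev.train_duration)):
                    pulses.append(ArtifactEvent(t_cursor + k / ev.frequency, artifact_amplitude))
            else:
                pulses.append(ArtifactEvent(t_cursor, artifact_amplitude, duration=0.1))
        events.append(ev)
        t_cursor += inter_stim
    duration = t_cursor

    def pulse_script(amps_idx):
        def conc(t):
            v = np.zeros_like(t)
            for onset, glu_a, gaba_a in segments:
                amp = (glu_a, gaba_a)[amps_idx]
                v = np.where((t >= onset) & (t < onset + release_duration), amp, v)
            return v

        return conc

    truth = GroundTruth(
        glu_conc=pulse_script(0),
        gaba_conc=pulse_script(1),
        artifact_events=pulses,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    trace, truth = simulate_channels(sensor, kinetics, truth, duration, rate)
    trace.metadata["session"] = "slice"
    return trace, truth, EventTable(stim_events=events)


# -- in vivo behavioural sessions ------------------------------------------

SEGMENT_KINDS = ("interictal", "seizure", "sleep", "wake", "walking", "grooming")


@dataclass
class Segment:
    """One behavioural segment of an in vivo session script."""

    kind: str
    duration: float  # s
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


def _segment_scripts(seg: Segment, t: np.ndarray, base_glu: float, base_gaba: float, rng) -> tuple:
    """Local (glu, gaba) concentration arrays for one segment, time from 0."""
    p = seg.params
    glu = np.full_like(t, base_glu)
    gaba = np.full_like(t, base_gaba)
    if seg.kind == "interictal":
        # synchronized sub-second dips on both analytes
        spike_rate = p.get("spike_rate", 0.13)  # Hz
        spike_dur = p.get("spike_duration", 0.44)  # s
        glu_low = p.get("glu_low", 4.0)
        gaba_low = p.get("gaba_low", 2.0)
        n_spikes = p.get("n_spikes", int(seg.duration * spike_rate))
        for k in range(n_spikes):
            t_on = (k + 0.5) / spike_rate
            dip = (t >= t_on) & (t < t_on + spike_dur)
            glu[dip] = glu_low
            gaba[dip] = gaba_low
    elif seg.kind == "seizure":
        # large synchronous fluctuations on both analytes
        amp = p.get("amplitude", 0.8)  # fraction of baseline
        f = p.get("frequency", 1.5)  # Hz
        phase = rng.uniform(0, 2 * np.pi)
        wob = 0.5 * (1 + np.sin(2 * np.pi * f * t + phase))
        glu = base_glu * (1 + amp * wob)
        gaba = base_gaba * (1 + amp * wob * p.get("gaba_coupling", 0.8))
    elif seg.kind == "sleep":
        # GABA ramps up then plateaus; GLU stays put
        rise = p.get("gaba_rise", 0.312)
        frac = p.get("ramp_fraction", 0.5)
        ramp_end = frac * seg.duration
        gaba = base_gaba * (1 + rise * np.clip(t / ramp_end, 0.0, 1.0))
    elif seg.kind == "wake":
        drop = p.get("gaba_drop", 0.319)
        gaba = np.full_like(t, base_gaba * (1 - drop))
    elif seg.kind in ("walking", "grooming"):
        f = p.get("fluct_hz", 9.7 if seg.kind == "walking" else 13.0)
        amp = p.get("amplitude", 0.1)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        glu = base_glu * (1 + amp * np.sin(2 * np.pi * f * t + ph1))
        # feedback network: GABA fluctuations oppose GLU
        gaba = base_gaba * (1 + amp * np.sin(2 * np.pi * f * t + ph2 + np.pi))
    return np.clip(glu, 0.0, None), np.clip(gaba, 0.0, None)


def make_invivo_session(
    script: list,
    sensor: SensorParams,
    kinetics: KineticsParams,
    seed: int = 0,
    rate: float = 1000.0,
    base_glu: float = 18.0,
    base_gaba: float = 15.0,
    noise_sd: float = 0.0,
    drift: float = 0.0,
) -> tuple[TimeSeriesTrace, GroundTruth]:
    """Simulate an awake-animal session from a list of behaviour Segments.

    Segments tile the session in order. Baseline concentrations default to
    18 µM GLU and 15 µM GABA; each segment kind perturbs them as described
    in :func:`_segment_scripts`. Segment boundaries are recorded as labelled
    epochs on the returned ground truth.
    """
    if not script:
        raise ValueError("script must contain at least one segment")
    rng = np.random.default_rng(seed)
    duration = sum(s.duration for s in script)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    glu = np.empty(n)
    gaba = np.empty(n)
    epochs = []
    t_cursor = 0.0
    for seg in script:
        i0 = int(round(t_cursor * rate))
        i1 = min(n, int(round((t_cursor + seg.duration) * rate)))
        local_t = t[i0:i1] - t_cursor
        glu[i0:i1], gaba[i0:i1] = _segment_scripts(seg, local_t, base_glu, base_gaba, rng)
        epochs.append(Epoch(start=t_cursor, end=t_cursor + seg.duration, label=seg.kind))
        t_cursor += seg.duration
    truth = GroundTruth(
        glu_conc=glu,
        gaba_conc=gaba,
        noise_sd=noise_sd,
        drift=drift,
        seed=int(rng.integers(2**31 - 1)),
        epochs=epochs,
    )
    trace, truth = simulate_channels(sensor, kinetics, truth, duration, rate)
    trace.metadata["session"] = "invivo"
    return trace, truth
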