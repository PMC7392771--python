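"""End-to-end session workflows: simulate (or load), calibrate, deconvolve
and summarise. These glue the module-level operations into the analyses a
recording session goes through: a calibration run yields a
SensorCalibration; a stimulated-slice run yields per-response peak tables
and an E/I-versus-frequency summary; in vivo runs yield interictal spike
statistics and sleep/wake E/I tables. The analysis drivers and the
acceptance script both call these.
"""

from __future__ import annotations

import numpy as np

from . import calibration as cal_mod
from .calibration import SensorCalibration
from .deconvolution import convert_peak, deconvolve_trace
from .ei import EIResult, ei_ratio, frequency_response_table, pooled_mean
from .peaks import (
    detect_interictal_spikes,
    qc_response,
    response_peak_metrics,
    segment_responses,
)
from .synthetic import (
    GroundTruth,
    KineticsParams,
    Segment,
    SensorParams,
    make_calibration_session,
    make_invivo_session,
    make_slice_session,
    simulate_channels,
)
from .trace_io import Addition, CalibrationProtocol, moving_average

__all__ = [
    "fit_sensor_calibration",
    "slice_frequency_analysis",
    "interictal_analysis",
    "sleep_wake_analysis",
]

#: Stepwise GLU additions used for sensitivity sessions (µM, cumulative);
#: the first five lie inside the 0-300 µM linear range, the rest probe
#: saturation for the linear-range determination.
GLU_ADDITIONS = (20.0, 50.0, 100.0, 200.0, 300.0, 500.0, 800.0, 1200.0)
AA_ADDITIONS = (100.0, 200.0, 300.0)
FAMILY_GLU_POINTS = (30.0, 60.0, 120.0, 200.0, 280.0)


def _protocol(concs, analyte, start=130.0, gap=60.0):
    return CalibrationProtocol(
        additions=[Addition(start + i * gap, analyte, c) for i, c in enumerate(concs)]
    )


def _family_grid(sensor, kinetics, levels, glus, noise_sd, rng, rate=50.0):
    """Plateau current densities on the GABA channel for a (GABA, GLU) grid.

    Each grid point is a short steady-state run; the GABA-attributable
    density is obtained through the same subtraction chain the analysis
    uses (sentinel and crosstalk removal at the known GLU level).
    """
    grid = {}
    for level in levels:
        pts = []
        for glu in glus:
            truth = GroundTruth(
                glu_conc=glu, gaba_conc=level, noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            trace, _ = simulate_channels(sensor, kinetics, truth, duration=2.0, rate=rate)
            half = len(trace) // 2
            i_gaba = (
                float(np.mean(trace.channels["gaba_raw"][half:]))
                - glu * sensor.ss_glu_in_gaba
                - float(np.mean(trace.channels["sentinel"][half:]))
            )
            pts.append((glu, (i_gaba / 1000.0) / sensor.area))
        grid[level] = pts
    return grid


def fit_sensor_calibration(
    sensor: SensorParams,
    kinetics: KineticsParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate: float = 50.0,
) -> tuple[SensorCalibration, dict]:
    """Run simulated calibration sessions and fit every calibration constant.

    Returns the fitted :class:`SensorCalibration` plus a details dict with
    current-density sensitivities (nA/(µM·cm²)), the determined linear
    range, LOD and AA selectivities.
    """
    rng = np.random.default_rng(seed)

    # GLU stepwise session, read on both enzymatic channels
    glu_proto = _protocol(GLU_ADDITIONS, "GLU")
    trace, _ = make_calibration_session(
        glu_proto, sensor, kinetics, noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)), rate=rate,
    )
    steps_glu = cal_mod.detect_steps(trace, glu_proto, channel="glu_raw")
    steps_gaba_ch = cal_mod.detect_steps(trace, glu_proto, channel="gaba_raw")
    linear_bound, range_flagged = cal_mod.determine_linear_range(steps_glu)
    fit_glu = cal_mod.fit_sensitivity(steps_glu, range_limit=linear_bound)
    fit_glu_in_gaba = cal_mod.fit_sensitivity(steps_gaba_ch, range_limit=linear_bound)

    # LOD from the analyte-free baseline preceding the first addition
    n_base = int((glu_proto.additions[0].time - 5.0) * rate)
    baseline = trace.channels["glu_raw"][:n_base]
    lod_glu = cal_mod.compute_lod(baseline, fit_glu.slope) if noise_sd > 0 else 0.0

    # AA interferent session for selectivity
    aa_proto = _protocol(AA_ADDITIONS, "AA")
    aa_trace, _ = make_calibration_session(
        aa_proto, sensor, kinetics, noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)), rate=rate,
    )
    fit_aa = cal_mod.fit_sensitivity(
        cal_mod.detect_steps(aa_trace, aa_proto, channel="glu_raw")
    )
    sel_glu, _ = cal_mod.compute_selectivity(fit_glu.slope, max(fit_aa.slope, 0.0))

    # GABA-channel line family
    levels = [g for g, _, _ in sensor.gaba_family]
    grid = _family_grid(sensor, kinetics, levels, FAMILY_GLU_POINTS, noise_sd, rng, rate)
    family = cal_mod.fit_gaba_family(grid)

    cal = SensorCalibration(
        ss_glu=fit_glu.slope,
        ss_glu_in_gaba=fit_glu_in_gaba.slope,
        gaba_family=family,
        area=sensor.area,
        lod={"GLU": lod_glu},
        selectivity={"GLU_vs_AA": sel_glu},
        linear_range={"GLU": linear_bound, "GABA": sensor.linear_range_gaba},
        diagnostics={
            "glu_r2": fit_glu.r2,
            "glu_slope_sem": fit_glu.sem,
            "linear_range_flagged": range_flagged,
        },
        sensor_id=f"sim-{seed}",
    )
    details = {
        "glu_density_sensitivity": cal_mod.to_current_density(fit_glu.slope, sensor.area),
        "glu_in_gaba_density_sensitivity": cal_mod.to_current_density(
            fit_glu_in_gaba.slope, sensor.area
        ),
        "family_slopes": [f.slope for f in family],
        "linear_range_glu": linear_bound,
        "lod_glu_uM": lod_glu,
        "selectivity_glu_vs_aa": sel_glu,
    }
    return cal, details


def slice_frequency_analysis(
    sensor: SensorParams,
    kinetics: KineticsParams,
    cal: SensorCalibration,
    seed: int = 0,
    n_repeats: int = 4,
    noise_sd: float = 2.0,
    rate: float = 200.0,
    release=None,
    release_jitter: float = 0.15,
) -> tuple[list[EIResult], list[dict], list[dict]]:
    """Stimulated-slice session: peaks, QC and E/I versus train frequency.

    Simulates ``n_repeats`` randomized blocks of 10/50/140-Hz trains,
    isolates each response, applies QC, converts the retained peak
    currents through the reference path and summarises E/I per condition.
    Returns (summary rows, pairwise tests, per-response records).
    """
    rng = np.random.default_rng(seed)
    plan = []
    for _ in range(n_repeats):
        block = [10.0, 50.0, 140.0]
        rng.shuffle(block)
        plan.extend(block)
    trace, truth, events = make_slice_session(
        plan, sensor, kinetics, seed=int(rng.integers(2**31 - 1)),
        release=release, inter_stim=40.0, release_duration=5.0,
        noise_sd=noise_sd, rate=rate, release_jitter=release_jitter,
        artifact_amplitude=500.0,
    )
    records = []
    by_cond: dict = {}
    smooth_w = 2 * int(0.025 * rate) + 1
    for seg in segment_responses(trace, events, artifact_blank=0.03):
        m = response_peak_metrics(seg, channel="glu_raw")
        peaks = {}
        for c in ("glu_raw", "gaba_raw", "sentinel"):
            x = seg.channels[c]
            x = x[np.isfinite(x)]
            base = float(np.mean(x[-int(10 * rate):]))
            peaks[c] = float(moving_average(x, smooth_w).max()) - base
        qc = qc_response(m, peaks["sentinel"], peaks["glu_raw"])
        out = convert_peak(peaks["glu_raw"], peaks["gaba_raw"], peaks["sentinel"], cal)
        rec = {
            "frequency": seg.event.frequency,
            "qc": qc,
            "glu_uM": out["glu_uM"],
            "gaba_uM": out["gaba_uM"],
            "t_r": m.t_r,
            "t_d": m.t_d,
            "fdhm": m.fdhm,
        }
        records.append(rec)
        if qc == "ok":
            by_cond.setdefault(seg.event.frequency, []).append(
                (out["glu_uM"], out["gaba_uM"])
            )
    rows, tests = frequency_response_table(by_cond)
    return rows, tests, records


#: In vivo defaults: printed interictal baselines (GLU 18 µM, GABA 15 µM)
#: and sub-second sensor kinetics appropriate to tissue apposition.
INVIVO_KINETICS = KineticsParams(tau_rise=0.05, tau_decay=0.05)


def interictal_analysis(
    sensor: SensorParams,
    cal: SensorCalibration,
    seed: int = 0,
    duration: float = 70.0,
    n_spikes: int = 9,
    spike_rate: float = 0.13,
    noise_sd: float = 2.0,
    rate: float = 1000.0,
    kinetics: KineticsParams | None = None,
) -> dict:
    """Quiet-rest segment with interictal-like dips: spike stats and E/I.

    Baseline concentrations are the per-analyte medians of the deconvolved
    segment (robust against the brief dips); E/I is their ratio.
    """
    script = [Segment("interictal", duration, {"n_spikes": n_spikes, "spike_rate": spike_rate})]
    trace, truth = make_invivo_session(
        script, sensor, kinetics or INVIVO_KINETICS, seed=seed, rate=rate, noise_sd=noise_sd
    )
    conc = deconvolve_trace(trace, cal)
    events, summary = detect_interictal_spikes(conc, depart_threshold=0.3)
    base_glu = float(np.median(conc.glu))
    base_gaba = float(np.median(conc.gaba))
    ei, _ = ei_ratio(base_glu, base_gaba)
    return {
        "spike_count": summary["count"],
        "mean_duration_ms": summary["mean_duration"] * 1000.0,
        "spike_frequency_hz": summary["frequency"],
        "baseline_glu_uM": base_glu,
        "baseline_gaba_uM": base_gaba,
        "ei": ei,
        "events": events,
    }


def sleep_wake_analysis(
    sensor: SensorParams,
    cal: SensorCalibration,
    seed: int = 0,
    n_cycles: int = 6,
    cycle_s: float = 120.0,
    base_glu: float = 18.0,
    base_gaba: float = 20.5,
    noise_sd: float = 2.0,
    rate: float = 100.0,
    kinetics: KineticsParams | None = None,
) -> dict:
    """Sleep--wake cycles: per-episode E/I and the pooled balance.

    Per episode, E/I uses the maximum GABA concentration during sleep and
    the minimum during wakefulness against the episode-mean GLU. The
    session GABA baseline (20.5 µM) sits so that a +31% sleep rise and a
    -32% wake drop bracket the printed per-state E/I levels around the
    18-µM GLU baseline.
    """
    script = []
    for _ in range(n_cycles):
        script.append(Segment("sleep", cycle_s / 2))
        script.append(Segment("wake", cycle_s / 2))
    trace, truth = make_invivo_session(
        script, sensor, kinetics or INVIVO_KINETICS, seed=seed, rate=rate,
        base_glu=base_glu, base_gaba=base_gaba, noise_sd=noise_sd,
    )
    conc = deconvolve_trace(trace, cal)
    t = conc.time
    w = 2 * int(2.5 * rate) + 1  # 5-s smoothing: sleep/wake GABA moves on minutes
    glu_s = moving_average(conc.glu, min(w, len(conc.glu) // 2 * 2 - 1))
    gaba_s = moving_average(conc.gaba, min(w, len(conc.gaba) // 2 * 2 - 1))
    sleep_eis, wake_eis = [], []
    for ep in truth.epochs:
        sel = (t >= ep.start) & (t < ep.end)
        glu_m = float(np.mean(glu_s[sel]))
        if ep.label == "sleep":
            sleep_eis.append(ei_ratio(glu_m, float(gaba_s[sel].max()))[0])
        else:
            wake_eis.append(ei_ratio(glu_m, float(gaba_s[sel].min()))[0])
    pooled = pooled_mean(
        [float(np.mean(sleep_eis)), float(np.mean(wake_eis))],
        [len(sleep_eis), len(wake_eis)],
    )
    return {
        "sleep_ei_mean": float(np.mean(sleep_eis)),
        "wake_ei_mean": float(np.mean(wake_eis)),
        "pooled_ei": pooled,
        "sleep_eis": sleep_eis,
        "wake_eis": wake_eis,
    }
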