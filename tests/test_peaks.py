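import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampsense.deconvolution import ConcentrationTrace
from ampsense.peaks import (
    PeakMetrics,
    QC_BELOW_2X_NOISE,
    QC_NO_RETURN,
    QC_OK,
    QC_SENTINEL_EXCEEDS_GLU,
    detect_interictal_spikes,
    estimate_baseline,
    peak_metrics,
    qc_response,
    response_peak_metrics,
    segment_responses,
    slice_health,
)
from ampsense.synthetic import (
    ArtifactEvent,
    GroundTruth,
    KineticsParams,
    Segment,
    SensorParams,
    make_invivo_session,
    simulate_channels,
)
from ampsense.trace_io import EventTable, StimEvent, TimeSeriesTrace


def triangle(rate=1000.0, rise=1.0, fall=2.0, amp=10.0, pad=1.0):
    """Piecewise-linear pulse: 0 -> amp over `rise` s, back to 0 over `fall` s."""
    t = np.arange(int((rise + fall + 2 * pad) * rate)) / rate
    up = np.clip((t - pad) / rise, 0, 1)
    down = np.clip((t - pad - rise) / fall, 0, 1)
    return amp * (up - down)


def conc_trace(glu, gaba, rate=1000.0):
    glu = np.asarray(glu, dtype=float)
    gaba = np.asarray(gaba, dtype=float)
    z = np.zeros(len(glu), dtype=int)
    return ConcentrationTrace(
        sampling_rate=rate, glu=glu, gaba=gaba, glu_flags=z, gaba_flags=z.copy()
    )


class TestBaseline:
    def test_constant(self):
        assert estimate_baseline(np.full(20_000, 5.0), 1000.0) == 5.0

    def test_ramp_last_half(self):
        # 0 -> 10 pA over 20 s: the final 10 s averages 7.5 pA
        seg = np.linspace(0, 10, 20_000, endpoint=False)
        assert estimate_baseline(seg, 1000.0, window=10.0) == pytest.approx(7.5, abs=1e-3)

    def test_short_segment_rejected_unless_allowed(self):
        seg = np.ones(3000)
        with pytest.raises(ValueError, match="shorter"):
            estimate_baseline(seg, 1000.0, window=10.0)
        assert estimate_baseline(seg, 1000.0, window=10.0, allow_short=True) == 1.0


class TestPeakMetrics:
    def test_triangle_closed_form(self):
        # rise 0->10 over 1 s and fall over 2 s: T_R = 0.8, T_D = 1.6, FDHM = 1.5
        m = peak_metrics(triangle(), 1000.0)
        assert m.t_r == pytest.approx(0.8, abs=2e-3)
        assert m.t_d == pytest.approx(1.6, abs=2e-3)
        assert m.fdhm == pytest.approx(1.5, abs=2e-3)
        assert m.peak_amplitude == pytest.approx(10.0)

    def test_symmetric_triangle_has_equal_rise_and_decay(self):
        m = peak_metrics(triangle(rise=1.5, fall=1.5), 1000.0)
        assert m.t_r == pytest.approx(m.t_d, abs=2e-3)

    def test_flat_segment_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            peak_metrics(np.zeros(100), 1000.0)

    def test_truncated_decay_flagged(self):
        seg = triangle()[: int(1.6 * 1000)]  # cut before the 10% fall crossing
        m = peak_metrics(seg, 1000.0)
        assert m.qc == QC_NO_RETURN
        assert np.isnan(m.t_d)

    def test_oracle_equivalence_on_random_unimodal_pulses(self, rng):
        # brute-force sample-scan oracle: crossing located at the first
        # bracketing sample, no interpolation -- agreement within one period
        rate = 500.0
        for _ in range(100):
            m, oracle = _random_pulse_metrics(rng, rate)
            for a, b in zip(m, oracle):
                assert abs(a - b) <= 1.0 / rate + 1e-12

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.1, 100.0), shift_s=st.floats(0.0, 1.0))
    def test_scale_invariance_and_shift_equivariance(self, scale, shift_s):
        rate = 1000.0
        base = triangle(rate)
        m0 = peak_metrics(base, rate)
        m_scaled = peak_metrics(scale * base, rate)
        for attr in ("t_r", "t_d", "fdhm"):
            assert getattr(m_scaled, attr) == pytest.approx(getattr(m0, attr), abs=1e-9)
        shift = int(shift_s * rate)
        m_shift = peak_metrics(np.concatenate([np.zeros(shift), base]), rate)
        assert m_shift.t_peak == pytest.approx(m0.t_peak + shift / rate, abs=1e-9)
        assert m_shift.fdhm == pytest.approx(m0.fdhm, abs=1e-9)

    def test_rise_time_monotone_in_simulator_tau(self, sensor):
        rate = 200.0
        t_rs = []
        for tau in (0.3, 0.8, 2.0):
            kin = KineticsParams(tau_rise=tau, tau_decay=1.0)
            truth = GroundTruth(
                glu_conc=lambda t: 100.0 * ((t > 5) & (t < 45)), seed=0
            )
            trace, _ = simulate_channels(sensor, kin, truth, duration=60, rate=rate)
            t_rs.append(peak_metrics(trace.channels["glu_raw"], rate).t_r)
        assert t_rs[0] < t_rs[1] < t_rs[2]


def _random_pulse_metrics(rng, rate):
    # smooth unimodal pulse: asymmetric gaussian with random widths
    t = np.arange(int(8 * rate)) / rate
    t_pk = rng.uniform(2.0, 6.0)
    w_up, w_dn = rng.uniform(0.2, 1.0, 2)
    amp = rng.uniform(1.0, 50.0)
    x = np.where(
        t < t_pk,
        amp * np.exp(-0.5 * ((t - t_pk) / w_up) ** 2),
        amp * np.exp(-0.5 * ((t - t_pk) / w_dn) ** 2),
    )
    x[x < amp * 1e-4] = 0.0
    m = peak_metrics(x, rate)

    i_pk = int(np.argmax(x))
    peak = x[i_pk]

    # scan convention: the first sample at-or-past each threshold in the
    # direction of travel, so every scanned time trails the true crossing
    # by less than one period and duration differences stay within one
    def scan_up(f):
        thr = f * peak
        j = i_pk
        while j > 0 and x[j - 1] >= thr:
            j -= 1
        return j / rate

    def scan_down(f):
        thr = f * peak
        j = i_pk
        while j < len(x) - 1 and x[j] >= thr:
            j += 1
        return j / rate

    t_r = scan_up(0.9) - scan_up(0.1)
    t_d = scan_down(0.1) - scan_down(0.9)
    fdhm = scan_down(0.5) - scan_up(0.5)
    return (m.t_r, m.t_d, m.fdhm), (t_r, t_d, fdhm)


class TestQcRules:
    def make_peak(self, amp, noise):
        return PeakMetrics(0.0, amp, 1.0, 0.1, 0.2, 0.15, noise_sd=noise)

    def test_below_twice_noise_discarded(self):
        assert qc_response(self.make_peak(1.5, 1.0), 0.0, 10.0) == QC_BELOW_2X_NOISE

    def test_sentinel_above_glu_discarded(self):
        assert qc_response(self.make_peak(50.0, 1.0), 120.0, 100.0) == QC_SENTINEL_EXCEEDS_GLU

    def test_clean_response_retained(self):
        assert qc_response(self.make_peak(10.0, 1.0), 20.0, 100.0) == QC_OK


class TestSliceHealth:
    def test_eighty_percent_boundary(self):
        # reference is mean of the first three controls (100)
        assert slice_health([100, 100, 100, 79])[-1] == "discarded"
        assert slice_health([100, 100, 100, 80])[-1] == "discarded"  # "80% or less"
        assert slice_health([100, 100, 100, 81])[-1] == "ok"

    def test_discard_is_sticky(self):
        status = slice_health([100, 100, 100, 75, 95, 99])
        assert status == ["ok", "ok", "ok", "discarded", "discarded", "discarded"]

    def test_needs_three_controls(self):
        with pytest.raises(ValueError):
            slice_health([100, 100])


class TestInterictalSpikes:
    def test_scripted_spikes_recovered(self, sensor, instant_kinetics, ideal_cal):
        from ampsense.deconvolution import deconvolve_trace

        script = [Segment("interictal", 70.0, {"n_spikes": 9, "spike_rate": 0.13})]
        trace, truth = make_invivo_session(
            script, sensor, instant_kinetics, seed=11, rate=1000.0, noise_sd=0.5
        )
        conc = deconvolve_trace(trace, ideal_cal)
        events, summary = detect_interictal_spikes(conc, depart_threshold=0.3)
        assert summary["count"] == 9
        assert summary["mean_duration"] == pytest.approx(0.44, rel=0.10)
        assert summary["frequency"] == pytest.approx(9 / 70.0, rel=0.05)
        assert all(ev.polarity == "negative" for ev in events)

    def test_flat_trace_yields_no_spikes(self):
        conc = conc_trace(np.full(5000, 18.0), np.full(5000, 15.0))
        events, summary = detect_interictal_spikes(conc)
        assert events == [] and summary["count"] == 0

    def test_spike_without_return_excluded(self):
        glu = np.full(5000, 18.0)
        glu[4000:] = 2.0  # departs, never returns
        conc = conc_trace(glu, np.full(5000, 15.0))
        events, summary = detect_interictal_spikes(conc, analytes=("glu",))
        assert summary["count"] == 0 and summary["truncated"] == 1


class TestSegmentation:
    def make_stim_trace(self, sensor, kinetics, artifact_amp=0.0, seed=0):
        events = EventTable(
            stim_events=[
                StimEvent(time=15.0 + 40.0 * i, kind="train", frequency=10.0, train_duration=5.0)
                for i in range(4)
            ]
        )
        artifacts = []
        if artifact_amp > 0:
            for ev in events.stim_events:
                for k in range(int(ev.frequency * ev.train_duration)):
                    artifacts.append(ArtifactEvent(ev.time + k / ev.frequency, artifact_amp))
        truth = GroundTruth(
            glu_conc=lambda t: sum(
                100.0 * ((t > ev.time) & (t < ev.time + 8.0)) for ev in events.stim_events
            ),
            artifact_events=artifacts,
            seed=seed,
        )
        trace, _ = simulate_channels(sensor, kinetics, truth, duration=175, rate=200)
        return trace, events

    def test_four_stimulations_partition_trace(self, sensor, instant_kinetics):
        trace, events = self.make_stim_trace(sensor, instant_kinetics)
        segs = segment_responses(trace, events)
        assert len(segs) == 4
        assert sum(len(s) for s in segs) == len(trace.slice(15.0, trace.duration))
        assert segs[0].t0 == pytest.approx(15.0)

    def test_zero_blank_is_identity_on_samples(self, sensor, instant_kinetics):
        trace, events = self.make_stim_trace(sensor, instant_kinetics)
        segs = segment_responses(trace, events, artifact_blank=0.0)
        assert not np.isnan(segs[0].channels["glu_raw"]).any()

    def test_overlapping_stimulations_rejected(self, sensor, instant_kinetics):
        trace, _ = self.make_stim_trace(sensor, instant_kinetics)
        bad = EventTable(
            stim_events=[
                StimEvent(time=20.0, kind="train", frequency=10.0, train_duration=5.0),
                StimEvent(time=22.0, kind="train", frequency=10.0, train_duration=5.0),
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            segment_responses(trace, bad)

    def test_masked_artifacts_match_artifact_free_metrics(self, sensor):
        # paired simulation: identical seeds, with and without artifact
        # spikes; with the artifacts masked the kinetics must agree
        kin = KineticsParams(tau_rise=0.5, tau_decay=1.5)
        clean, events = self.make_stim_trace(sensor, kin, artifact_amp=0.0, seed=9)
        dirty, _ = self.make_stim_trace(sensor, kin, artifact_amp=800.0, seed=9)
        blank = 0.03  # covers each 5-ms artifact after every pulse
        for s_clean, s_dirty in zip(
            segment_responses(clean, events, artifact_blank=blank),
            segment_responses(dirty, events, artifact_blank=blank),
        ):
            m_clean = response_peak_metrics(s_clean, channel="glu_raw")
            m_dirty = response_peak_metrics(s_dirty, channel="glu_raw")
            for attr in ("t_r", "t_d", "fdhm", "peak_amplitude", "baseline"):
                assert getattr(m_dirty, attr) == pytest.approx(
                    getattr(m_clean, attr), abs=1e-6
                )
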