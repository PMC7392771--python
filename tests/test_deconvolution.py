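import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ampsense.calibration import CalibrationQualityError, FamilyLine
from ampsense.deconvolution import (
    FLAG_CLIPPED_NEGATIVE,
    FLAG_FAMILY_EXTRAPOLATED,
    FLAG_OUT_OF_LINEAR_RANGE,
    convert_peak,
    deconvolve_trace,
    gaba_concentration,
    gaba_current,
    glu_concentration,
    glu_crosstalk_current,
    subtract_sentinel,
)
from ampsense.synthetic import GroundTruth, InterferentEvent, simulate_channels

TWO_LINE_FAMILY = [FamilyLine(50.0, 14.0, 0.0), FamilyLine(100.0, 28.0, 0.0)]


class TestScalarSteps:
    def test_sentinel_subtraction(self):
        assert subtract_sentinel(100.0, 20.0) == 80.0
        assert subtract_sentinel(7.5, 0.0) == 7.5
        assert subtract_sentinel(10.0, 30.0) == -20.0  # clipped downstream

    def test_glu_concentration_division(self, ideal_cal):
        ideal_cal.ss_glu = 4.0
        conc, flags = glu_concentration(80.0, ideal_cal)
        assert conc == 20.0 and flags == 0
        assert glu_concentration(0.0, ideal_cal)[0] == 0.0

    def test_negative_current_clipped_and_flagged(self, ideal_cal):
        conc, flags = glu_concentration(-10.0, ideal_cal)
        assert conc == 0.0 and flags & FLAG_CLIPPED_NEGATIVE

    def test_above_linear_range_flagged_not_altered(self, ideal_cal):
        i = ideal_cal.ss_glu * 350.0  # 350 µM > 300 µM linear range
        conc, flags = glu_concentration(i, ideal_cal)
        assert conc == pytest.approx(350.0)
        assert flags & FLAG_OUT_OF_LINEAR_RANGE

    def test_crosstalk_current(self, ideal_cal):
        ideal_cal.ss_glu_in_gaba = 4.5
        assert glu_crosstalk_current(20.0, ideal_cal) == pytest.approx(90.0)
        assert glu_crosstalk_current(0.0, ideal_cal) == 0.0
        with pytest.raises(ValueError):
            glu_crosstalk_current(-1.0, ideal_cal)

    def test_gaba_current_double_subtraction(self):
        assert gaba_current(300.0, 90.0, 20.0) == pytest.approx(190.0)
        assert gaba_current(0.0, 0.0, 0.0) == 0.0
        assert gaba_current(50.0, 90.0, 0.0) == pytest.approx(-40.0)


class TestFamilyInversion:
    def test_hand_interpolated_value(self):
        # at [GLU]=100 the two lines predict 1400 and 2800 nA/cm²;
        # 2100 sits halfway: 75 µM GABA
        gaba, flags = gaba_concentration(2100.0, 100.0, TWO_LINE_FAMILY)
        assert gaba == pytest.approx(75.0) and flags == 0

    def test_density_on_anchor_line(self):
        assert gaba_concentration(1400.0, 100.0, TWO_LINE_FAMILY)[0] == pytest.approx(50.0)

    def test_above_top_line_clamped_and_flagged(self):
        gaba, flags = gaba_concentration(5000.0, 100.0, TWO_LINE_FAMILY)
        assert gaba == 100.0 and flags & FLAG_FAMILY_EXTRAPOLATED

    def test_below_lowest_line_interpolates_toward_zero(self):
        gaba, flags = gaba_concentration(700.0, 100.0, TWO_LINE_FAMILY)
        assert gaba == pytest.approx(25.0) and flags == 0

    def test_non_monotone_predictions_rejected(self):
        bad = [FamilyLine(50.0, 14.0, 2000.0), FamilyLine(100.0, 15.0, 0.0)]
        with pytest.raises(CalibrationQualityError):
            gaba_concentration(1000.0, 10.0, bad)

    @settings(deadline=None, max_examples=60)
    @given(
        g=st.floats(0.0, 100.0),
        glu=st.floats(1.0, 300.0),
    )
    def test_inverse_consistency_within_anchor_span(self, g, glu):
        # forward family evaluation then inversion returns the level
        levels = np.array([0.0, 50.0, 100.0])
        slopes = np.array([0.0, 14.0, 28.0])
        density = np.interp(g, levels, slopes) * glu
        back, _ = gaba_concentration(density, glu, TWO_LINE_FAMILY)
        assert back == pytest.approx(g, rel=1e-9, abs=1e-9)


class TestTraceDeconvolution:
    def test_noiseless_end_to_end_identity(self, sensor, instant_kinetics, ideal_cal):
        glu = lambda t: 10.0 + 200.0 * ((t > 2) & (t < 6))
        gaba = lambda t: 20.0 + 300.0 * ((t > 3) & (t < 7))
        truth = GroundTruth(glu_conc=glu, gaba_conc=gaba, seed=0)
        trace, truth = simulate_channels(sensor, instant_kinetics, truth, duration=10, rate=200)
        conc = deconvolve_trace(trace, ideal_cal)
        np.testing.assert_allclose(conc.glu, truth.glu_conc, rtol=1e-9)
        np.testing.assert_allclose(conc.gaba, truth.gaba_conc, rtol=1e-9, atol=1e-9)

    def test_interferent_transients_cancel_exactly(self, sensor, instant_kinetics, ideal_cal):
        base = GroundTruth(glu_conc=50.0, gaba_conc=80.0, seed=0)
        events = [InterferentEvent(1.0, 500.0, 0.5), InterferentEvent(3.0, 1200.0, 1.0)]
        with_aa = GroundTruth(glu_conc=50.0, gaba_conc=80.0, interferent_events=events, seed=0)
        t_clean, _ = simulate_channels(sensor, instant_kinetics, base, duration=5, rate=200)
        t_aa, _ = simulate_channels(sensor, instant_kinetics, with_aa, duration=5, rate=200)
        c_clean = deconvolve_trace(t_clean, ideal_cal)
        c_aa = deconvolve_trace(t_aa, ideal_cal)
        np.testing.assert_allclose(c_aa.glu, c_clean.glu, atol=1e-9)
        np.testing.assert_allclose(c_aa.gaba, c_clean.gaba, atol=1e-9)

    def test_all_zero_trace_gives_zero_concentrations(self, ideal_cal):
        from ampsense.trace_io import TimeSeriesTrace

        tr = TimeSeriesTrace(
            sampling_rate=1000.0,
            channels={c: np.zeros(100) for c in ("gaba_raw", "glu_raw", "sentinel")},
        )
        conc = deconvolve_trace(tr, ideal_cal)
        np.testing.assert_array_equal(conc.glu, 0.0)
        np.testing.assert_array_equal(conc.gaba, 0.0)

    def test_glu_only_input_yields_zero_gaba(self, sensor, instant_kinetics, ideal_cal):
        truth = GroundTruth(glu_conc=lambda t: 100.0 + 50 * np.sin(t), gaba_conc=0.0, seed=0)
        trace, _ = simulate_channels(sensor, instant_kinetics, truth, duration=5, rate=200)
        conc = deconvolve_trace(trace, ideal_cal)
        np.testing.assert_allclose(conc.gaba, 0.0, atol=1e-9)

    def test_linear_in_corrected_current_within_range(self, sensor, instant_kinetics, ideal_cal):
        # doubling both concentrations doubles the recovered values while
        # every sample stays inside the linear ranges
        def run(scale):
            truth = GroundTruth(glu_conc=40.0 * scale, gaba_conc=100.0 * scale, seed=0)
            tr, _ = simulate_channels(sensor, instant_kinetics, truth, duration=1, rate=100)
            return deconvolve_trace(tr, ideal_cal)

        c1, c2 = run(1.0), run(2.0)
        assert not (c1.glu_flags.any() or c2.glu_flags.any())
        np.testing.assert_allclose(c2.glu, 2 * c1.glu, rtol=1e-9)
        np.testing.assert_allclose(c2.gaba, 2 * c1.gaba, rtol=1e-9)

    def test_agrees_with_root_finding_oracle(self, sensor, instant_kinetics, ideal_cal):
        # independent route: per sample, solve the forward model for
        # (glu, gaba) by division plus 1-D root finding on the family
        truth = GroundTruth(
            glu_conc=lambda t: 60 + 40 * np.sin(2 * t),
            gaba_conc=lambda t: 200 + 150 * np.cos(3 * t),
            seed=0,
        )
        trace, truth = simulate_channels(sensor, instant_kinetics, truth, duration=3, rate=50)
        conc = deconvolve_trace(trace, ideal_cal)

        levels = np.array([0.0] + [f.gaba_level for f in ideal_cal.gaba_family])
        slopes = np.array([0.0] + [f.slope for f in ideal_cal.gaba_family])
        for i in range(0, len(trace), 17):
            i_glu = trace.channels["glu_raw"][i] - trace.channels["sentinel"][i]
            glu = i_glu / sensor.ss_glu
            resid = (
                trace.channels["gaba_raw"][i]
                - glu * sensor.ss_glu_in_gaba
                - trace.channels["sentinel"][i]
            ) / 1000.0 / sensor.area

            def f(g):
                return np.interp(g, levels, slopes) * glu - resid

            gaba = brentq(f, 0.0, levels[-1])
            assert conc.glu[i] == pytest.approx(glu, rel=1e-9)
            assert conc.gaba[i] == pytest.approx(gaba, rel=1e-7, abs=1e-7)

    def test_peak_reference_path_matches_sample_wise(self, ideal_cal):
        out = convert_peak(500.0, 2500.0, 40.0, ideal_cal)
        assert out["i_glu"] == pytest.approx(460.0)
        assert out["glu_uM"] == pytest.approx(460.0 / ideal_cal.ss_glu)
        # and the same numbers through the trace path
        from ampsense.trace_io import TimeSeriesTrace

        tr = TimeSeriesTrace(
            sampling_rate=1000.0,
            channels={
                "gaba_raw": np.full(3, 2500.0),
                "glu_raw": np.full(3, 500.0),
                "sentinel": np.full(3, 40.0),
            },
        )
        conc = deconvolve_trace(tr, ideal_cal)
        assert conc.glu[0] == pytest.approx(out["glu_uM"], rel=1e-12)
        assert conc.gaba[0] == pytest.approx(out["gaba_uM"], rel=1e-12)

    def test_csv_export_round_trips(self, tmp_path, sensor, instant_kinetics, ideal_cal):
        import pandas as pd

        truth = GroundTruth(glu_conc=30.0, gaba_conc=100.0, seed=0)
        trace, _ = simulate_channels(sensor, instant_kinetics, truth, duration=0.2, rate=100)
        conc = deconvolve_trace(trace, ideal_cal)
        conc.to_csv(tmp_path / "c.csv")
        df = pd.read_csv(tmp_path / "c.csv")
        assert list(df.columns) == ["time_s", "glu_uM", "gaba_uM", "flags"]
        np.testing.assert_allclose(df["glu_uM"], conc.glu, rtol=1e-9)
        assert set(df["flags"]) == {"ok"}
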