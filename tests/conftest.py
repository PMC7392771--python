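import numpy as np
import pytest

from ampsense.calibration import FamilyLine, SensorCalibration
from ampsense.synthetic import KineticsParams, SensorParams


def calibration_from_sensor(sensor: SensorParams, with_ranges: bool = True) -> SensorCalibration:
    """The calibration an ideal fit of the simulated sensor would return."""
    cal = SensorCalibration(
        ss_glu=sensor.ss_glu,
        ss_glu_in_gaba=sensor.ss_glu_in_gaba,
        gaba_family=[FamilyLine(g, s, b) for g, s, b in sensor.gaba_family],
        area=sensor.area,
        sensor_id="synthetic-ideal",
    )
    if with_ranges:
        cal.linear_range = {"GLU": sensor.linear_range_glu, "GABA": sensor.linear_range_gaba}
    return cal


@pytest.fixture
def sensor() -> SensorParams:
    return SensorParams()


@pytest.fixture
def ideal_cal(sensor) -> SensorCalibration:
    return calibration_from_sensor(sensor)


@pytest.fixture
def instant_kinetics() -> KineticsParams:
    return KineticsParams(tau_rise=0.0, tau_decay=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
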