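"""Convert raw three-channel currents into GLU and GABA concentrations.

The conversion chain, applied either to scalar peak currents (the
reference path) or sample-wise to whole traces:

1. sentinel subtraction:      I_GLU = I_RAW.GLU - I_Sentinel
2. GLU concentration:         [GLU] = I_GLU / SS_GLU
3. crosstalk on GABA channel: I_GLU.in.GABA = [GLU] x SS_GLU.in.GABA
4. GABA current:              I_GABA = (I_GABA+GLU - I_GLU.in.GABA) - I_Sentinel

The GABA current is converted to a current density (nA/cm², dividing by
the electrode area) and inverted through the calibration line family:
each family line predicts a density at the measured [GLU], and the GABA
concentration is found by piecewise-linear interpolation of the GABA level
against those predicted densities. Below the lowest line the interpolation
extends toward zero; above the highest line the result clamps to the top
level and is flagged as extrapolated. Negative concentrations are clipped
to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationQualityError, SensorCalibration
from .trace_io import TimeSeriesTrace

__all__ = [
    "ConcentrationTrace",
    "FLAG_OK",
    "FLAG_CLIPPED_NEGATIVE",
    "FLAG_OUT_OF_LINEAR_RANGE",
    "FLAG_FAMILY_EXTRAPOLATED",
    "subtract_sentinel",
    "glu_concentration",
    "glu_crosstalk_current",
    "gaba_current",
    "gaba_concentration",
    "deconvolve_trace",
    "convert_peak",
]

# per-sample flag bits
FLAG_OK = 0
FLAG_CLIPPED_NEGATIVE = 1
FLAG_OUT_OF_LINEAR_RANGE = 2
FLAG_FAMILY_EXTRAPOLATED = 4

_FLAG_NAMES = {
    FLAG_CLIPPED_NEGATIVE: "clipped_negative",
    FLAG_OUT_OF_LINEAR_RANGE: "out_of_linear_range",
    FLAG_FAMILY_EXTRAPOLATED: "family_extrapolated",
}


def flag_names(code: int) -> str:
    """Human-readable form of a flag bitmask (``"ok"`` when clear)."""
    names = [n for bit, n in _FLAG_NAMES.items() if code & bit]
    return "+".join(names) if names else "ok"


@dataclass
class ConcentrationTrace:
    """Derived [GLU](t) and [GABA](t) with per-sample QC flags."""

    sampling_rate: float
    glu: np.ndarray  # µM
    gaba: np.ndarray  # µM
    glu_flags: np.ndarray  # int bitmask per sample
    gaba_flags: np.ndarray
    t0: float = 0.0
    provenance: str = ""  # calibration id
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.glu) == len(self.gaba) == len(self.glu_flags) == len(self.gaba_flags)):
            raise ValueError("series lengths differ")

    def __len__(self) -> int:
        return len(self.glu)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sampling_rate

    def to_csv(self, path) -> None:
        combined = self.glu_flags | self.gaba_flags
        pd.DataFrame(
            {
                "time_s": self.time,
                "glu_uM": self.glu,
                "gaba_uM": self.gaba,
                "flags": [flag_names(int(c)) for c in combined],
            }
        ).to_csv(path, index=False, float_format="%.12g")


def subtract_sentinel(i_raw, i_sentinel):
    """Remove interferent current measured on the enzyme-free sentinel wire."""
    return np.asarray(i_raw, dtype=float) - np.asarray(i_sentinel, dtype=float)


def glu_concentration(i_glu, cal: SensorCalibration):
    """[GLU] = I_GLU / SS_GLU, with clipping and linear-range flags.

    Returns ``(conc µM, flags)``; works on scalars and arrays alike.
    """
    if cal is None or cal.ss_glu <= 0:
        raise ValueError("a calibration with positive ss_glu is required")
    scalar = np.ndim(i_glu) == 0
    conc = np.atleast_1d(np.asarray(i_glu, dtype=float)) / cal.ss_glu
    flags = np.zeros(conc.shape, dtype=int)
    neg = conc < 0
    flags[neg] |= FLAG_CLIPPED_NEGATIVE
    conc = np.where(neg, 0.0, conc)
    upper = cal.linear_range.get("GLU")
    if upper is not None:
        flags[conc > upper] |= FLAG_OUT_OF_LINEAR_RANGE
    if scalar:
        return float(conc[0]), int(flags[0])
    return conc, flags


def glu_crosstalk_current(glu_conc, cal: SensorCalibration):
    """Current the measured GLU contributes to the GABA channel (pA)."""
    glu_conc = np.asarray(glu_conc, dtype=float)
    if np.any(glu_conc < 0):
        raise ValueError("glu_conc must be non-negative")
    return glu_conc * cal.ss_glu_in_gaba


def gaba_current(i_gaba_plus_glu, crosstalk, i_sentinel):
    """GABA-attributable current: raw GABA channel minus crosstalk and sentinel."""
    return (
        np.asarray(i_gaba_plus_glu, dtype=float)
        - np.asarray(crosstalk, dtype=float)
        - np.asarray(i_sentinel, dtype=float)
    )


def gaba_concentration(i_gaba_density, glu_conc, family):
    """Invert the calibration line family at the measured [GLU].

    ``i_gaba_density`` is the GABA-attributable current density (nA/cm²)
    and ``family`` the sorted list of :class:`~ampsense.calibration.FamilyLine`.
    Each line predicts a density at ``glu_conc``; GABA level is interpolated
    piecewise-linearly against those predictions, anchored at (0, 0) below
    the lowest line and clamped (with a flag) above the highest.

    Returns ``(gaba µM, flags)``.
    """
    if len(family) < 2:
        raise ValueError("family needs >= 2 levels")
    d = np.atleast_1d(np.asarray(i_gaba_density, dtype=float))
    g = np.atleast_1d(np.asarray(glu_conc, dtype=float))
    if np.any(g < 0):
        raise ValueError("glu_conc must be non-negative")
    d, g = np.broadcast_arrays(d, g)
    levels = np.array([0.0] + [f.gaba_level for f in family])
    slopes = np.array([0.0] + [f.slope for f in family])
    intercepts = np.array([0.0] + [f.intercept for f in family])
    # predicted density of each line at each sample's [GLU]: (levels, n)
    pred = slopes[:, None] * g[None, :] + intercepts[:, None]
    if np.any(np.diff(pred, axis=0) <= 0) and np.any(g > 0):
        bad = np.where(np.any(np.diff(pred, axis=0) <= 0, axis=0) & (g > 0))[0]
        if bad.size:
            raise CalibrationQualityError(
                "family lines give non-monotone predicted densities "
                f"at [GLU]={g[bad[0]]:g} µM"
            )
    flags = np.zeros(d.shape, dtype=int)
    out = np.zeros(d.shape, dtype=float)
    top = pred[-1]
    # with no GLU (and a through-origin family) every line collapses and the
    # family carries no information: no α-keto shuttle means GABA is unseen
    uninformative = top <= 0
    flags[uninformative & (d > 0)] |= FLAG_FAMILY_EXTRAPOLATED
    neg = ~uninformative & (d < 0)
    flags[neg] |= FLAG_CLIPPED_NEGATIVE
    above = ~uninformative & (d >= top)
    out[above] = levels[-1]
    flags[above & (d > top)] |= FLAG_FAMILY_EXTRAPOLATED
    mid = ~(uninformative | above | neg)
    if np.any(mid):
        idx = np.arange(len(d))[mid]
        # locate the bracketing pair of lines per sample
        k = np.sum(pred[:, idx] <= d[idx][None, :], axis=0) - 1
        k = np.clip(k, 0, len(levels) - 2)
        p_lo = pred[k, idx]
        p_hi = pred[k + 1, idx]
        frac = (d[idx] - p_lo) / (p_hi - p_lo)
        out[idx] = levels[k] + frac * (levels[k + 1] - levels[k])
    if np.ndim(i_gaba_density) == 0 and np.ndim(glu_conc) == 0:
        return float(out[0]), int(flags[0])
    return out, flags


def deconvolve_trace(trace: TimeSeriesTrace, cal: SensorCalibration) -> ConcentrationTrace:
    """Apply the full conversion chain sample-wise to a three-channel trace."""
    sent = trace.channels["sentinel"]
    i_glu = subtract_sentinel(trace.channels["glu_raw"], sent)
    glu, glu_flags = glu_concentration(i_glu, cal)
    crosstalk = glu_crosstalk_current(glu, cal)
    i_gaba = gaba_current(trace.channels["gaba_raw"], crosstalk, sent)
    density = (i_gaba / 1000.0) / cal.area  # pA -> nA/cm²
    gaba, gaba_flags = gaba_concentration(density, glu, cal.gaba_family)
    upper = cal.linear_range.get("GABA")
    if upper is not None:
        gaba_flags[gaba > upper] |= FLAG_OUT_OF_LINEAR_RANGE
    return ConcentrationTrace(
        sampling_rate=trace.sampling_rate,
        glu=np.asarray(glu, dtype=float),
        gaba=np.asarray(gaba, dtype=float),
        glu_flags=glu_flags,
        gaba_flags=gaba_flags,
        t0=trace.t0,
        provenance=cal.sensor_id,
        metadata=dict(trace.metadata),
    )


def convert_peak(
    i_raw_glu: float,
    i_gaba_plus_glu: float,
    i_sentinel: float,
    cal: SensorCalibration,
) -> dict:
    """Reference peak-level conversion of one response's peak currents.

    Returns the intermediate currents and final concentrations as a dict:
    ``i_glu``, ``glu_uM``, ``crosstalk_pA``, ``i_gaba``, ``gaba_uM`` plus
    per-analyte flags.
    """
    i_glu = subtract_sentinel(i_raw_glu, i_sentinel)
    glu, glu_flags = glu_concentration(float(i_glu), cal)
    glu = float(np.asarray(glu).reshape(()))
    crosstalk = float(glu_crosstalk_current(glu, cal))
    i_gaba = float(gaba_current(i_gaba_plus_glu, crosstalk, i_sentinel))
    density = (i_gaba / 1000.0) / cal.area
    gaba, gaba_flags = gaba_concentration(density, glu, cal.gaba_family)
    return {
        "i_glu": float(i_glu),
        "glu_uM": glu,
        "glu_flags": int(np.asarray(glu_flags).reshape(())),
        "crosstalk_pA": crosstalk,
        "i_gaba": i_gaba,
        "gaba_uM": float(gaba),
        "gaba_flags": int(gaba_flags),
    }
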