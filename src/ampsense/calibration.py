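"""Derive a SensorCalibration from stepwise-addition calibration sessions.

Sensitivity is the slope (pA/µM) of plateau current versus bath
concentration; dividing by the Pt microwire area (1.27e-4 cm² by default)
converts it to a current density sensitivity in nA/(µM·cm²). The limit of
detection follows the 3-sigma convention (three times the standard
deviation of ten analyte-free baseline samples divided by the slope), and
selectivity is the analyte/interferent sensitivity ratio. The GABA channel
is calibrated as a family of lines -- current density versus [GLU], one
line per GABA level -- whose slopes must increase with GABA level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace_io import CalibrationProtocol, TimeSeriesTrace

__all__ = [
    "SensorCalibration",
    "FamilyLine",
    "LinearFit",
    "detect_steps",
    "fit_sensitivity",
    "to_current_density",
    "determine_linear_range",
    "compute_lod",
    "compute_selectivity",
    "fit_gaba_family",
    "anova_oneway",
    "ttest_independent",
    "InsufficientDataError",
    "CalibrationQualityError",
]


class InsufficientDataError(ValueError):
    pass


class CalibrationQualityError(ValueError):
    pass


@dataclass
class LinearFit:
    slope: float  # pA/µM
    intercept: float  # pA
    r2: float
    sem: float  # standard error of the slope
    n: int


@dataclass
class FamilyLine:
    gaba_level: float  # µM
    slope: float  # nA/(µM·cm²) per µM GLU
    intercept: float  # nA/cm²
    r2: float = 1.0


@dataclass
class SensorCalibration:
    """Calibration constants for one three-wire sensor."""

    ss_glu: float  # pA/µM, GLU channel
    ss_glu_in_gaba: float  # pA/µM, GLU response of the GABA channel at [GABA]=0
    gaba_family: list  # FamilyLine, sorted by gaba_level
    area: float = 1.27e-4  # cm²
    lod: dict = field(default_factory=dict)  # µM per analyte/channel key
    selectivity: dict = field(default_factory=dict)  # ratio per analyte
    linear_range: dict = field(default_factory=dict)  # µM upper bound per analyte
    diagnostics: dict = field(default_factory=dict)  # fit R², slope SEM, ...
    sensor_id: str = ""

    def __post_init__(self) -> None:
        if self.ss_glu <= 0:
            raise ValueError("ss_glu must be positive")
        fam = sorted(self.gaba_family, key=lambda f: f.gaba_level)
        slopes = [f.slope for f in fam]
        if any(s2 <= s1 for s1, s2 in zip(slopes, slopes[1:])):
            raise CalibrationQualityError("gaba_family slopes must increase with gaba_level")
        self.gaba_family = fam

    def to_json(self, path) -> None:
        doc = {
            "schema": "ampsense.sensor_calibration/1",
            "sensor_id": self.sensor_id,
            "ss_glu": self.ss_glu,
            "ss_glu_in_gaba": self.ss_glu_in_gaba,
            "area": self.area,
            "gaba_family": [vars(f) for f in self.gaba_family],
            "lod": self.lod,
            "selectivity": self.selectivity,
            "linear_range": self.linear_range,
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SensorCalibration":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            ss_glu=doc["ss_glu"],
            ss_glu_in_gaba=doc["ss_glu_in_gaba"],
            gaba_family=[FamilyLine(**f) for f in doc["gaba_family"]],
            area=doc.get("area", 1.27e-4),
            lod=doc.get("lod", {}),
            selectivity=doc.get("selectivity", {}),
            linear_range=doc.get("linear_range", {}),
            diagnostics=doc.get("diagnostics", {}),
            sensor_id=doc.get("sensor_id", ""),
        )


def detect_steps(
    trace: TimeSeriesTrace,
    protocol: CalibrationProtocol,
    channel: str = "glu_raw",
    analyte: str | None = None,
    settle: float = 20.0,
    window: float = 30.0,
    guard: float = 2.0,
) -> list[dict]:
    """Measure the plateau current after each stepwise addition.

    For each addition, the plateau is the mean current over a ``window``
    that ends ``guard`` seconds before the next addition (or the end of the
    trace) and begins no earlier than ``settle`` seconds after the
    addition; ``sd`` is the standard deviation over the same window.
    """
    additions = protocol.additions
    if analyte is not None:
        additions = [a for a in additions if a.analyte == analyte]
    if not additions:
        raise InsufficientDataError("no additions for requested analyte")
    x = trace.channels[channel]
    t_end = trace.t0 + trace.duration
    out = []
    for i, a in enumerate(additions):
        nxt = additions[i + 1].time if i + 1 < len(additions) else t_end + 1.0 / trace.sampling_rate
        w_end = min(nxt, t_end + 1.0 / trace.sampling_rate) - guard
        w_start = max(a.time + settle, w_end - window)
        if w_start >= w_end or w_start < a.time + settle - 1e-9:
            raise ValueError(
                f"no room for a plateau window after addition at {a.time} s "
                f"(settle={settle}, window={window}, guard={guard})"
            )
        i0 = int(np.ceil((w_start - trace.t0) * trace.sampling_rate))
        i1 = int(np.floor((w_end - trace.t0) * trace.sampling_rate)) + 1
        i1 = min(i1, len(x))
        seg = x[i0:i1]
        out.append(
            {
                "concentration": a.target_concentration,
                "plateau": float(np.mean(seg)),
                "sd": float(np.std(seg, ddof=1)) if len(seg) > 1 else 0.0,
                "n": len(seg),
            }
        )
    return out


def fit_sensitivity(points, range_limit: float = np.inf) -> LinearFit:
    """Ordinary least squares of plateau current on concentration.

    ``points`` is an iterable of (concentration µM, plateau pA) pairs or
    the dict records from :func:`detect_steps`. Only points with
    concentration <= range_limit enter the fit; the slope is the
    sensitivity in pA/µM (an intercept is fitted but not part of the
    sensitivity).
    """
    pts = [
        (p["concentration"], p["plateau"]) if isinstance(p, dict) else (p[0], p[1])
        for p in points
    ]
    pts = [(c, y) for c, y in pts if c <= range_limit]
    if len(pts) < 3:
        raise InsufficientDataError(f"need >= 3 in-range points, got {len(pts)}")
    c = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res = stats.linregress(c, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        sem=float(res.stderr),
        n=len(pts),
    )


def to_current_density(slope: float, area: float) -> float:
    """pA/µM -> nA/(µM·cm²): divide by 1000 (pA->nA) and by electrode area."""
    if area <= 0:
        raise ValueError("electrode area must be positive")
    return (slope / 1000.0) / area


def determine_linear_range(points, r2_threshold: float = 0.98) -> tuple[float, bool]:
    """Upper concentration bound of the linear response region.

    Takes the largest prefix of the ascending-concentration points whose
    OLS fit keeps R² >= ``r2_threshold``; returns ``(bound_µM, flagged)``
    where ``flagged`` marks the degenerate case in which even the smallest
    3-point prefix fails the threshold (the bound then covers that minimal
    prefix anyway).
    """
    pts = sorted(
        (p["concentration"], p["plateau"]) if isinstance(p, dict) else (p[0], p[1])
        for p in points
    )
    if len(pts) < 4:
        raise InsufficientDataError("need >= 4 points to determine a linear range")
    best, flagged = None, False
    for k in range(3, len(pts) + 1):
        fit = fit_sensitivity(pts[:k])
        if fit.r2 >= r2_threshold:
            best = pts[k - 1][0]
    if best is None:
        best, flagged = pts[2][0], True
    return float(best), flagged


def compute_lod(baseline: np.ndarray, slope: float, n_points: int = 10) -> float:
    """Limit of detection: 3·sd of the last ``n_points`` baseline samples / slope (µM)."""
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) < n_points:
        raise InsufficientDataError(f"baseline needs >= {n_points} samples")
    if slope <= 0:
        raise ValueError("slope must be positive")
    return 3.0 * float(np.std(baseline[-n_points:], ddof=1)) / slope


def compute_selectivity(s_analyte: float, s_interferent: float) -> tuple[float, bool]:
    """Analyte/interferent sensitivity ratio; (inf, True) when the interferent slope is 0."""
    if s_analyte < 0 or s_interferent < 0:
        raise ValueError("sensitivities must be non-negative")
    if s_interferent == 0:
        return math.inf, True
    return s_analyte / s_interferent, False


def fit_gaba_family(grid: dict) -> list[FamilyLine]:
    """Fit the GABA-channel line family from a calibration grid.

    ``grid`` maps gaba_level (µM) to a list of (glu µM, current density
    nA/cm²) points; each level gets an OLS line. Slopes must increase with
    GABA level, otherwise the calibration is rejected.
    """
    if len(grid) < 2:
        raise InsufficientDataError("need >= 2 gaba levels")
    lines = []
    for level in sorted(grid):
        pts = grid[level]
        if len(pts) < 3:
            raise InsufficientDataError(f"gaba level {level}: need >= 3 GLU points")
        g = np.array([p[0] for p in pts], dtype=float)
        d = np.array([p[1] for p in pts], dtype=float)
        res = stats.linregress(g, d)
        lines.append(
            FamilyLine(
                gaba_level=float(level),
                slope=float(res.slope),
                intercept=float(res.intercept),
                r2=float(res.rvalue**2),
            )
        )
    slopes = [ln.slope for ln in lines]
    if any(s2 <= s1 for s1, s2 in zip(slopes, slopes[1:])):
        raise CalibrationQualityError("family slopes not strictly increasing with gaba_level")
    return lines


# -- group-comparison utilities used on calibration replicates -------------


def anova_oneway(*groups):
    """One-way ANOVA across groups: (F, p). Significance threshold alpha=0.05."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("need >= 2 groups of >= 2 values")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def ttest_independent(a, b):
    """Two-tailed independent-samples Student t-test: (t, p)."""
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 values per sample")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
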