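"""Calibration fitting, detection limits, and concentration readout.

Calibration curves are ordinary least squares of replicate-averaged line
intensity against concentration (or log10 concentration for the wide CRP
window).  The limit of detection comes from the limit of the blank,
mu_blank + 3*sigma_blank, mapped through the inverse calibration.  CRP is
quantified piecewise to handle the high-dose hook: a sandwich (test-line)
curve below 10 ug/mL and a competitive (antigen-line) curve above, with
the branch chosen from the antigen-line intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, FitError, InvalidTestError

CRP_BRANCH_BOUNDARY = 10.0  # ug/mL; hook onset for the CRP sandwich line

#: Clinical interpretation thresholds.  Bands are advisory flags against
#: normal ranges, never a diagnosis.
CLINICAL_THRESHOLDS: dict[str, dict] = {
    "CEA": {"units": "ng/mL", "normal_below": 5.0, "elevated_above": 20.0},
    "CA-125": {"units": "U/mL", "normal_upto": 35.0, "strongly_elevated_above": 100.0},
    "CRP": {"units": "ug/mL", "boundary": CRP_BRANCH_BOUNDARY},
}


class CurveForm(str, Enum):
    LINEAR_C = "linear_c"
    LINEAR_LOG10C = "linear_log10c"


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted intensity <-> concentration relation with blank statistics."""

    analyte: str
    line_role: str                 # "test" or "antigen"
    form: CurveForm
    slope: float
    intercept: float
    valid_range: tuple[float, float]
    r_squared: float
    residual_sd: float
    blank_mean: float
    blank_sd: float

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise FitError("valid_range must be non-degenerate")
        if not (0.0 <= self.r_squared <= 1.0):
            raise FitError("r_squared must lie in [0, 1]")

    @property
    def direction(self) -> str:
        return "increasing" if self.slope > 0 else "decreasing"

    def _x(self, c: float) -> float:
        return math.log10(c) if self.form is CurveForm.LINEAR_LOG10C else c

    def predict(self, c: float) -> float:
        """Forward-evaluate the fitted line: expected intensity at ``c``."""
        return self.slope * self._x(c) + self.intercept

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte, "line_role": self.line_role,
            "form": self.form.value, "slope": self.slope,
            "intercept": self.intercept, "valid_range": list(self.valid_range),
            "r_squared": self.r_squared, "residual_sd": self.residual_sd,
            "blank_mean": self.blank_mean, "blank_sd": self.blank_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationCurve":
        return cls(
            analyte=d["analyte"], line_role=d["line_role"],
            form=CurveForm(d["form"]), slope=d["slope"], intercept=d["intercept"],
            valid_range=tuple(d["valid_range"]), r_squared=d["r_squared"],
            residual_sd=d["residual_sd"], blank_mean=d["blank_mean"],
            blank_sd=d["blank_sd"],
        )


def fit_calibration(
    points: Sequence[tuple[float, Sequence[float]]],
    form: CurveForm | str = CurveForm.LINEAR_C,
    blanks: Sequence[float] = (),
    analyte: str = "",
    line_role: str = "test",
) -> CalibrationCurve:
    """OLS fit of replicate-mean intensity against c (or log10 c).

    ``points`` holds (concentration, replicate intensities) tuples;
    replicates are averaged with uniform weight before fitting.  Blank
    replicate intensities feed the limit-of-blank statistics.
    """
    form = CurveForm(form)
    concs = np.array([float(c) for c, _ in points])
    if len(set(concs.tolist())) < 4:
        raise FitError("need at least 4 distinct concentrations")
    if np.ptp(concs) == 0:
        raise FitError("all concentrations identical")
    if len(blanks) < 2:
        raise FitError("need at least 2 blank replicates")
    means = np.array([float(np.mean(reps)) for _, reps in points])
    if form is CurveForm.LINEAR_LOG10C:
        if np.any(concs <= 0):
            raise FitError("log10 form requires strictly positive concentrations")
        x = np.log10(concs)
    else:
        x = concs

    res = stats.linregress(x, means)
    fitted = res.slope * x + res.intercept
    resid = means - fitted
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(len(x) - 2, 1)))
    return CalibrationCurve(
        analyte=analyte,
        line_role=line_role,
        form=form,
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(concs.min()), float(concs.max())),
        r_squared=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
        residual_sd=residual_sd,
        blank_mean=float(np.mean(blanks)),
        blank_sd=float(np.std(blanks, ddof=1)),
    )


def lod(curve: CalibrationCurve) -> float:
    """Limit of detection: inverse calibration of the limit of the blank.

    LoB = mu_blank + 3*sigma_blank in intensity units; LOD is the
    concentration whose expected intensity equals the LoB, floored at 0.
    Defined for increasing (sandwich test line) curves only.
    """
    if curve.slope <= 0:
        raise ValueError("LOD is defined for increasing calibration curves")
    lob = curve.blank_mean + 3.0 * curve.blank_sd
    x = (lob - curve.intercept) / curve.slope
    c = 10.0**x if curve.form is CurveForm.LINEAR_LOG10C else x
    return max(0.0, float(c))


def snr(signal_intensities: Sequence[float], noise_intensities: Sequence[float]) -> float:
    """Signal-to-noise ratio: mean signal over noise standard deviation."""
    noise_sd = float(np.std(noise_intensities, ddof=1))
    if noise_sd == 0:
        raise ValueError("noise standard deviation is zero; SNR undefined")
    return float(np.mean(signal_intensities)) / noise_sd


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent (sample SD, n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("zero mean; CV undefined")
    return 100.0 * float(v.std(ddof=1)) / mean


@dataclass(frozen=True)
class ConcentrationEstimate:
    value: float
    units: str = ""
    in_range: bool = True
    below_lod: bool = False
    branch: str | None = None     # CRP: "low" or "high"

    @property
    def text(self) -> str:
        if self.below_lod:
            return "< LOD"
        return f"{self.value:.3g} {self.units}".strip()


def invert_calibration(
    curve: CalibrationCurve, intensity: float, units: str = ""
) -> ConcentrationEstimate:
    """Map a measured line intensity to concentration via the fitted curve.

    The raw inversion is clamped to the curve's valid range with an
    out-of-range flag; on an increasing curve an intensity at or below the
    limit of the blank is reported as "< LOD" rather than as a negative or
    extrapolated concentration.
    """
    if not math.isfinite(intensity):
        raise ValueError("intensity must be finite")
    if curve.slope == 0:
        raise ValueError("curve slope is zero; inversion undefined")
    x = (intensity - curve.intercept) / curve.slope
    c = 10.0**x if curve.form is CurveForm.LINEAR_LOG10C else x
    below_lod = False
    if curve.slope > 0 and intensity <= curve.blank_mean + 3.0 * curve.blank_sd:
        below_lod = True
    lo, hi = curve.valid_range
    in_range = lo <= c <= hi
    c = min(max(c, lo), hi)
    return ConcentrationEstimate(
        value=float(c), units=units, in_range=in_range, below_lod=below_lod
    )


def quantify_crp(
    test_intensity: float,
    antigen_intensity: float,
    low_curve: CalibrationCurve,
    high_curve: CalibrationCurve,
    units: str = "ug/mL",
) -> ConcentrationEstimate:
    """Piecewise CRP readout around the hook-effect boundary (10 ug/mL).

    The antigen (competitive) line decreases monotonically with CRP, so it
    selects the branch: at or above its expected intensity at 10 ug/mL the
    sample is in the sandwich regime and the test-line curve applies;
    below it, the antigen-line curve covers 10-500 ug/mL.
    """
    if low_curve.slope <= 0:
        raise ValueError("low curve must be increasing (sandwich line)")
    if high_curve.slope >= 0:
        raise ValueError("high curve must be decreasing (competitive line)")
    noise_floor_test = low_curve.blank_mean + 3.0 * low_curve.blank_sd
    if test_intensity < noise_floor_test and antigen_intensity < noise_floor_test:
        raise InvalidTestError(
            "both CRP lines below the noise floor; strip invalid or depleted"
        )
    crossover = high_curve.predict(CRP_BRANCH_BOUNDARY)
    if antigen_intensity >= crossover:
        est = invert_calibration(low_curve, test_intensity, units=units)
        lo, hi = low_curve.valid_range
        value = min(max(est.value, lo), min(hi, CRP_BRANCH_BOUNDARY))
        return ConcentrationEstimate(
            value=value, units=units, in_range=est.in_range,
            below_lod=est.below_lod, branch="low",
        )
    est = invert_calibration(high_curve, antigen_intensity, units=units)
    value = max(est.value, CRP_BRANCH_BOUNDARY)
    return ConcentrationEstimate(
        value=value, units=units, in_range=est.in_range, branch="high"
    )


@dataclass(frozen=True)
class AnalyteInterpretation:
    analyte: str
    concentration: float
    units: str
    band: str
    note: str


@dataclass(frozen=True)
class PanelResult:
    analytes: tuple[AnalyteInterpretation, ...]
    valid: bool = True

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "analytes": [
                {
                    "analyte": a.analyte, "concentration": a.concentration,
                    "units": a.units, "band": a.band, "note": a.note,
                }
                for a in self.analytes
            ],
        }


def interpret_panel(concentrations: Mapping[str, float]) -> PanelResult:
    """Band each analyte against its normal clinical range.

    CEA: normal < 5, intermediate 5-20, elevated > 20 ng/mL.
    CA-125: normal <= 35, elevated > 35, strongly elevated > 100 U/mL.
    CRP: reported relative to the 10 ug/mL sandwich/competitive boundary.
    Wording is advisory only.
    """
    interpretations = []
    for analyte, c in concentrations.items():
        if c < 0:
            raise ConfigError("concentrations must be non-negative")
        if analyte == "CEA":
            t = CLINICAL_THRESHOLDS["CEA"]
            if c < t["normal_below"]:
                band = "normal"
            elif c <= t["elevated_above"]:
                band = "intermediate"
            else:
                band = "elevated"
            note = "within normal range" if band == "normal" else (
                "above the normal range; advisory only, consult a clinician"
            )
        elif analyte == "CA-125":
            t = CLINICAL_THRESHOLDS["CA-125"]
            if c <= t["normal_upto"]:
                band = "normal"
            elif c <= t["strongly_elevated_above"]:
                band = "elevated"
            else:
                band = "strongly_elevated"
            note = "within normal range" if band == "normal" else (
                "above the normal range; advisory only, consult a clinician"
            )
        elif analyte == "CRP":
            boundary = CLINICAL_THRESHOLDS["CRP"]["boundary"]
            band = "low" if c <= boundary else "high"
            note = (
                f"{'at or below' if band == 'low' else 'above'} "
                f"{boundary:g} ug/mL; advisory only"
            )
        else:
            raise ConfigError(f"unknown analyte {analyte!r}")
        units = CLINICAL_THRESHOLDS[analyte]["units"]
        interpretations.append(
            AnalyteInterpretation(analyte, float(c), units, band, note)
        )
    return PanelResult(analytes=tuple(interpretations), valid=True)
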