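"""End-to-end orchestration: image -> detection -> classification ->
segmentation -> line intensities -> concentrations -> panel report.

Every stage failure produces a structured report (status "zone_not_found"
or "invalid_test"), never a partial silent result.  Inference is fully
deterministic: randomness exists only in simulation and training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .errors import ConfigError, InvalidTestError
from .imaging import (
    CONFIDENCE_THRESHOLD,
    DetectionResult,
    IntensityProfile,
    classify_readout,
    crop_readout_zone,
    detect_readout_zone,
    extract_intensity_profile,
    line_intensity,
    significance_floor,
)
from .quant import (
    CalibrationCurve,
    ConcentrationEstimate,
    interpret_panel,
    invert_calibration,
    quantify_crp,
)
from .segmentation import (
    FclModel,
    PeakSegment,
    assign_roles,
    predict_mask,
    segments_from_mask,
)
from .synthetic import (
    PROFILE_LEN,
    RESPONSES,
    THREE_LINE_LAYOUT,
    TWO_LINE_LAYOUT,
    LineRole,
    NoiseSpec,
    DEFAULT_NOISE,
    ReadoutClass,
    StripLayout,
    SyntheticSample,
    render_analyte_strip,
)

logger = logging.getLogger("lfaquant")

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class PipelineConfig:
    channel: str = "green"
    confidence_threshold: float = CONFIDENCE_THRESHOLD

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class AnalyteCurves:
    """Calibration curves for one analyte: sandwich test line, plus the
    competitive antigen-line curve for hook-affected analytes (CRP)."""

    test: CalibrationCurve
    antigen: CalibrationCurve | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test.to_dict(),
            "antigen": self.antigen.to_dict() if self.antigen else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalyteCurves":
        return cls(
            test=CalibrationCurve.from_dict(d["test"]),
            antigen=CalibrationCurve.from_dict(d["antigen"]) if d.get("antigen") else None,
        )


@dataclass
class AnalysisReport:
    status: str                       # "ok" | "zone_not_found" | "invalid_test"
    analyte: str
    valid: bool
    detection: DetectionResult | None = None
    readout_class: str | None = None
    segments: list[PeakSegment] = field(default_factory=list)
    intensities: dict[str, float] = field(default_factory=dict)
    concentration: ConcentrationEstimate | None = None
    interpretation: dict | None = None
    message: str = ""
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "status": self.status,
            "analyte": self.analyte,
            "valid": self.valid,
            "detection": None if self.detection is None else {
                "bbox": [float(v) for v in self.detection.bbox],
                "confidence": self.detection.confidence,
                "accepted": self.detection.accepted,
            },
            "readout_class": self.readout_class,
            "segments": [
                {"start": s.start, "end": s.end, "apex": s.apex, "role": s.role}
                for s in self.segments
            ],
            "intensities": self.intensities,
            "concentration": None if self.concentration is None else {
                "value": self.concentration.value,
                "units": self.concentration.units,
                "text": self.concentration.text,
                "in_range": self.concentration.in_range,
                "below_lod": self.concentration.below_lod,
                "branch": self.concentration.branch,
            },
            "interpretation": self.interpretation,
            "message": self.message,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _layout_for(analyte: str) -> StripLayout:
    return THREE_LINE_LAYOUT if RESPONSES[analyte].has_antigen_line else TWO_LINE_LAYOUT


def _model_for(models: Mapping[str, FclModel], readout_class: ReadoutClass) -> FclModel:
    variant = (
        "three_peak"
        if readout_class is ReadoutClass.TEST_ANTIGEN_AND_CONTROL
        else "two_peak"
    )
    try:
        return models[variant]
    except KeyError:
        raise ConfigError(f"no segmentation model for variant {variant!r}") from None


def analyze_image(
    image: np.ndarray,
    curves: Mapping[str, AnalyteCurves],
    models: Mapping[str, FclModel],
    analyte: str,
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Run the full readout pipeline on one strip image.

    Stages in order: readout-zone detection (reject below the confidence
    threshold), rectified crop, profile extraction, readout classification,
    FCL peak segmentation with the variant matching the class, role
    assignment against the analyte's layout, line intensities, and
    calibration inversion (piecewise for CRP).
    """
    if analyte not in RESPONSES:
        raise ConfigError(f"unknown analyte {analyte!r}")
    if analyte not in curves:
        raise ConfigError(f"no calibration curves for analyte {analyte!r}")
    provenance = {
        "package_version": _pkg_version,
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": config.hash(),
        "models": {
            k: {"variant": m.variant, "seed": m.seed} for k, m in models.items()
        },
    }

    det = detect_readout_zone(np.asarray(image))
    if not det.accepted or det.confidence < config.confidence_threshold:
        return AnalysisReport(
            status="zone_not_found", analyte=analyte, valid=False,
            detection=det, message="readout zone not found above confidence threshold",
            provenance=provenance,
        )

    zone = crop_readout_zone(image, det)
    profile = extract_intensity_profile(zone, channel=config.channel)

    try:
        readout_class = classify_readout(profile)
        model = _model_for(models, readout_class)
        _, mask = predict_mask(model, profile)
        # the segmenter proposes peak regions; a region only counts as a
        # line if its measured contrast clears the noise floor (guards
        # against the position prior proposing lines that are not there,
        # e.g. the test-line slot on a control-only strip)
        floor = significance_floor(profile)
        segments = [
            s for s in segments_from_mask(mask, profile)
            if line_intensity(profile, s) >= floor
        ]
        layout = _layout_for(analyte)
        segments = assign_roles(segments, readout_class, layout)
    except InvalidTestError as exc:
        return AnalysisReport(
            status="invalid_test", analyte=analyte, valid=False, detection=det,
            message=str(exc), provenance=provenance,
        )

    intensities = {
        s.role: line_intensity(profile, s) for s in segments
    }
    analyte_curves = curves[analyte]
    units = RESPONSES[analyte].units

    try:
        concentration = _concentration_from_intensities(
            analyte, intensities, analyte_curves, units
        )
    except InvalidTestError as exc:
        return AnalysisReport(
            status="invalid_test", analyte=analyte, valid=False, detection=det,
            readout_class=readout_class.value, segments=segments,
            intensities=intensities, message=str(exc), provenance=provenance,
        )

    panel = interpret_panel({analyte: concentration.value})
    return AnalysisReport(
        status="ok", analyte=analyte, valid=True, detection=det,
        readout_class=readout_class.value, segments=segments,
        intensities=intensities, concentration=concentration,
        interpretation=panel.to_dict(), provenance=provenance,
    )


def _concentration_from_intensities(
    analyte: str,
    intensities: Mapping[str, float],
    analyte_curves: AnalyteCurves,
    units: str,
) -> ConcentrationEstimate:
    test_int = intensities.get(LineRole.TEST.value)
    if analyte == "CRP":
        if analyte_curves.antigen is None:
            raise ConfigError("CRP requires an antigen-line (high branch) curve")
        antigen_int = intensities.get(LineRole.ANTIGEN.value, 0.0)
        return quantify_crp(
            test_int if test_int is not None else 0.0,
            antigen_int,
            analyte_curves.test,
            analyte_curves.antigen,
            units=units,
        )
    if test_int is None:
        # control-only readout: analyte below what the strip can show
        lo = analyte_curves.test.valid_range[0]
        return ConcentrationEstimate(value=lo, units=units, below_lod=True)
    return invert_calibration(analyte_curves.test, test_int, units=units)


def batch_analyze(
    manifest: Sequence[Mapping],
    curves: Mapping[str, AnalyteCurves],
    models: Mapping[str, FclModel],
    config: PipelineConfig = PipelineConfig(),
):
    """Analyse a batch of strips and summarise replicate precision.

    ``manifest`` rows need an ``image`` (array, SyntheticSample, or PNG
    path), an ``analyte``, and optionally a ``group`` replicate label.
    Returns (reports, summary DataFrame) where the summary carries, per
    (analyte, group), the replicate count, mean test-line intensity and its
    CV in percent over valid reports; unreadable or invalid entries are
    logged, excluded from the CV, and counted.
    """
    import pandas as pd

    from .quant import cv as cv_percent

    reports: list[AnalysisReport | None] = []
    rows = []
    for i, entry in enumerate(manifest):
        image = entry["image"]
        try:
            if isinstance(image, SyntheticSample):
                image = image.image
            elif isinstance(image, (str,)) or hasattr(image, "__fspath__"):
                import imageio.v3 as iio

                image = iio.imread(image)
            report = analyze_image(
                np.asarray(image), curves, models, entry["analyte"], config
            )
        except (OSError, ValueError, ConfigError) as exc:
            logger.warning("skipping manifest entry %d: %s", i, exc)
            reports.append(None)
            rows.append(
                {"index": i, "analyte": entry.get("analyte"),
                 "group": entry.get("group"), "status": "unreadable",
                 "test_intensity": np.nan}
            )
            continue
        reports.append(report)
        rows.append(
            {"index": i, "analyte": entry["analyte"], "group": entry.get("group"),
             "status": report.status,
             "test_intensity": report.intensities.get("test", np.nan)}
        )

    detail = pd.DataFrame(rows)
    summaries = []
    if not detail.empty:
        for (analyte, group), sub in detail.groupby(["analyte", "group"], dropna=False):
            valid = sub[(sub["status"] == "ok") & sub["test_intensity"].notna()]
            vals = valid["test_intensity"].to_numpy(dtype=float)
            summaries.append(
                {
                    "analyte": analyte,
                    "group": group,
                    "n_total": int(len(sub)),
                    "n_valid": int(len(vals)),
                    "mean_intensity": float(vals.mean()) if len(vals) else np.nan,
                    "cv_percent": cv_percent(vals) if len(vals) >= 2 and vals.mean() != 0 else np.nan,
                }
            )
    summary = pd.DataFrame(
        summaries,
        columns=["analyte", "group", "n_total", "n_valid", "mean_intensity", "cv_percent"],
    )
    return reports, summary


# --------------------------------------------------------------------------
# calibration building against rendered strips

_CAL_LEVELS: dict[str, list[float]] = {
    "CEA": [2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0],
    "CA-125": [50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0],
    "CRP_low": [1.0, 2.0, 4.0, 6.0, 8.0, 10.0],
    "CRP_high": [10.0, 20.0, 50.0, 100.0, 200.0, 500.0],
}


def measure_layout_intensities(sample: SyntheticSample, channel: str = "green") -> dict[str, float]:
    """Line intensities of a rendered strip read at the known layout windows.

    Uses the ground-truth zone crop and fixed windows around each layout
    line centre; this is the measurement used to build calibration tables,
    independent of the trained segmenter.
    """
    x0, y0, x1, y1 = (int(round(v)) for v in sample.truth_bbox)
    profile = extract_intensity_profile(sample.image[y0:y1, x0:x1], channel=channel)
    out = {}
    for ln in sample.layout.lines:
        centre = ln.center * PROFILE_LEN
        half = 20
        seg = PeakSegment(
            start=max(0, int(centre - half)),
            end=min(PROFILE_LEN, int(centre + half)),
            apex=int(centre),
            role=ln.role.value,
        )
        out[ln.role.value] = line_intensity(profile, seg)
    return out


def build_calibration_curves(
    seed: int = 0,
    replicates: int = 3,
    noise: NoiseSpec = DEFAULT_NOISE,
) -> dict[str, AnalyteCurves]:
    """Build the default panel's calibration curves from rendered strips.

    Mirrors a spiked-replicate calibration campaign: strips rendered in
    replicate at each level, line intensities measured at the layout
    windows, replicate means fitted by OLS.  CEA and CA-125 are linear in
    concentration; CRP uses a linear test-line curve on 0-10 ug/mL and a
    log10-linear antigen-line curve on 10-500 ug/mL.
    """
    from .quant import CurveForm, fit_calibration

    rng = np.random.default_rng(seed)

    def measure(analyte: str, levels: Sequence[float], role: str):
        points = []
        for c in levels:
            reps = []
            for _ in range(replicates):
                s = render_analyte_strip(
                    analyte, c, noise=noise, seed=int(rng.integers(0, 2**31 - 1))
                )
                reps.append(measure_layout_intensities(s)[role])
            points.append((c, reps))
        blanks = []
        for _ in range(max(replicates, 3)):
            s = render_analyte_strip(
                analyte, 0.0, noise=noise, seed=int(rng.integers(0, 2**31 - 1))
            )
            blanks.append(measure_layout_intensities(s)[role])
        return points, blanks

    curves: dict[str, AnalyteCurves] = {}
    for analyte in ("CEA", "CA-125"):
        points, blanks = measure(analyte, _CAL_LEVELS[analyte], "test")
        curves[analyte] = AnalyteCurves(
            test=fit_calibration(
                points, CurveForm.LINEAR_C, blanks, analyte=analyte, line_role="test"
            )
        )

    # both CRP branches are fitted against log10 c: the assay's window spans
    # several decades and the saturating sandwich response over 1-10 ug/mL is
    # much closer to linear on a log abscissa
    low_points, low_blanks = measure("CRP", _CAL_LEVELS["CRP_low"], "test")
    high_points, high_blanks = measure("CRP", _CAL_LEVELS["CRP_high"], "antigen")
    curves["CRP"] = AnalyteCurves(
        test=fit_calibration(
            low_points, CurveForm.LINEAR_LOG10C, low_blanks, analyte="CRP", line_role="test"
        ),
        antigen=fit_calibration(
            high_points, CurveForm.LINEAR_LOG10C, high_blanks,
            analyte="CRP", line_role="antigen",
        ),
    )
    return curves


def save_curves(curves: Mapping[str, AnalyteCurves], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in curves.items()}, fh, indent=2, sort_keys=True)


def load_curves(path) -> dict[str, AnalyteCurves]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: AnalyteCurves.from_dict(v) for k, v in raw.items()}
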