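"""Readout-zone detection, intensity-profile extraction, classification.

The readout stage mirrors how a strip photo is turned into numbers: find
the pale membrane region in the scene, rectify small rotations, collapse
the readout zone to a 1-D intensity profile in one colour channel
(inverted so darker lines become peaks), and read each line's intensity as
the peak value minus the background value.

Zone detection is deterministic: brightness thresholding isolates the
membrane, the principal axis of the detected region estimates rotation,
and the confidence score measures red-line contrast inside the region,
mapped to [0, 1] with acceptance at the 0.8 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.stats import trim_mean
from skimage.filters import threshold_otsu
from skimage.transform import rotate

from .errors import ContractError, GeometryError, InvalidTestError
from .synthetic import PROFILE_LEN, ReadoutClass, StripLayout

__all__ = [
    "ReadoutClass",
    "DetectionResult",
    "IntensityProfile",
    "detect_readout_zone",
    "crop_readout_zone",
    "extract_intensity_profile",
    "line_intensity",
    "classify_readout",
]

CONFIDENCE_THRESHOLD = 0.8
#: red-line contrast (98th-percentile redness minus median, intensity
#: units) at which detection confidence saturates at 1.0
_CONTRAST_REF = 30.0
_MIN_REGION_PX = 64 * 64 // 16  # smallest plausible membrane region


@dataclass(frozen=True)
class DetectionResult:
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1 image px
    confidence: float
    accepted: bool
    angle_deg: float = 0.0  # estimated in-plane rotation of the strip

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ContractError("confidence must be in [0, 1]")
        if self.accepted != (self.confidence >= CONFIDENCE_THRESHOLD):
            raise ContractError("accepted must equal confidence >= 0.8")


@dataclass(frozen=True)
class IntensityProfile:
    """512-sample line scan of a readout zone, darker lines as peaks."""

    values: np.ndarray            # non-negative, length 512
    channel: str = "green"
    background_level: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (PROFILE_LEN,):
            raise ContractError(f"profile length must be {PROFILE_LEN}")
        if not np.all(np.isfinite(v)):
            raise ContractError("profile values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def axis(self) -> np.ndarray:
        """Normalised position in [0, 1] along the flow direction."""
        return np.linspace(0.0, 1.0, PROFILE_LEN)

    @staticmethod
    def from_values(values: np.ndarray, channel: str = "green") -> "IntensityProfile":
        values = np.asarray(values, dtype=float)
        return IntensityProfile(
            values=values,
            channel=channel,
            background_level=float(np.quantile(values, 0.2)),
        )


def _redness(img: np.ndarray) -> np.ndarray:
    f = img.astype(float)
    return f[:, :, 0] - 0.5 * (f[:, :, 1] + f[:, :, 2])


def detect_readout_zone(image: np.ndarray) -> DetectionResult:
    """Locate the strip readout zone in a scene; never raises on content.

    The membrane is found as the largest bright connected region (Otsu on
    smoothed brightness; the whole frame if brightness is near-uniform,
    i.e. a strip-only image).  Confidence combines red-line contrast inside
    the region with a plausibility check on region size, clipped to [0, 1];
    a box is accepted iff confidence >= 0.8.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or min(img.shape[:2]) < 64:
        return DetectionResult((0.0, 0.0, 0.0, 0.0), 0.0, False)

    brightness = ndimage.gaussian_filter(img.astype(float).mean(axis=2), 2.0)
    spread = brightness.max() - brightness.min()
    if spread < 20.0:
        # near-uniform frame: either a strip filling the image or a blank
        mask = np.ones(brightness.shape, dtype=bool)
    else:
        thr = threshold_otsu(brightness)
        mask = brightness > thr
        labels, nlab = ndimage.label(mask)
        if nlab == 0:
            return DetectionResult((0.0, 0.0, 0.0, 0.0), 0.0, False)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)

    if mask.sum() < _MIN_REGION_PX:
        return DetectionResult((0.0, 0.0, 0.0, 0.0), 0.0, False)

    ys, xs = np.nonzero(mask)
    x0, x1 = float(xs.min()), float(xs.max() + 1)
    y0, y1 = float(ys.min()), float(ys.max() + 1)

    # principal-axis rotation estimate from the region's second moments
    xc, yc = xs.mean(), ys.mean()
    cov = np.cov(np.stack([xs - xc, ys - yc]))
    angle = 0.5 * math.degrees(math.atan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1]))

    # line contrast is measured over the bounding box of the region, not the
    # bright mask itself: the lines are the dark pixels the mask excludes
    red = _redness(img)
    inside = red[int(y0):int(y1), int(x0):int(x1)]
    contrast = float(np.percentile(inside, 98) - np.median(inside))
    confidence = max(0.0, min(1.0, contrast / _CONTRAST_REF))
    return DetectionResult(
        bbox=(x0, y0, x1, y1),
        confidence=confidence,
        accepted=confidence >= CONFIDENCE_THRESHOLD,
        angle_deg=angle,
    )


def crop_readout_zone(
    image: np.ndarray, detection: DetectionResult | None = None
) -> np.ndarray:
    """Rectified crop of the detected readout zone.

    Undoes the estimated in-plane rotation about the box centre, then
    re-detects in the rectified frame and crops.  Landscape orientation is
    enforced (flow axis horizontal).
    """
    det = detection or detect_readout_zone(image)
    img = np.asarray(image)
    if abs(det.angle_deg) > 0.5:
        x0, y0, x1, y1 = det.bbox
        centre = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
        img = rotate(
            img.astype(float), det.angle_deg, center=centre, order=1,
            mode="edge", preserve_range=True,
        ).astype(np.uint8)
        det = detect_readout_zone(img)
    x0, y0, x1, y1 = (int(round(v)) for v in det.bbox)
    crop = img[y0:y1, x0:x1]
    if crop.shape[0] > crop.shape[1]:  # portrait: rotate to landscape
        crop = np.rot90(crop)
    return crop


def extract_intensity_profile(
    zone_image: np.ndarray, channel: str = "green"
) -> IntensityProfile:
    """Collapse a rectified zone crop to a 512-sample intensity profile.

    Per-column trimmed mean (10% trim each side, robust to specular
    highlights) of the chosen channel, inverted so darker lines become
    peaks, linearly resampled to 512 samples.  The background level is the
    20th percentile of the profile.
    """
    img = np.asarray(zone_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise GeometryError("zone image must be H x W x 3")
    if img.shape[1] < 8:
        raise GeometryError("readout zone narrower than 8 px")
    chan_idx = {"red": 0, "green": 1, "blue": 2}
    try:
        ch = chan_idx[channel]
    except KeyError:
        raise GeometryError(f"unknown channel {channel!r}") from None

    cols = trim_mean(img[:, :, ch].astype(float), 0.1, axis=0)
    inverted = float(cols.max()) - cols
    x_src = np.linspace(0.0, 1.0, inverted.size)
    x_dst = np.linspace(0.0, 1.0, PROFILE_LEN)
    values = np.interp(x_dst, x_src, inverted)

    # orientation normalisation: the control line sits downstream and is
    # darker than any upstream test line, so the downstream half carries
    # more integrated contrast; flip when the upstream half dominates
    half = PROFILE_LEN // 2
    peaks_only = np.clip(values - np.quantile(values, 0.75), 0.0, None)
    if peaks_only[:half].sum() > peaks_only[half:].sum():
        values = values[::-1].copy()

    return IntensityProfile(
        values=values,
        channel=channel,
        background_level=float(np.quantile(values, 0.2)),
    )


def line_intensity(profile: IntensityProfile, segment) -> float:
    """Line intensity: peak value within the segment minus the background.

    Non-negative by the sign convention (contrast of the line against
    background); accepts any object with integer ``start``/``end``.
    """
    start, end = int(segment.start), int(segment.end)
    if not (0 <= start < end <= PROFILE_LEN):
        raise ValueError(f"segment [{start}, {end}) out of profile bounds")
    return abs(float(profile.values[start:end].max()) - profile.background_level)


def estimate_profile_noise(values: np.ndarray) -> float:
    """Robust noise SD from first differences (peaks are locally smooth)."""
    d = np.diff(np.asarray(values, dtype=float))
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def significance_floor(profile: IntensityProfile) -> float:
    """Minimum contrast (intensity units) for a line to count as present."""
    return max(6.0 * estimate_profile_noise(profile.values), 5.0)


def candidate_peaks(profile: IntensityProfile) -> np.ndarray:
    """Indices of peaks exceeding a noise-scaled prominence threshold."""
    prominence = significance_floor(profile)
    peaks, props = find_peaks(
        profile.values, prominence=prominence, distance=int(0.04 * PROFILE_LEN)
    )
    if peaks.size > 3:  # keep the three most prominent candidates
        keep = np.argsort(props["prominences"])[-3:]
        peaks = np.sort(peaks[keep])
    return peaks


def classify_readout(profile: IntensityProfile) -> ReadoutClass:
    """Classify a profile by its number of significant peaks.

    One peak (at the downstream control position) is a control-only
    readout, two peaks test+control, three peaks test+antigen+control.
    A profile without any significant peak has no control line and is an
    invalid test.
    """
    peaks = candidate_peaks(profile)
    if peaks.size == 0:
        raise InvalidTestError("no significant peaks: control line absent")
    if peaks.size == 1:
        return ReadoutClass.CONTROL_ONLY
    if peaks.size == 2:
        return ReadoutClass.TEST_AND_CONTROL
    return ReadoutClass.TEST_ANTIGEN_AND_CONTROL
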