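"""Seeded synthetic gold-nanoparticle LFA strips with complete ground truth.

Emulates colorimetric lateral-flow strips read by a camera: reddish
antibody/antigen lines on a pale nitrocellulose membrane, line darkness set
by the assay dose-response (sandwich, competitive, and hook-affected
sandwich formats), replicate noise at the few-percent level, and pad scenes
with rotation and lighting variation for detector testing.

Every stochastic operation takes an explicit integer seed; nothing touches
global random state.  All rendered samples carry their ground truth (zone
box, readout class, per-position line mask, nominal signals and
concentrations) so downstream stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ConfigError, LayoutError

PROFILE_LEN = 512  # fixed resample length; matches the segmenter input size

# Visibility floor for a rendered line, in green-channel intensity units.
# Lines with nominal amplitude below this are treated as absent when the
# ground-truth readout class and mask are derived.
VISIBILITY_THRESHOLD = 6.0


class LineRole(str, Enum):
    TEST = "test"
    ANTIGEN = "antigen"
    CONTROL = "control"


class ReadoutClass(str, Enum):
    """The three readout categories a strip image can present."""

    CONTROL_ONLY = "control_only"
    TEST_AND_CONTROL = "test_and_control"
    TEST_ANTIGEN_AND_CONTROL = "test_antigen_and_control"


@dataclass(frozen=True)
class StripLine:
    role: LineRole
    center: float          # fraction of readout-zone length along flow
    width_px: float        # nominal full width of the flat line core


@dataclass(frozen=True)
class StripLayout:
    """Geometry of a strip: size, readout zone, and ordered line positions.

    The readout zone is an axis-aligned box in fractional strip coordinates
    (x0, y0, x1, y1) with x along the flow direction (left to right).
    """

    strip_length_px: int = 400
    strip_width_px: int = 120
    readout_zone: tuple[float, float, float, float] = (0.02, 0.05, 0.98, 0.95)
    lines: tuple[StripLine, ...] = ()

    format: str = "line_based"

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.readout_zone
        if not (0.0 <= x0 < x1 <= 1.0 and 0.0 <= y0 < y1 <= 1.0):
            raise LayoutError("readout_zone must lie inside strip bounds")
        centers = [ln.center for ln in self.lines]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise LayoutError("line centers must be strictly increasing")
        roles = [ln.role for ln in self.lines]
        if roles.count(LineRole.CONTROL) != 1:
            raise LayoutError("exactly one control line required")
        if LineRole.ANTIGEN in roles and len(self.lines) != 3:
            raise LayoutError("antigen line only valid in three-line layouts")
        if self.format not in ("line_based", "dot_based"):
            raise ConfigError(f"unknown strip format {self.format!r}")

    @property
    def zone_px(self) -> tuple[int, int, int, int]:
        """Readout zone in integer pixel coordinates (x0, y0, x1, y1)."""
        x0, y0, x1, y1 = self.readout_zone
        return (
            int(round(x0 * self.strip_length_px)),
            int(round(y0 * self.strip_width_px)),
            int(round(x1 * self.strip_length_px)),
            int(round(y1 * self.strip_width_px)),
        )

    def line_center_px(self, line: StripLine) -> float:
        zx0, _, zx1, _ = self.zone_px
        return zx0 + line.center * (zx1 - zx0)


#: Two-line geometry used for the sandwich assays (CEA, CA-125).
TWO_LINE_LAYOUT = StripLayout(
    lines=(
        StripLine(LineRole.TEST, 0.30, 10.0),
        StripLine(LineRole.CONTROL, 0.75, 10.0),
    )
)

#: Three-line geometry used for CRP: sandwich test line, pre-immobilised
#: antigen line (competitive), control line.
THREE_LINE_LAYOUT = StripLayout(
    lines=(
        StripLine(LineRole.TEST, 0.20, 10.0),
        StripLine(LineRole.ANTIGEN, 0.50, 10.0),
        StripLine(LineRole.CONTROL, 0.80, 10.0),
    )
)


@dataclass(frozen=True)
class AnalyteResponse:
    """Concentration -> nominal line-signal model for one analyte.

    Sandwich test line with optional high-dose hook:
        S(c) = s_max * c / (k_d + c) * 1 / (1 + c / hook_c)
    Competitive antigen line (intensity decreasing with analyte):
        A(c) = a_max / (1 + c / k_c)
    The control line binds conjugate regardless of analyte and carries a
    fixed signal.  Signals are in arbitrary green-channel intensity units.
    """

    analyte: str
    units: str
    s_max: float
    k_d: float
    hook_c: float = math.inf
    a_max: float = 0.0
    k_c: float = math.inf
    control_signal: float = 120.0
    valid_range: tuple[float, float] = (0.0, math.inf)

    @property
    def has_antigen_line(self) -> bool:
        return self.a_max > 0

    def test_signal(self, c: float) -> float:
        if c < 0:
            raise ValueError("concentration must be non-negative")
        return self.s_max * c / (self.k_d + c) / (1.0 + c / self.hook_c)

    def antigen_signal(self, c: float) -> float:
        if c < 0:
            raise ValueError("concentration must be non-negative")
        return self.a_max / (1.0 + c / self.k_c)


#: Default panel.  Constants chosen to emulate the qualitative published
#: behaviour: near-linear sandwich response over each clinical window, a
#: CRP hook setting in above 10 ug/mL, and a competitive line that is close
#: to log-linear over 10-500 ug/mL.
CEA_RESPONSE = AnalyteResponse(
    analyte="CEA", units="ng/mL", s_max=180.0, k_d=150.0, valid_range=(0.0, 50.0)
)
CA125_RESPONSE = AnalyteResponse(
    analyte="CA-125", units="U/mL", s_max=200.0, k_d=3000.0, valid_range=(0.0, 1000.0)
)
CRP_RESPONSE = AnalyteResponse(
    analyte="CRP",
    units="ug/mL",
    s_max=200.0,
    k_d=15.0,
    hook_c=10.0,
    a_max=150.0,
    k_c=70.0,
    valid_range=(0.1, 500.0),
)

RESPONSES: dict[str, AnalyteResponse] = {
    "CEA": CEA_RESPONSE,
    "CA-125": CA125_RESPONSE,
    "CRP": CRP_RESPONSE,
}


def signal_from_concentration(
    response: AnalyteResponse, c: float
) -> tuple[float, float | None, float]:
    """Nominal (test, antigen, control) line signals at concentration ``c``.

    ``antigen`` is None for analytes without a competitive line.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    test = response.test_signal(c)
    antigen = response.antigen_signal(c) if response.has_antigen_line else None
    return test, antigen, response.control_signal


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate-to-replicate imaging noise.

    amp_rel: multiplicative Gaussian noise on each line amplitude (relative
        sigma); the dominant contributor to replicate CV.
    pixel_sd: additive per-pixel Gaussian noise (8-bit intensity units).
    illum_rel: peak-to-centre relative amplitude of a smooth linear
        illumination gradient across the strip.
    center_jitter: per-line positional jitter (fraction of zone length).
    width_jitter: relative jitter of the line core width.
    """

    amp_rel: float = 0.05
    pixel_sd: float = 2.0
    illum_rel: float = 0.03
    center_jitter: float = 0.008
    width_jitter: float = 0.05


DEFAULT_NOISE = NoiseSpec()
NO_NOISE = NoiseSpec(amp_rel=0.0, pixel_sd=0.0, illum_rel=0.0,
                     center_jitter=0.0, width_jitter=0.0)

#: Membrane base colour (pale warm white) and per-channel line absorption
#: weights.  AuNP lines are red-dominant, so absorption is strongest in the
#: green/blue channels; the green channel carries the unit-amplitude dip.
MEMBRANE_RGB = np.array([238.0, 233.0, 226.0])
LINE_CHANNEL_WEIGHTS = np.array([0.25, 1.0, 0.8])  # R, G, B


@dataclass
class SyntheticSample:
    """A rendered strip (or pad scene) together with its ground truth."""

    image: np.ndarray                       # uint8, H x W x 3
    truth_bbox: tuple[float, float, float, float]  # x0, y0, x1, y1 image px
    truth_class: ReadoutClass
    truth_mask: np.ndarray                  # uint8, length 512
    truth_concentrations: dict[str, float]
    truth_signals: dict[str, float]         # nominal per-role signals
    layout: StripLayout
    seed: int

    def to_sidecar(self) -> dict:
        """JSON-serialisable ground-truth sidecar (mask as run lengths)."""
        mask = np.asarray(self.truth_mask, dtype=np.uint8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
        runs = [[int(a), int(b)] for a, b in zip(edges[::2], edges[1::2])]
        return {
            "bbox": [float(v) for v in self.truth_bbox],
            "class": self.truth_class.value,
            "mask_runs": runs,
            "concentrations": self.truth_concentrations,
            "signals": self.truth_signals,
            "seed": int(self.seed),
        }


def _line_profile(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-amplitude line cross-section: flat core + Gaussian shoulders."""
    sigma = width / 3.0
    d = np.abs(x - center) - width / 2.0
    return np.where(d <= 0, 1.0, np.exp(-0.5 * (np.maximum(d, 0) / sigma) ** 2))


def _line_extent_px(center: float, width: float) -> tuple[float, float]:
    """Half-amplitude extent of the rendered cross-section, in pixels."""
    half = width / 2.0 + (width / 3.0) * math.sqrt(2.0 * math.log(2.0))
    return center - half, center + half


def render_strip(
    layout: StripLayout,
    signals: Mapping[LineRole | str, float],
    noise: NoiseSpec = DEFAULT_NOISE,
    seed: int = 0,
    concentrations: Mapping[str, float] | None = None,
) -> SyntheticSample:
    """Render a strip image from per-line nominal signals.

    ``signals`` maps every role present in ``layout`` to its nominal
    amplitude (green-channel dip, 8-bit units).  Deterministic given the
    seed.  Ground truth (zone box, class, 512-sample line mask) is derived
    from the nominal, noise-free amplitudes.
    """
    roles = {ln.role for ln in layout.lines}
    sig: dict[LineRole, float] = {}
    for key, value in signals.items():
        role = LineRole(key)
        if role not in roles:
            raise ConfigError(f"signal given for role {role.value!r} absent from layout")
        sig[role] = float(value)
    missing = roles - set(sig)
    if missing:
        raise ConfigError(f"missing signals for roles: {sorted(r.value for r in missing)}")

    rng = np.random.default_rng(seed)
    H, W = layout.strip_width_px, layout.strip_length_px
    xs = np.arange(W, dtype=float)
    ys = np.arange(H, dtype=float)

    img = np.ones((H, W, 3)) * MEMBRANE_RGB
    # smooth linear illumination gradient, multiplicative
    gx = rng.uniform(-noise.illum_rel, noise.illum_rel)
    gy = rng.uniform(-noise.illum_rel, noise.illum_rel)
    field_ = 1.0 + gx * (xs[None, :] / W - 0.5) + gy * (ys[:, None] / H - 0.5)
    img *= field_[:, :, None]

    zx0, zy0, zx1, zy1 = layout.zone_px
    zone_len = zx1 - zx0
    for line in layout.lines:
        amp_nominal = sig[line.role]
        if amp_nominal <= 0:
            continue
        amp = amp_nominal * (1.0 + noise.amp_rel * rng.standard_normal())
        center = layout.line_center_px(line) + rng.uniform(
            -noise.center_jitter, noise.center_jitter
        ) * zone_len
        width = line.width_px * (1.0 + noise.width_jitter * rng.uniform(-1, 1))
        prof = _line_profile(xs, center, width)
        dip = amp * prof[None, :, None] * LINE_CHANNEL_WEIGHTS[None, None, :]
        # lines only exist inside the readout zone rows
        rows = slice(zy0, zy1)
        img[rows, :, :] -= dip

    img += rng.normal(0.0, noise.pixel_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth_mask = np.zeros(PROFILE_LEN, dtype=np.uint8)
    visible: set[LineRole] = set()
    for line in layout.lines:
        amp_nominal = sig[line.role]
        if amp_nominal < VISIBILITY_THRESHOLD:
            continue
        visible.add(line.role)
        center = layout.line_center_px(line)
        lo, hi = _line_extent_px(center, line.width_px)
        # map strip-x to profile index over the readout zone
        i_lo = (lo - zx0) / zone_len * PROFILE_LEN
        i_hi = (hi - zx0) / zone_len * PROFILE_LEN
        truth_mask[max(0, int(math.ceil(i_lo))): min(PROFILE_LEN, int(math.floor(i_hi)) + 1)] = 1

    truth_class = _class_from_visible(visible)
    return SyntheticSample(
        image=img,
        truth_bbox=(float(zx0), float(zy0), float(zx1), float(zy1)),
        truth_class=truth_class,
        truth_mask=truth_mask,
        truth_concentrations=dict(concentrations or {}),
        truth_signals={r.value: sig[r] for r in sig},
        layout=layout,
        seed=seed,
    )


def _class_from_visible(visible: set[LineRole]) -> ReadoutClass:
    # The readout class is an image-level property: how many lines a reader
    # sees.  A CRP blank (bright antigen + control, test invisible) therefore
    # presents as a two-line readout.
    if len(visible) >= 3:
        return ReadoutClass.TEST_ANTIGEN_AND_CONTROL
    if len(visible) == 2:
        return ReadoutClass.TEST_AND_CONTROL
    return ReadoutClass.CONTROL_ONLY


def render_analyte_strip(
    analyte: str,
    concentration: float,
    noise: NoiseSpec = DEFAULT_NOISE,
    seed: int = 0,
) -> SyntheticSample:
    """Convenience: render a strip for one panel analyte at a concentration."""
    try:
        response = RESPONSES[analyte]
    except KeyError:
        raise ConfigError(f"unknown analyte {analyte!r}") from None
    test, antigen, control = signal_from_concentration(response, concentration)
    layout = THREE_LINE_LAYOUT if response.has_antigen_line else TWO_LINE_LAYOUT
    signals: dict[LineRole, float] = {LineRole.TEST: test, LineRole.CONTROL: control}
    if antigen is not None:
        signals[LineRole.ANTIGEN] = antigen
    return render_strip(
        layout, signals, noise=noise, seed=seed,
        concentrations={analyte: concentration},
    )


@dataclass(frozen=True)
class PadScene:
    """Composition spec: strip on a textured pad under varied imaging.

    rotation_deg is limited to +/-15 degrees and gain (global lighting
    multiplier) to [0.7, 1.3], the ranges the detector is expected to
    handle.  pad_shape is (height, width); offset is the top-left corner of
    the unrotated strip in pad coordinates (None centres the strip).
    """

    rotation_deg: float = 0.0
    gain: float = 1.0
    pad_shape: tuple[int, int] = (360, 560)
    offset: tuple[float, float] | None = None
    texture_sd: float = 6.0

    MAX_ROTATION = 15.0
    GAIN_RANGE = (0.7, 1.3)


PAD_RGB = np.array([206.0, 206.0, 212.0])


def render_pad_scene(
    sample: SyntheticSample, scene: PadScene = PadScene(), seed: int = 0
) -> SyntheticSample:
    """Composite a rendered strip onto a textured pad background.

    The strip is rotated about its centre and pasted at the scene offset;
    the ground-truth zone box is transformed by the same affine map and
    re-boxed axis-aligned.
    """
    if abs(scene.rotation_deg) > PadScene.MAX_ROTATION:
        raise LayoutError(
            f"rotation {scene.rotation_deg} deg outside +/-{PadScene.MAX_ROTATION}"
        )
    g0, g1 = PadScene.GAIN_RANGE
    if not (g0 <= scene.gain <= g1):
        raise LayoutError(f"gain {scene.gain} outside [{g0}, {g1}]")

    rng = np.random.default_rng(seed)
    ph, pw = scene.pad_shape
    sh, sw = sample.image.shape[:2]
    if scene.offset is None:
        ox, oy = (pw - sw) / 2.0, (ph - sh) / 2.0
    else:
        ox, oy = scene.offset

    theta = math.radians(scene.rotation_deg)
    centre_src = np.array([sw / 2.0, sh / 2.0])
    centre_dst = np.array([ox + sw / 2.0, oy + sh / 2.0])
    tform = (
        AffineTransform(translation=-centre_src)
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=centre_dst)
    )

    corners = np.array([[0, 0], [sw, 0], [sw, sh], [0, sh]], dtype=float)
    mapped = tform(corners)
    if (mapped[:, 0].min() < 0 or mapped[:, 1].min() < 0
            or mapped[:, 0].max() > pw or mapped[:, 1].max() > ph):
        raise LayoutError("strip falls outside the pad scene bounds")

    # textured pad: smooth fibrous noise around the pad base colour
    texture = rng.normal(0.0, scene.texture_sd, size=(ph, pw))
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(texture, sigma=3.0) * 3.0
    pad = np.ones((ph, pw, 3)) * PAD_RGB + texture[:, :, None]

    strip_f = sample.image.astype(float)
    inv = tform.inverse
    warped = np.stack(
        [
            warp(strip_f[:, :, ch], inv, output_shape=(ph, pw), order=1,
                 cval=0.0, preserve_range=True)
            for ch in range(3)
        ],
        axis=-1,
    )
    alpha = warp(np.ones((sh, sw)), inv, output_shape=(ph, pw), order=1, cval=0.0)
    mask = alpha > 0.5
    pad[mask] = warped[mask]

    pad *= scene.gain
    # auto-exposure convention: a camera never delivers a blown-out frame of
    # a white pad, so bright scenes are renormalised to keep highlights on
    # scale while preserving relative contrast
    peak = pad.max()
    if peak > 252.0:
        pad *= 252.0 / peak
    pad = np.clip(pad, 0, 255).astype(np.uint8)

    bx0, by0, bx1, by1 = sample.truth_bbox
    zone_corners = np.array(
        [[bx0, by0], [bx1, by0], [bx1, by1], [bx0, by1]], dtype=float
    )
    mz = tform(zone_corners)
    new_bbox = (
        float(mz[:, 0].min()), float(mz[:, 1].min()),
        float(mz[:, 0].max()), float(mz[:, 1].max()),
    )

    return dataclasses.replace(sample, image=pad, truth_bbox=new_bbox, seed=seed)


# --------------------------------------------------------------------------
# dataset generation

DEFAULT_CLASS_MIX: dict[ReadoutClass, float] = {
    ReadoutClass.CONTROL_ONLY: 1 / 3,
    ReadoutClass.TEST_AND_CONTROL: 1 / 3,
    ReadoutClass.TEST_ANTIGEN_AND_CONTROL: 1 / 3,
}


def default_concentration_sampler(
    cls: ReadoutClass, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw an (analyte, concentration) pair that realises a readout class.

    Concentrations are drawn from mid-assay ranges where every class-defining
    line is well above the visibility floor, emulating the spiked-sample
    levels used to build calibration and training sets.
    """
    if cls is ReadoutClass.CONTROL_ONLY:
        analyte = ("CEA", "CA-125")[rng.integers(2)]
        return analyte, 0.0
    if cls is ReadoutClass.TEST_AND_CONTROL:
        if rng.integers(2):
            return "CEA", float(rng.uniform(10.0, 50.0))
        return "CA-125", float(rng.uniform(200.0, 1000.0))
    # three-line CRP strip: both test and antigen lines visible
    return "CRP", float(10 ** rng.uniform(0.0, 2.0))  # 1-100 ug/mL


@dataclass
class LabeledDataset:
    samples: list[SyntheticSample]
    partitions: dict[str, list[int]]  # split name -> sample indices


def partition_sizes(n: int, splits: Sequence[float]) -> list[int]:
    """Deterministic split sizes: nearest-integer for all but the last
    partition, remainder to the last; always sums to n."""
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ConfigError("split proportions must sum to 1")
    sizes = [int(round(n * p)) for p in splits[:-1]]
    last = n - sum(sizes)
    if last < 0:
        raise ConfigError("split proportions round above n")
    return sizes + [last]


def generate_dataset(
    n: int,
    class_mix: Mapping[ReadoutClass, float] | None = None,
    conc_sampler: Callable[[ReadoutClass, np.random.Generator], tuple[str, float]]
    | None = None,
    splits: Sequence[float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    noise: NoiseSpec = DEFAULT_NOISE,
    split_names: Sequence[str] = ("train", "val", "test"),
) -> LabeledDataset:
    """Generate a labelled strip dataset partitioned into disjoint splits."""
    if n < 10:
        raise ConfigError("need n >= 10")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    for key in mix:
        if not isinstance(key, ReadoutClass):
            raise ConfigError(f"unknown readout class {key!r}")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigError("class mix proportions must sum to 1")
    if len(splits) != len(split_names):
        raise ConfigError("splits and split_names length mismatch")
    sampler = conc_sampler or default_concentration_sampler

    classes = list(mix.keys())
    counts = partition_sizes(n, [mix[c] for c in classes])
    rng = np.random.default_rng(seed)

    samples: list[SyntheticSample] = []
    for cls, count in zip(classes, counts):
        for _ in range(count):
            analyte, c = sampler(cls, rng)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            s = render_analyte_strip(analyte, c, noise=noise, seed=sub_seed)
            if s.truth_class is not cls:
                raise ConfigError(
                    f"sampler produced class {s.truth_class.value} for requested "
                    f"{cls.value} (analyte={analyte}, c={c:g})"
                )
            samples.append(s)

    order = rng.permutation(len(samples))
    sizes = partition_sizes(len(samples), list(splits))
    partitions: dict[str, list[int]] = {}
    start = 0
    for name, size in zip(split_names, sizes):
        partitions[name] = [int(i) for i in order[start:start + size]]
        start += size
    return LabeledDataset(samples=samples, partitions=partitions)


def generate_labeled_profiles(
    n: int,
    variant: str,
    seed: int = 0,
    noise: NoiseSpec = DEFAULT_NOISE,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Labelled (profile values, 0/1 mask) pairs for segmenter training.

    ``variant`` is ``"two_peak"`` (CEA / CA-125 strips) or ``"three_peak"``
    (CRP strips).  Profiles are extracted from rendered strips through the
    imaging stage using the ground-truth zone crop, so they match what the
    pipeline produces at inference time.
    """
    from .imaging import extract_intensity_profile

    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n):
        if variant == "two_peak":
            cls = ReadoutClass.TEST_AND_CONTROL
        elif variant == "three_peak":
            cls = ReadoutClass.TEST_ANTIGEN_AND_CONTROL
        else:
            raise ConfigError(f"unknown variant {variant!r}")
        analyte, c = default_concentration_sampler(cls, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        s = render_analyte_strip(analyte, c, noise=noise, seed=sub_seed)
        x0, y0, x1, y1 = (int(round(v)) for v in s.truth_bbox)
        zone = s.image[y0:y1, x0:x1]
        profile = extract_intensity_profile(zone)
        out.append((profile.values, s.truth_mask.astype(np.uint8)))
    return out


def write_dataset(dataset: LabeledDataset, out_dir) -> None:
    """Write images as PNG with JSON ground-truth sidecars and a manifest."""
    import csv
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_of_split = {}
    for name, idxs in dataset.partitions.items():
        for i in idxs:
            index_of_split[i] = name
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "sidecar", "split", "class", "seed"])
        for i, s in enumerate(dataset.samples):
            img_name = f"strip_{i:05d}.png"
            sc_name = f"strip_{i:05d}.json"
            iio.imwrite(out / img_name, s.image)
            with open(out / sc_name, "w") as sfh:
                json.dump(s.to_sidecar(), sfh)
            writer.writerow(
                [img_name, sc_name, index_of_split.get(i, ""),
                 s.truth_class.value, s.seed]
            )
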