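"""Per-pixel peak segmentation of intensity profiles with a small MLP.

A fully connected network — input layer of 512 nodes, hidden layer of 256
nodes (ReLU, dropout 0.5 during training), single sigmoid output — assigns
each of the 512 profile positions a probability of belonging to a coloured
line.  The network is evaluated once per position: the input vector
encodes (pixel position, pixel intensity) as a one-hot position vector
whose active node carries 1 + the min-max-normalised intensity, so each
position owns one input node, the position prior survives faint lines
(at zero intensity the input is the pure position one-hot), and the
hidden layer is shared.

Two variant-specific models are kept (two-peak profiles from two-line
strips, three-peak profiles from CRP strips); discriminating the profile
type before segmenting is part of the method — a single pooled model must
reconcile conflicting position priors between the two layouts and pays
for it in accuracy.  Training uses binary cross-entropy over 100 epochs
with mini-batch Adam (batch size 10 profiles) and an 80/20 train/test
split; everything is deterministic given the seed.

Probabilities >= 0.5 are binarised to a mask, maximal runs of the mask
become peak segments, and segments are assigned line roles by nearest
expected layout position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ContractError, DataError, InvalidTestError
from .imaging import IntensityProfile
from .synthetic import PROFILE_LEN, LineRole, ReadoutClass, StripLayout

MIN_SEGMENT_WIDTH = 4  # px at 512 resolution; suppresses noise runs

INPUT_ENCODING = "position_indexed_intensity"


@dataclass
class FclModel:
    """Trained fully connected segmenter (one of the two variants).

    ``w1`` row i holds the input weights of position i's input node, so the
    hidden pre-activation at position i is ``intensity_i * w1[i] + b1``.
    """

    variant: str                       # "two_peak", "three_peak" or "pooled"
    w1: np.ndarray                     # (512, 256)
    b1: np.ndarray                     # (256,)
    w2: np.ndarray                     # (256, 1)
    b2: np.ndarray                     # (1,)
    threshold: float = 0.5
    seed: int = 0
    metrics: dict = field(default_factory=dict)
    input_encoding: str = INPUT_ENCODING

    def save(self, path) -> None:
        """Single portable text file: JSON header + flattened weights."""
        header = {
            "variant": self.variant,
            "threshold": self.threshold,
            "seed": self.seed,
            "metrics": self.metrics,
            "input_encoding": self.input_encoding,
            "shapes": {k: list(getattr(self, k).shape) for k in ("w1", "b1", "w2", "b2")},
        }
        flat = np.concatenate([getattr(self, k).ravel() for k in ("w1", "b1", "w2", "b2")])
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            fh.write(",".join(f"{v:.9e}" for v in flat) + "\n")

    @classmethod
    def load(cls, path) -> "FclModel":
        with open(path) as fh:
            header = json.loads(fh.readline())
            flat = np.array(fh.readline().split(","), dtype=float)
        arrays = {}
        start = 0
        for k in ("w1", "b1", "w2", "b2"):
            shape = tuple(header["shapes"][k])
            size = int(np.prod(shape))
            arrays[k] = flat[start:start + size].reshape(shape)
            start += size
        return cls(
            variant=header["variant"], threshold=header["threshold"],
            seed=header["seed"], metrics=header["metrics"],
            input_encoding=header.get("input_encoding", INPUT_ENCODING),
            **arrays,
        )


@dataclass(frozen=True)
class PeakSegment:
    """Half-open run [start, end) of line pixels with its apex index."""

    start: int
    end: int
    apex: int
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= PROFILE_LEN):
            raise ContractError("segment bounds must satisfy 0 <= start < end <= 512")
        if not (self.start <= self.apex < self.end):
            raise ContractError("apex must lie within [start, end)")


# --------------------------------------------------------------------------
# model evaluation

def normalize_profile(values: np.ndarray) -> np.ndarray:
    """Min-max normalisation to [0, 1]; flat profiles map to zeros."""
    v = np.asarray(values, dtype=np.float32)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(model: FclModel, norm: np.ndarray) -> np.ndarray:
    """Per-position probabilities for one normalised profile (length 512).

    The active input node of position i carries 1 + intensity_i.
    """
    h = np.maximum((1.0 + norm)[:, None] * model.w1 + model.b1, 0.0)
    return _sigmoid(h @ model.w2 + model.b2)[:, 0]


def predict_proba(model: FclModel, profile: IntensityProfile | np.ndarray) -> np.ndarray:
    values = profile.values if isinstance(profile, IntensityProfile) else np.asarray(profile)
    if values.shape != (PROFILE_LEN,):
        raise ContractError(f"profile length must be {PROFILE_LEN}")
    return _forward(model, normalize_profile(values))


def predict_mask(
    model: FclModel, profile: IntensityProfile | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel line probabilities and the thresholded binary mask.

    mask[i] = 1 iff probability[i] >= threshold (ties count as peak).
    """
    proba = predict_proba(model, profile)
    return proba, (proba >= model.threshold).astype(np.uint8)


# --------------------------------------------------------------------------
# training

def train_fcl(
    variant: str,
    labeled_profiles: Sequence[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    epochs: int = 100,
    batch_size: int = 10,
    lr: float = 1e-3,
    dropout: float = 0.5,
    test_fraction: float = 0.2,
) -> FclModel:
    """Train a variant-specific segmenter on labelled profiles.

    ``labeled_profiles`` is a list of (values, mask) pairs with 512-sample
    0/1 masks.  An 80/20 train/test split is made first; held-out pixelwise
    accuracy, precision and recall are stored in ``model.metrics``.
    Deterministic given the seed.
    """
    if len(labeled_profiles) < 50:
        raise DataError("need at least 50 labelled profiles")
    for values, mask in labeled_profiles:
        if np.asarray(values).shape != (PROFILE_LEN,) or np.asarray(mask).shape != (PROFILE_LEN,):
            raise DataError("profiles and masks must have length 512")

    rng = np.random.default_rng(seed)
    n = len(labeled_profiles)
    order = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test_idx, train_idx = order[:n_test], order[n_test:]

    X_all = np.stack([normalize_profile(v) for v, _ in labeled_profiles])   # (n, 512)
    Y_all = np.stack([np.asarray(m, dtype=np.float32) for _, m in labeled_profiles])

    # He init for the ReLU layer, Glorot for the sigmoid head
    w1 = rng.normal(0.0, np.sqrt(2.0 / PROFILE_LEN), (PROFILE_LEN, 256)).astype(np.float32)
    b1 = np.zeros(256, dtype=np.float32)
    w2 = rng.normal(0.0, np.sqrt(2.0 / (256 + 1)), (256, 1)).astype(np.float32)
    b2 = np.zeros(1, dtype=np.float32)
    params = [w1, b1, w2, b2]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for _ in range(epochs):
        epoch_order = train_idx[rng.permutation(len(train_idx))]
        for start in range(0, len(epoch_order), batch_size):
            ids = epoch_order[start:start + batch_size]
            xb = 1.0 + X_all[ids]               # (b, 512); offset one-hot input
            yb = Y_all[ids]                     # (b, 512)
            b = len(ids)

            z1 = xb[:, :, None] * w1[None, :, :] + b1       # (b, 512, 256)
            h = np.maximum(z1, 0.0)
            keep = (rng.random(h.shape, dtype=np.float32) >= dropout).astype(
                np.float32
            ) / (1.0 - dropout)
            hd = h * keep
            p = _sigmoid(hd @ w2 + b2)[:, :, 0]             # (b, 512)

            # BCE gradient over b*512 per-pixel samples: dL/dz2 = p - y
            g2 = (p - yb) / (b * PROFILE_LEN)               # (b, 512)
            grad_w2 = np.einsum("bij,bi->j", hd, g2)[:, None]
            grad_b2 = np.array([g2.sum()], dtype=np.float32)
            gh = g2[:, :, None] * w2[None, None, :, 0] * keep * (z1 > 0)
            grad_w1 = np.einsum("bi,bij->ij", xb, gh)
            grad_b1 = gh.sum(axis=(0, 1))

            step += 1
            for i, (par, g) in enumerate(
                zip(params, (grad_w1, grad_b1, grad_w2, grad_b2))
            ):
                m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * g
                v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * g * g
                mhat = m_adam[i] / (1 - beta1**step)
                vhat = v_adam[i] / (1 - beta2**step)
                par -= lr * mhat / (np.sqrt(vhat) + eps)

    model = FclModel(variant=variant, w1=w1, b1=b1, w2=w2, b2=b2, seed=seed)

    preds = np.concatenate(
        [(_forward(model, X_all[i]) >= model.threshold).astype(np.uint8)
         for i in test_idx]
    )
    truth = Y_all[test_idx].reshape(-1).astype(np.uint8)
    acc, prec, rec = evaluate_segmentation(preds, truth)
    model.metrics = {
        "accuracy": acc, "precision": prec, "recall": rec,
        "n_train": int(len(train_idx)), "n_test": int(len(test_idx)),
        "epochs": epochs,
    }
    return model


# --------------------------------------------------------------------------
# post-processing

def segments_from_mask(
    mask: np.ndarray,
    profile: IntensityProfile | np.ndarray,
    min_width: int = MIN_SEGMENT_WIDTH,
) -> list[PeakSegment]:
    """Maximal runs of 1s in the mask, short runs dropped, apex at the
    profile extremum within each run; ordered by start index."""
    m = np.asarray(mask).astype(np.uint8)
    if m.shape != (PROFILE_LEN,):
        raise ContractError(f"mask length must be {PROFILE_LEN}")
    values = profile.values if isinstance(profile, IntensityProfile) else np.asarray(profile)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m, [0]))))
    segments = []
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a < min_width:
            continue
        apex = int(a + np.argmax(values[a:b]))
        segments.append(PeakSegment(start=int(a), end=int(b), apex=apex))
    return segments


_CLASS_COUNT = {
    ReadoutClass.CONTROL_ONLY: 1,
    ReadoutClass.TEST_AND_CONTROL: 2,
    ReadoutClass.TEST_ANTIGEN_AND_CONTROL: 3,
}


def assign_roles(
    segments: Sequence[PeakSegment],
    readout_class: ReadoutClass,
    layout: StripLayout,
) -> list[PeakSegment]:
    """Assign line roles to segments by nearest expected layout position.

    The readout class fixes the expected segment count; roles come from
    the layout geometry (in 512-sample profile coordinates over the
    readout zone), matched one-to-one by minimising total apex-to-line
    distance.  The control line must always be among the assignments.
    """
    expected = _CLASS_COUNT[readout_class]
    if len(segments) != expected:
        raise InvalidTestError(
            f"{len(segments)} segments inconsistent with class "
            f"{readout_class.value} (expected {expected})"
        )
    line_pos = np.array([ln.center * PROFILE_LEN for ln in layout.lines])
    apexes = np.array([s.apex for s in segments], dtype=float)
    cost = np.abs(apexes[:, None] - line_pos[None, :])
    rows, cols = linear_sum_assignment(cost)
    assigned = []
    roles_used = set()
    for r, c in zip(rows, cols):
        role = layout.lines[c].role
        roles_used.add(role)
        seg = segments[r]
        assigned.append(PeakSegment(seg.start, seg.end, seg.apex, role=role.value))
    if LineRole.CONTROL not in roles_used:
        raise InvalidTestError("control line could not be assigned")
    return sorted(assigned, key=lambda s: s.start)


def evaluate_segmentation(
    pred_mask: np.ndarray, truth_mask: np.ndarray
) -> tuple[float, float, float]:
    """Pixelwise (accuracy, precision, recall); 0 when a denominator is 0."""
    p = np.asarray(pred_mask).astype(bool).ravel()
    t = np.asarray(truth_mask).astype(bool).ravel()
    if p.shape != t.shape:
        raise ContractError("prediction and truth masks must have equal length")
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    acc = (tp + tn) / p.size if p.size else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return float(acc), float(prec), float(rec)
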