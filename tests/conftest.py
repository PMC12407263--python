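"""Shared fixtures: rendered strip corpora, trained segmenters, curves.

Everything is generated programmatically and seeded; session scope keeps
the expensive pieces (model training, calibration rendering) to one build
per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import lfaquant as lq


@pytest.fixture(scope="session")
def small_models() -> dict[str, lq.FclModel]:
    """Quickly trained variant models for pipeline-level tests."""
    models = {}
    for variant, seed in (("two_peak", 5), ("three_peak", 6)):
        data = lq.generate_labeled_profiles(150, variant, seed=seed)
        models[variant] = lq.train_fcl(variant, data, seed=seed, epochs=40)
    return models


@pytest.fixture(scope="session")
def curves() -> dict[str, lq.AnalyteCurves]:
    """Calibration curves built from rendered replicate strips."""
    return lq.build_calibration_curves(seed=101)


@pytest.fixture(scope="session")
def strip_corpus() -> lq.synthetic.LabeledDataset:
    """201 default-noise strips across the three readout classes."""
    return lq.generate_dataset(201, seed=42)


def truth_zone_profile(sample: lq.SyntheticSample) -> lq.IntensityProfile:
    """Profile extracted from the ground-truth readout-zone crop."""
    x0, y0, x1, y1 = (int(round(v)) for v in sample.truth_bbox)
    return lq.extract_intensity_profile(sample.image[y0:y1, x0:x1])


def box_iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
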