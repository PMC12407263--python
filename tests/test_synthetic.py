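"""Generator tests: dose-response shapes, rendering, scenes, datasets."""

import math

import numpy as np
import pytest

import lfaquant as lq
from lfaquant.synthetic import _line_extent_px

from conftest import truth_zone_profile


class TestSignalFromConcentration:
    def test_zero_analyte_limit(self):
        t, a, ctl = lq.signal_from_concentration(lq.CRP_RESPONSE, 0.0)
        assert t == 0.0
        assert a == lq.CRP_RESPONSE.a_max
        assert ctl == lq.CRP_RESPONSE.control_signal

    def test_crp_hook_is_non_monotone_around_onset(self):
        # rises into the hook onset at 10 ug/mL, falls well above it
        s = lq.CRP_RESPONSE.test_signal
        assert s(5.0) < s(10.0)
        assert s(200.0) < s(10.0)

    def test_competitive_line_vanishes_at_high_dose(self):
        a_far = lq.CRP_RESPONSE.antigen_signal(1e9)
        assert a_far < 1e-3 * lq.CRP_RESPONSE.a_max

    def test_competitive_line_strictly_decreasing(self):
        grid = np.linspace(0.0, 500.0, 30)
        sig = [lq.CRP_RESPONSE.antigen_signal(c) for c in grid]
        assert all(b < a for a, b in zip(sig, sig[1:]))

    def test_sandwich_line_without_hook_is_nondecreasing(self):
        grid = np.linspace(0.0, 1000.0, 30)
        sig = [lq.CA125_RESPONSE.test_signal(c) for c in grid]
        assert all(b >= a for a, b in zip(sig, sig[1:]))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            lq.signal_from_concentration(lq.CEA_RESPONSE, -1.0)

    def test_two_line_analyte_has_no_antigen_signal(self):
        _, antigen, _ = lq.signal_from_concentration(lq.CEA_RESPONSE, 10.0)
        assert antigen is None


class TestRenderStrip:
    def test_same_seed_is_bit_identical(self):
        a = lq.render_analyte_strip("CEA", 25.0, seed=3)
        b = lq.render_analyte_strip("CEA", 25.0, seed=3)
        np.testing.assert_array_equal(a.image, b.image)

    def test_unknown_role_signal_rejected(self):
        with pytest.raises(lq.ConfigError):
            lq.render_strip(lq.TWO_LINE_LAYOUT, {"antigen": 50.0, "control": 100.0})

    def test_missing_role_signal_rejected(self):
        with pytest.raises(lq.ConfigError):
            lq.render_strip(lq.TWO_LINE_LAYOUT, {"control": 100.0})

    def test_control_only_render_has_single_green_dip(self):
        s = lq.render_strip(
            lq.TWO_LINE_LAYOUT, {"test": 0.0, "control": 120.0},
            noise=lq.NO_NOISE, seed=0,
        )
        x0, y0, x1, y1 = (int(round(v)) for v in s.truth_bbox)
        col = s.image[y0:y1, x0:x1, 1].astype(float).mean(axis=0)
        dips = [
            i for i in range(1, len(col) - 1)
            if col[i] < col[i - 1] and col[i] <= col[i + 1] and col[i] < col.max() - 20
        ]
        # contiguous indices at the flat line core belong to one dip
        groups = 1 + sum(1 for a, b in zip(dips, dips[1:]) if b - a > 1)
        assert len(dips) > 0 and groups == 1

    def test_larger_signal_gives_larger_extracted_intensity(self):
        lo = lq.render_strip(lq.TWO_LINE_LAYOUT, {"test": 30.0, "control": 120.0}, seed=4)
        hi = lq.render_strip(lq.TWO_LINE_LAYOUT, {"test": 90.0, "control": 120.0}, seed=4)
        assert (
            lq.measure_layout_intensities(hi)["test"]
            > lq.measure_layout_intensities(lo)["test"]
        )

    def test_truth_mask_matches_half_amplitude_extents(self):
        """Mask pixels coincide with rendered line extents within +/-2 px."""
        s = lq.render_analyte_strip("CRP", 5.0, noise=lq.NO_NOISE, seed=0)
        zx0, _, zx1, _ = s.layout.zone_px
        zone_len = zx1 - zx0
        expected = np.zeros(lq.PROFILE_LEN, dtype=bool)
        for line in s.layout.lines:
            if s.truth_signals[line.role.value] < 6.0:
                continue
            lo, hi = _line_extent_px(s.layout.line_center_px(line), line.width_px)
            i = np.arange(lq.PROFILE_LEN)
            pos = zx0 + i / lq.PROFILE_LEN * zone_len
            expected |= (pos >= lo) & (pos <= hi)
        mismatch = np.flatnonzero(expected != s.truth_mask.astype(bool))
        if mismatch.size:
            # all mismatches must hug a boundary within 2 profile px
            edges = np.flatnonzero(np.diff(expected.astype(int)))
            assert max(min(abs(m - e) for e in edges) for m in mismatch) <= 2

    def test_replicate_cv_below_ten_percent(self):
        for analyte, c in (("CEA", 25.0), ("CA-125", 500.0), ("CRP", 5.0)):
            vals = [
                lq.measure_layout_intensities(
                    lq.render_analyte_strip(analyte, c, seed=700 + k)
                )["test"]
                for k in range(10)
            ]
            assert lq.cv(vals) < 10.0


class TestPadScene:
    def test_identity_scene_preserves_bbox(self):
        s = lq.render_analyte_strip("CEA", 25.0, seed=1)
        scene = lq.PadScene(
            rotation_deg=0.0, gain=1.0,
            pad_shape=s.image.shape[:2], offset=(0.0, 0.0), texture_sd=0.0,
        )
        p = lq.render_pad_scene(s, scene, seed=2)
        assert p.truth_bbox == pytest.approx(s.truth_bbox)

    def test_rotation_beyond_limit_rejected(self):
        s = lq.render_analyte_strip("CEA", 25.0, seed=1)
        with pytest.raises(lq.LayoutError):
            lq.render_pad_scene(s, lq.PadScene(rotation_deg=90.0), seed=0)

    def test_gain_outside_bounds_rejected(self):
        s = lq.render_analyte_strip("CEA", 25.0, seed=1)
        with pytest.raises(lq.LayoutError):
            lq.render_pad_scene(s, lq.PadScene(gain=2.0), seed=0)

    def test_strip_outside_scene_rejected(self):
        s = lq.render_analyte_strip("CEA", 25.0, seed=1)
        with pytest.raises(lq.LayoutError):
            lq.render_pad_scene(s, lq.PadScene(pad_shape=(100, 100)), seed=0)

    def test_bbox_transforms_by_the_scene_rotation(self):
        """Zone corners must map through the same rotation about the strip
        centre that places the strip in the pad (hand-composed affine)."""
        s = lq.render_analyte_strip("CEA", 25.0, seed=1)
        theta = math.radians(10.0)
        scene = lq.PadScene(rotation_deg=10.0)
        p = lq.render_pad_scene(s, scene, seed=2)
        sh, sw = s.image.shape[:2]
        ph, pw = scene.pad_shape
        ox, oy = (pw - sw) / 2.0, (ph - sh) / 2.0
        cx, cy = sw / 2.0, sh / 2.0
        x0, y0, x1, y1 = s.truth_bbox
        corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        mapped = (corners - [cx, cy]) @ rot.T + [ox + cx, oy + cy]
        expected = (
            mapped[:, 0].min(), mapped[:, 1].min(),
            mapped[:, 0].max(), mapped[:, 1].max(),
        )
        assert p.truth_bbox == pytest.approx(expected, abs=1e-6)


class TestGenerateDataset:
    def test_split_sizes_for_published_corpus_size(self):
        assert lq.partition_sizes(549, (0.7, 0.2, 0.1)) == [384, 110, 55]

    def test_partitions_disjoint_and_exhaustive(self):
        ds = lq.generate_dataset(60, seed=9)
        all_idx = sorted(i for part in ds.partitions.values() for i in part)
        assert all_idx == list(range(60))

    def test_single_class_dataset(self):
        mix = {lq.ReadoutClass.TEST_AND_CONTROL: 1.0}
        ds = lq.generate_dataset(10, class_mix=mix, seed=3)
        assert all(
            s.truth_class is lq.ReadoutClass.TEST_AND_CONTROL for s in ds.samples
        )

    def test_same_seed_same_partition_membership(self):
        a = lq.generate_dataset(30, seed=11)
        b = lq.generate_dataset(30, seed=11)
        assert a.partitions == b.partitions

    def test_bad_class_mix_rejected(self):
        with pytest.raises(lq.ConfigError):
            lq.generate_dataset(20, class_mix={"not_a_class": 1.0}, seed=0)
        with pytest.raises(lq.ConfigError):
            lq.generate_dataset(
                20, class_mix={lq.ReadoutClass.CONTROL_ONLY: 0.5}, seed=0
            )

    def test_minimum_size_enforced(self):
        with pytest.raises(lq.ConfigError):
            lq.generate_dataset(5, seed=0)


class TestMonotonicity:
    def test_extracted_intensity_nondecreasing_below_hook(self):
        """Imaged test-line intensity tracks concentration below the hook
        (10-point grid, 3 seeds, CEA sandwich line)."""
        grid = np.linspace(2.0, 50.0, 10)
        for seed in (1, 2, 3):
            vals = [
                lq.measure_layout_intensities(
                    lq.render_analyte_strip("CEA", c, noise=lq.NO_NOISE, seed=seed)
                )["test"]
                for c in grid
            ]
            assert all(b >= a - 0.5 for a, b in zip(vals, vals[1:]))


def test_dataset_writer_roundtrip(tmp_path):
    ds = lq.generate_dataset(12, seed=2)
    lq.write_dataset(ds, tmp_path)
    import csv

    with open(tmp_path / "manifest.csv") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == 12
    assert all((tmp_path / r["image"]).exists() for r in rows)

    import imageio.v3 as iio
    import json

    img = iio.imread(tmp_path / rows[0]["image"])
    assert img.shape == ds.samples[0].image.shape
    sidecar = json.loads((tmp_path / rows[0]["sidecar"]).read_text())
    assert sidecar["class"] == ds.samples[0].truth_class.value
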