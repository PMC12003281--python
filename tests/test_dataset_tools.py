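"""Dataset tooling: YOLO label I/O, the 8:1:1 split rule, and the
augmentation operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atwkit.dataset_tools import (
    AffineSpec,
    DatasetManifest,
    LabeledImage,
    affine,
    color_distort,
    cutout,
    environment_preset,
    gaussian_noise,
    mosaic,
    read_predictions,
    read_yolo_labels,
    split_dataset,
    write_yolo_labels,
)
from atwkit.detection_eval import Box


def checker(h=40, w=40):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[::2, ::2] = 255
    img[1::2, 1::2] = 128
    return img


valid_box = st.builds(
    lambda cx, cy, w, h: Box(
        0,
        min(max(cx, w / 2), 1 - w / 2),
        min(max(cy, h / 2), 1 - h / 2),
        w,
        h,
    ),
    cx=st.floats(0.0, 1.0),
    cy=st.floats(0.0, 1.0),
    w=st.floats(0.01, 0.9),
    h=st.floats(0.01, 0.9),
)


class TestYoloIO:
    def test_single_line(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n")
        boxes = read_yolo_labels(p)
        assert boxes == [Box(0, 0.5, 0.5, 0.2, 0.1)]

    def test_empty_file_means_no_targets(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    @pytest.mark.parametrize("line", ["0 0.5 0.5 0.2", "0 1.5 0.5 0.2 0.1", "x 0.5 0.5 0.2 0.1"])
    def test_malformed_lines_report_line_number(self, tmp_path, line):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_labels(p)

    @given(boxes=st.lists(valid_box, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_write_read_round_trip(self, tmp_path_factory, boxes):
        p = tmp_path_factory.mktemp("io") / "boxes.txt"
        write_yolo_labels(boxes, p)
        back = read_yolo_labels(p)
        assert len(back) == len(boxes)
        for a, b in zip(boxes, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_prediction_round_trip(self, tmp_path):
        p = tmp_path / "pred.txt"
        p.write_text("0 0.9 0.5 0.5 0.2 0.1\n1 0.35 0.2 0.2 0.1 0.1\n")
        dets = read_predictions(p)
        assert [d.confidence for d in dets] == [0.9, 0.35]
        assert dets[1].box.class_id == 1


class TestSplit:
    def _manifest(self, n):
        return DatasetManifest(items=[{"id": i, "image": f"{i}.png", "label": f"{i}.txt"} for i in range(n)])

    def test_reproduces_published_sizes_at_3358(self):
        sizes = split_dataset(self._manifest(3358), seed=7).split_sizes()
        assert sizes == {"train": 2687, "val": 336, "test": 335}

    def test_small_exact_ratio(self):
        sizes = split_dataset(self._manifest(10), seed=0).split_sizes()
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_deterministic_and_partitioning(self):
        m = self._manifest(97)
        a = split_dataset(m, seed=11)
        b = split_dataset(m, seed=11)
        assert [it["split"] for it in a.items] == [it["split"] for it in b.items]
        assert sum(a.split_sizes().values()) == 97

    def test_seed_changes_assignment(self):
        m = self._manifest(200)
        a = split_dataset(m, seed=1)
        b = split_dataset(m, seed=2)
        assert [it["split"] for it in a.items] != [it["split"] for it in b.items]

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._manifest(2))

    def test_csv_round_trip(self, tmp_path):
        m = split_dataset(self._manifest(12), seed=3)
        p = tmp_path / "manifest.csv"
        m.to_csv(p)
        back = DatasetManifest.from_csv(p)
        assert back.split_sizes() == m.split_sizes()


class TestAffine:
    def test_identity_leaves_boxes(self):
        li = LabeledImage(checker(), [Box(0, 0.5, 0.5, 0.4, 0.2)])
        out = affine(li, AffineSpec())
        assert out.boxes[0].w == pytest.approx(0.4, abs=1e-9)
        assert out.boxes[0].h == pytest.approx(0.2, abs=1e-9)
        assert np.array_equal(out.image, li.image)

    def test_translation_shifts_centers(self):
        li = LabeledImage(checker(), [Box(0, 0.4, 0.3, 0.2, 0.2)])
        out = affine(li, AffineSpec(translate=(0.1, 0.2)))
        b = out.boxes[0]
        assert (b.cx, b.cy) == pytest.approx((0.5, 0.5), abs=1e-9)

    def test_right_angle_rotation_swaps_extents(self):
        li = LabeledImage(checker(), [Box(0, 0.5, 0.5, 0.4, 0.2)])
        b = affine(li, AffineSpec(angle=90)).boxes[0]
        assert (b.w, b.h) == pytest.approx((0.2, 0.4), abs=1e-9)

    def test_boxes_clipped_and_dropped(self):
        li = LabeledImage(checker(), [Box(0, 0.05, 0.05, 0.08, 0.08)])
        out = affine(li, AffineSpec(translate=(-0.5, -0.5)))
        assert out.boxes == []  # shifted off-canvas entirely


class TestColorDistort:
    def test_identity_parameters(self):
        img = checker()
        assert np.array_equal(color_distort(img), img)

    def test_brightness_shifts_mean(self):
        img = np.full((10, 10, 3), 100, dtype=np.uint8)
        out = color_distort(img, brightness=0.2)
        assert out.mean() / 255.0 == pytest.approx(100 / 255 + 0.2, abs=0.01)

    def test_zero_saturation_is_grayscale(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        out = color_distort(img, saturation=0.0)
        assert np.abs(out.astype(int) - out[..., :1].astype(int)).max() <= 1

    def test_fog_preset_reduces_rms_contrast(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        out = environment_preset(img, "fog")
        assert out.astype(float).std() < img.astype(float).std()

    def test_dim_preset_reduces_mean_luminance(self, rng):
        img = rng.integers(50, 256, (32, 32, 3)).astype(np.uint8)
        out = environment_preset(img, "dim")
        assert out.mean() < img.mean()


class TestNoise:
    def test_sigma_zero_is_identity(self):
        img = checker()
        assert np.array_equal(gaussian_noise(img, 0.0, seed=1), img)

    def test_noise_is_zero_mean(self):
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        out = gaussian_noise(img, 0.05, seed=2)
        delta = (out.astype(float) - img.astype(float)) / 255.0
        n = delta.size
        assert abs(delta.mean()) < 3 * 0.05 / np.sqrt(n)

    def test_seeded_determinism(self):
        img = checker()
        a = gaussian_noise(img, 0.1, seed=5)
        b = gaussian_noise(img, 0.1, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, gaussian_noise(img, 0.1, seed=6))


class TestCutout:
    def test_no_patches_is_identity(self):
        li = LabeledImage(checker(), [Box(0, 0.5, 0.5, 0.2, 0.2)])
        out = cutout(li, 0, seed=0)
        assert np.array_equal(out.image, li.image)

    def test_patch_area_fraction(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        li = LabeledImage(img, [])
        out = cutout(li, 1, patch_size=0.2, seed=3)
        changed = (out.image != img).any(axis=-1).sum()
        assert changed <= 20 * 20  # one 20×20 patch (mean fill may equal source)

    def test_labels_unchanged_by_default(self):
        boxes = [Box(0, 0.5, 0.5, 0.9, 0.9)]
        out = cutout(LabeledImage(checker(), boxes), 5, patch_size=0.3, seed=1)
        assert out.boxes == boxes

    def test_drop_fully_occluded_box(self):
        boxes = [Box(0, 0.5, 0.5, 0.1, 0.1)]
        out = cutout(
            LabeledImage(checker(), boxes), 200, patch_size=0.5, seed=1, drop_occluded=0.8
        )
        assert out.boxes == []  # 200 half-size patches cover everything


class TestMosaic:
    def test_four_copies_centered(self):
        li = LabeledImage(np.full((100, 100, 3), 99, np.uint8), [Box(0, 0.5, 0.5, 0.2, 0.2)])
        out = mosaic([li] * 4, (100, 100), jitter=0.0, seed=0)
        assert len(out.boxes) == 4
        centers = sorted((round(b.cx, 3), round(b.cy, 3)) for b in out.boxes)
        assert centers == [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]
        for b in out.boxes:
            assert (b.w, b.h) == pytest.approx((0.1, 0.1), abs=1e-9)

    def test_all_boxes_within_canvas(self, rng):
        imgs = []
        for _ in range(4):
            boxes = [
                Box(0, float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9)), 0.15, 0.15)
                for _ in range(3)
            ]
            imgs.append(LabeledImage(checker(), boxes))
        out = mosaic(imgs, (120, 120), jitter=0.2, seed=9)
        for b in out.boxes:
            x1, y1, x2, y2 = b.corners
            assert -1e-9 <= x1 <= x2 <= 1 + 1e-9
            assert -1e-9 <= y1 <= y2 <= 1 + 1e-9

    def test_seeded_determinism(self):
        li = LabeledImage(checker(), [Box(0, 0.5, 0.5, 0.3, 0.3)])
        a = mosaic([li] * 4, (80, 80), jitter=0.2, seed=4)
        b = mosaic([li] * 4, (80, 80), jitter=0.2, seed=4)
        assert np.array_equal(a.image, b.image)
        assert a.boxes == b.boxes
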