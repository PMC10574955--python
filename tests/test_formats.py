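import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafseg.formats import (
    Box,
    DetectionLabel,
    ImageRecord,
    LabelParseError,
    box_to_yolo,
    read_mask,
    read_yolo_labels,
    split_dataset,
    write_mask,
    write_yolo_labels,
    yolo_to_box,
)


class TestYoloLabels:
    def test_parse_single_line(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("3 0.5 0.5 0.2 0.4\n")
        labels = read_yolo_labels(p)
        assert labels == [DetectionLabel(3, 0.5, 0.5, 0.2, 0.4)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    @pytest.mark.parametrize("line", ["3 0.5 0.5 1.5 0.4", "3 0.5 0.5 0.2", "x 1 1 1 1"])
    def test_malformed_lines_name_the_line(self, tmp_path, line):
        p = tmp_path / "a.txt"
        p.write_text(line + "\n")
        with pytest.raises(LabelParseError, match="line 1"):
            read_yolo_labels(p)

    def test_boundary_jitter_is_clamped(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0 1.0005 0.5 0.2 0.4\n")
        assert read_yolo_labels(p)[0].cx == 1.0

    def test_round_trip_random_labels(self, tmp_path, rng):
        labels = []
        for _ in range(100):
            w, h = rng.uniform(0.05, 0.5, size=2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            labels.append(DetectionLabel(int(rng.integers(0, 39)),
                                         float(cx), float(cy), float(w), float(h)))
        p = tmp_path / "many.txt"
        write_yolo_labels(labels, p)
        back = read_yolo_labels(p)
        assert len(back) == 100
        for a, b in zip(labels, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert abs(getattr(a, f) - getattr(b, f)) < 1e-6


class TestBoxConversion:
    def test_full_image_box(self):
        box = yolo_to_box(DetectionLabel(0, 0.5, 0.5, 1.0, 1.0), 100, 100)
        assert (box.x1, box.y1, box.x2, box.y2) == (0, 0, 100, 100)

    def test_quarter_box_non_square_image(self):
        box = yolo_to_box(DetectionLabel(0, 0.25, 0.25, 0.5, 0.5), 200, 100)
        assert (box.x1, box.y1, box.x2, box.y2) == (0, 0, 100, 50)

    def test_mutual_inverse_on_random_labels(self, rng):
        for _ in range(100):
            w, h = rng.uniform(0.05, 0.4, size=2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            lab = DetectionLabel(0, float(cx), float(cy), float(w), float(h))
            back = box_to_yolo(yolo_to_box(lab, 640, 480), 640, 480)
            for f in ("cx", "cy", "w", "h"):
                assert getattr(back, f) == pytest.approx(getattr(lab, f), abs=1e-9)

    def test_degenerate_box_is_rejected(self):
        with pytest.raises(ValueError):
            Box(5, 5, 5, 10)

    @settings(derandomize=True, max_examples=100)
    @given(
        x1=st.floats(0, 600), y1=st.floats(0, 400),
        w=st.floats(1, 40), h=st.floats(1, 40),
        img=st.tuples(st.integers(640, 1280), st.integers(480, 960)),
    )
    def test_pixel_yolo_pixel_round_trip_property(self, x1, y1, w, h, img):
        img_w, img_h = img
        box = Box(x1, y1, x1 + w, y1 + h)
        back = yolo_to_box(box_to_yolo(box, img_w, img_h), img_w, img_h)
        for f in ("x1", "y1", "x2", "y2"):
            assert getattr(back, f) == pytest.approx(getattr(box, f), abs=1e-6)


class TestMasks:
    def test_tiny_mask_round_trip(self, tmp_path):
        m = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        write_mask(m, tmp_path / "m.png")
        assert np.array_equal(read_mask(tmp_path / "m.png"), m)

    def test_all_background(self, tmp_path):
        m = np.zeros((5, 7), dtype=np.uint8)
        write_mask(m, tmp_path / "m.png")
        assert read_mask(tmp_path / "m.png").max() == 0

    def test_39_class_round_trip(self, tmp_path, rng):
        m = rng.integers(0, 40, size=(33, 21)).astype(np.uint8)
        write_mask(m, tmp_path / "m.png")
        assert np.array_equal(read_mask(tmp_path / "m.png"), m)

    def test_rgb_png_is_rejected_with_guidance(self, tmp_path):
        from PIL import Image

        Image.new("RGB", (4, 4)).save(tmp_path / "rgb.png")
        with pytest.raises(ValueError, match="palette"):
            read_mask(tmp_path / "rgb.png")


def _records(n, n_species, rng):
    return [ImageRecord(f"img_{i}.png", species_id=1 + int(rng.integers(n_species)))
            for i in range(n)]


class TestSplit:
    def test_reference_dataset_arithmetic(self, rng):
        # 9763 images over 39 species at an 8:1:1 ratio with explicit
        # 975-image validation and test sets leaves 7813 for training
        recs = _records(9763, 39, rng)
        manifest = split_dataset(recs, val_count=975, test_count=975, seed=1)
        assert manifest.counts() == {"train": 7813, "val": 975, "test": 975}

    def test_tiny_split(self, rng):
        manifest = split_dataset(_records(10, 2, rng), 1, 1, seed=0)
        assert manifest.counts() == {"train": 8, "val": 1, "test": 1}

    def test_same_seed_identical(self, rng):
        recs = _records(50, 3, rng)
        a = split_dataset(recs, 5, 5, seed=9)
        b = split_dataset(recs, 5, 5, seed=9)
        assert [r.split for r in a.records] == [r.split for r in b.records]

    def test_splits_disjoint_and_exhaustive(self, rng):
        recs = _records(101, 7, rng)
        m = split_dataset(recs, 11, 13, seed=3)
        assert sum(m.counts().values()) == 101
        assert m.counts()["val"] == 11 and m.counts()["test"] == 13

    def test_stratification_is_proportional(self, rng):
        # 2 species of 80/20 records; 10 val slots must split about 8/2
        recs = _records(0, 1, rng)
        recs = [ImageRecord(f"a{i}.png", 1) for i in range(80)]
        recs += [ImageRecord(f"b{i}.png", 2) for i in range(20)]
        m = split_dataset(recs, 10, 10, seed=0)
        val_sp1 = sum(1 for r in m.by_split("val") if r.species_id == 1)
        assert val_sp1 == 8

    def test_counts_exceeding_total_raise(self, rng):
        with pytest.raises(ValueError):
            split_dataset(_records(10, 2, rng), 6, 6, seed=0)
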