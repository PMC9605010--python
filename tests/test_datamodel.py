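import json
import math

import pytest
from hypothesis import given, strategies as st

from trichoscan.datamodel import (
    AnnotationSet,
    CLASS_NAMES,
    Circle,
    CODE_TO_LABEL,
    FollicleAnnotation,
    LABEL_TO_CODE,
    ViaParseError,
    read_via_annotations,
    rescale_annotation,
    split_dataset,
    write_via_annotations,
)


def via_doc(regions, filename="img0.png", width=640, height=480):
    return {
        "_via_img_metadata": {
            filename: {
                "filename": filename,
                "width": width,
                "height": height,
                "regions": regions,
            }
        }
    }


def circle_region(cx, cy, r, code):
    return {
        "shape_attributes": {"name": "circle", "cx": cx, "cy": cy, "r": r},
        "region_attributes": {"class": code},
    }


class TestCircle:
    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            Circle(cx=0, cy=0, r=0)
        with pytest.raises(ValueError):
            Circle(cx=0, cy=0, r=-3)

    def test_non_finite_center_rejected(self):
        with pytest.raises(ValueError):
            Circle(cx=math.nan, cy=0, r=1)

    def test_inside_image(self):
        assert Circle(cx=50, cy=50, r=10).inside_image(640, 480)
        assert not Circle(cx=5, cy=50, r=10).inside_image(640, 480)


class TestClassCodes:
    def test_bijection_is_fixed(self):
        assert CODE_TO_LABEL == {0: "severe", 1: "normal", 2: "healthy"}
        assert all(CODE_TO_LABEL[LABEL_TO_CODE[lbl]] == lbl for lbl in CLASS_NAMES)

    def test_annotation_exposes_code(self):
        ann = FollicleAnnotation("im", Circle(10, 10, 5), "healthy")
        assert ann.class_code == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            FollicleAnnotation("im", Circle(10, 10, 5), "bald")


class TestViaRead:
    def test_single_circle_region_maps_fields(self, tmp_path):
        p = tmp_path / "via.json"
        p.write_text(json.dumps(via_doc([circle_region(100, 80, 15, "2")])))
        ann_set = read_via_annotations(p)
        assert len(ann_set.annotations) == 1
        ann = ann_set.annotations[0]
        assert (ann.circle.cx, ann.circle.cy, ann.circle.r) == (100, 80, 15)
        assert ann.label == "healthy"
        assert ann_set.metadata["parsed"] == 1

    def test_integer_class_code_accepted(self, tmp_path):
        p = tmp_path / "via.json"
        p.write_text(json.dumps(via_doc([circle_region(10, 10, 5, 0)])))
        assert read_via_annotations(p).annotations[0].label == "severe"

    def test_non_circle_region_skipped_with_warning(self, tmp_path, caplog):
        poly = {
            "shape_attributes": {"name": "polygon", "all_points_x": [1], "all_points_y": [1]},
            "region_attributes": {"class": "1"},
        }
        p = tmp_path / "via.json"
        p.write_text(json.dumps(via_doc([circle_region(50, 50, 8, "1"), poly])))
        with caplog.at_level("WARNING"):
            ann_set = read_via_annotations(p)
        assert len(ann_set.annotations) == 1
        assert ann_set.metadata["skipped"] == 1
        assert any("polygon" in rec.message for rec in caplog.records)

    def test_malformed_json_raises(self, tmp_path):
        p = tmp_path / "via.json"
        p.write_text("{not json")
        with pytest.raises(ViaParseError, match="malformed"):
            read_via_annotations(p)

    def test_bad_class_code_names_region(self, tmp_path):
        p = tmp_path / "via.json"
        p.write_text(json.dumps(via_doc([circle_region(10, 10, 5, "7")])))
        with pytest.raises(ViaParseError, match="region 0"):
            read_via_annotations(p)

    def test_border_circle_flagged_not_clipped(self, tmp_path):
        p = tmp_path / "via.json"
        p.write_text(json.dumps(via_doc([circle_region(5, 50, 10, "1")])))
        ann = read_via_annotations(p).annotations[0]
        assert ann.out_of_bounds
        assert ann.circle.r == 10  # geometry untouched


annotation_sets = st.builds(
    lambda circles: AnnotationSet(
        images=[("img0.png", 640, 480), ("img1.png", 640, 480)],
        annotations=[
            FollicleAnnotation(
                image_id=f"img{i % 2}.png",
                circle=Circle(cx, cy, r),
                label=CLASS_NAMES[code],
            )
            for i, (cx, cy, r, code) in enumerate(circles)
        ],
    ),
    st.lists(
        st.tuples(
            st.floats(5, 630), st.floats(5, 470), st.floats(1, 40),
            st.integers(0, 2),
        ),
        max_size=20,
    ),
)


class TestViaRoundTrip:
    @given(annotation_sets)
    def test_lossless_for_circles_and_codes(self, tmp_path_factory, ann_set):
        p = tmp_path_factory.mktemp("via") / "rt.json"
        write_via_annotations(ann_set, p)
        back = read_via_annotations(p)
        assert [im[:3] for im in back.images] == ann_set.images

        def key(ann):
            return (ann.image_id, ann.circle.cx, ann.circle.cy, ann.circle.r, ann.label)

        # lossless as a per-image set (the writer groups regions by image)
        assert sorted(map(key, back.annotations)) == sorted(map(key, ann_set.annotations))

    def test_second_write_byte_identical(self, tmp_path):
        ann_set = AnnotationSet(
            images=[("a.png", 640, 480)],
            annotations=[
                FollicleAnnotation("a.png", Circle(100, 100, 12), "normal"),
                FollicleAnnotation("a.png", Circle(300, 200, 25), "healthy"),
                FollicleAnnotation("a.png", Circle(500, 400, 7), "severe"),
            ],
        )
        p1, p2 = tmp_path / "one.json", tmp_path / "two.json"
        write_via_annotations(ann_set, p1)
        write_via_annotations(read_via_annotations(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_set_valid_json(self, tmp_path):
        p = tmp_path / "empty.json"
        write_via_annotations(AnnotationSet(images=[("a.png", 640, 480)], annotations=[]), p)
        back = read_via_annotations(p)
        assert back.annotations == []


class TestAnnotationSetInvariants:
    def test_unknown_image_id_rejected(self):
        with pytest.raises(ValueError, match="unknown image_id"):
            AnnotationSet(
                images=[("a.png", 640, 480)],
                annotations=[FollicleAnnotation("b.png", Circle(1, 1, 1), "severe")],
            )

    def test_per_image_count_bound(self):
        anns = [
            FollicleAnnotation("a.png", Circle(i + 1, 1, 1), "severe") for i in range(5)
        ]
        with pytest.raises(ValueError, match="max_per_image"):
            AnnotationSet(images=[("a.png", 640, 480)], annotations=anns, max_per_image=3)


def _make_set(n):
    return AnnotationSet(images=[(f"im{i:04d}", 640, 480) for i in range(n)], annotations=[])


class TestSplitDataset:
    def test_study_regime_600_images(self):
        split = split_dataset(_make_set(600), fraction=0.75, seed=1)
        assert len(split.train_ids) == 450
        assert len(split.test_ids) == 150

    def test_small_n_rounding(self):
        split = split_dataset(_make_set(4), fraction=0.75, seed=0)
        assert (len(split.train_ids), len(split.test_ids)) == (3, 1)

    def test_deterministic_under_seed(self):
        s = _make_set(40)
        assert split_dataset(s, 0.75, seed=7) == split_dataset(s, 0.75, seed=7)
        assert split_dataset(s, 0.75, seed=7) != split_dataset(s, 0.75, seed=8)

    def test_partition_and_rounding_rule_all_n(self):
        for n in range(2, 1001):
            split = split_dataset(_make_set(n), fraction=0.75, seed=n)
            train, test = set(split.train_ids), set(split.test_ids)
            assert len(train) == math.floor(0.75 * n + 0.5)
            assert not (train & test)
            assert len(train) + len(test) == n

    def test_annotations_travel_with_images(self):
        ann_set = AnnotationSet(
            images=[("a", 10, 10), ("b", 10, 10), ("c", 10, 10), ("d", 10, 10)],
            annotations=[FollicleAnnotation("b", Circle(5, 5, 2), "normal")],
        )
        split = split_dataset(ann_set, 0.75, seed=0)
        sub = ann_set.subset(list(split.train_ids))
        if "b" in split.train_ids:
            assert len(sub.annotations) == 1
        else:
            assert len(sub.annotations) == 0

    @pytest.mark.parametrize("n,frac", [(1, 0.75), (600, 0.0), (600, 1.0), (600, 1.5)])
    def test_invalid_inputs_rejected(self, n, frac):
        with pytest.raises(ValueError):
            split_dataset(_make_set(n), fraction=frac, seed=0)


def test_rescale_annotation_geometric_mean_radius():
    ann = FollicleAnnotation("a", Circle(200, 100, 10), "normal")
    out = rescale_annotation(ann, 0.8, 1.0)
    assert out.circle.cx == pytest.approx(160)
    assert out.circle.cy == pytest.approx(100)
    assert out.circle.r == pytest.approx(10 * math.sqrt(0.8))
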