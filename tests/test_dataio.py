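"""Annotation rasterization, plant-level splitting, augmentation, VOC layout."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import winding_number_inside
from stemseg import dataio as dio
from stemseg import synthgen as sg


def make_manifest(class_counts, views=4, prefix="p"):
    records = []
    i = 0
    for cls, count in class_counts.items():
        for _ in range(count):
            pid = f"{prefix}_{i:04d}"
            for v in range(views):
                records.append(sg.ManifestRecord(pid, cls, v, f"i/{pid}_{v}.png", f"m/{pid}_{v}.png"))
            i += 1
    return sg.AcquisitionManifest(records, views)


class TestPolygonsToMask:
    def test_axis_aligned_square_covers_16_pixel_centers(self):
        anns = [dio.PolygonAnnotation("stem", ((0, 0), (4, 0), (4, 4), (0, 4)))]
        mask = dio.polygons_to_mask(anns, 8, 8, "stem")
        assert mask.sum() == 16
        assert mask[:4, :4].all()

    def test_empty_and_non_matching_labels_give_zero_mask(self):
        assert dio.polygons_to_mask([], 5, 5, "stem").sum() == 0
        anns = [dio.PolygonAnnotation("pod", ((0, 0), (4, 0), (4, 4)))]
        assert dio.polygons_to_mask(anns, 5, 5, "stem").sum() == 0

    def test_short_polygon_rejected(self):
        with pytest.raises(ValueError):
            dio.PolygonAnnotation("stem", ((0, 0), (1, 1)))

    @settings(max_examples=25, deadline=None)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(-2, 34, allow_nan=False), st.floats(-2, 34, allow_nan=False)
            ),
            min_size=3,
            max_size=7,
        )
    )
    def test_matches_exhaustive_winding_oracle(self, pts):
        """Rasterization agrees with a per-pixel nonzero-winding test on
        canvases up to 32x32, including self-intersecting polygons."""
        anns = [dio.PolygonAnnotation("stem", tuple(pts))]
        mask = dio.polygons_to_mask(anns, 32, 32, "stem")
        for row in range(32):
            for col in range(32):
                expected = winding_number_inside(col + 0.5, row + 0.5, pts)
                assert bool(mask[row, col]) == expected

    def test_read_labelme_keeps_polygons_only(self, tmp_path):
        payload = {
            "shapes": [
                {"label": "stem", "shape_type": "polygon", "points": [[0, 0], [5, 0], [5, 5]]},
                {"label": "tip", "shape_type": "point", "points": [[1, 1]]},
            ]
        }
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(payload))
        anns = dio.read_labelme(path)
        assert len(anns) == 1 and anns[0].label == "stem"


class TestStratifiedPlantSplit:
    def test_reference_study_partition(self):
        m = make_manifest({"simple": 150, "double": 120, "complex": 80})
        result = dio.stratified_plant_split(m, 0.8, 11)
        assert len(result.train_plants) == 280
        assert len(result.val_plants) == 70

    def test_ratio_one_puts_everything_in_train(self):
        m = make_manifest({"simple": 5, "double": 3}, views=2)
        result = dio.stratified_plant_split(m, 1.0, 3)
        assert len(result.train_plants) == 8 and not result.val_plants

    def test_single_class_rounding(self):
        m = make_manifest({"simple": 10}, views=1)
        result = dio.stratified_plant_split(m, 0.8, 0)
        assert len(result.train_plants) == 8 and len(result.val_plants) == 2

    @pytest.mark.parametrize("seed", [0, 11, 42])
    def test_no_plant_leakage_and_determinism(self, seed):
        m = make_manifest({"simple": 13, "double": 7, "complex": 9}, views=3)
        a = dio.stratified_plant_split(m, 0.7, seed)
        b = dio.stratified_plant_split(m, 0.7, seed)
        assert a == b
        assert not (a.train_plants & a.val_plants)
        assert a.train_plants | a.val_plants == {r.plant_id for r in m.records}
        # image-level partitions inherit plant disjointness
        train_imgs = {r.image_path for r in m.records if r.plant_id in a.train_plants}
        val_imgs = {r.image_path for r in m.records if r.plant_id in a.val_plants}
        assert not (train_imgs & val_imgs)

    def test_plant_with_two_classes_rejected(self):
        records = [
            sg.ManifestRecord("p1", "simple", 0, "a.png", "b.png"),
            sg.ManifestRecord("p1", "double", 1, "c.png", "d.png"),
        ]
        m = sg.AcquisitionManifest(records, 2)
        with pytest.raises(ValueError):
            dio.stratified_plant_split(m, 0.8, 0)

    def test_bad_ratio_rejected(self):
        m = make_manifest({"simple": 2}, views=1)
        with pytest.raises(ValueError):
            dio.stratified_plant_split(m, 1.2, 0)


class TestAugmentPair:
    @pytest.fixture
    def pair(self):
        rng = np.random.default_rng(0)
        img = (rng.random((24, 24, 3)) * 255).astype(np.uint8)
        mask = (rng.random((24, 24)) > 0.8).astype(np.uint8)
        return img, mask

    def test_horizontal_flip_is_an_involution(self, pair):
        img, mask = pair
        cfg = dio.AugmentConfig(ops=frozenset({"horizontal_flip"}), prob=1.0)
        i1, m1 = dio.augment_pair(img, mask, cfg, 1)
        i2, m2 = dio.augment_pair(i1, m1, cfg, 2)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(m2, mask)

    def test_zero_degree_rotation_is_identity(self, pair):
        img, mask = pair
        cfg = dio.AugmentConfig(ops=frozenset({"rotation"}), prob=1.0, rotation_deg=0.0)
        i1, m1 = dio.augment_pair(img, mask, cfg, 1)
        np.testing.assert_array_equal(i1, img)
        np.testing.assert_array_equal(m1, mask)

    def test_photometric_ops_leave_mask_untouched(self, pair):
        img, mask = pair
        cfg = dio.AugmentConfig(ops=frozenset({"gaussian_noise", "hsv_perturb"}), prob=1.0)
        _, m1 = dio.augment_pair(img, mask, cfg, 5)
        np.testing.assert_array_equal(m1, mask)

    def test_geometric_ops_keep_mask_binary_and_deterministic(self, pair):
        img, mask = pair
        cfg = dio.AugmentConfig(prob=1.0)
        i1, m1 = dio.augment_pair(img, mask, cfg, 9)
        i2, m2 = dio.augment_pair(img, mask, cfg, 9)
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(m1, m2)
        assert set(np.unique(m1)) <= {0, 1}

    def test_mismatched_shapes_rejected(self, pair):
        img, mask = pair
        with pytest.raises(ValueError):
            dio.augment_pair(img, mask[:-1], dio.AugmentConfig(), 0)


class TestVocLayout:
    def test_round_trip_identity(self, tmp_path):
        m = sg.build_manifest({"simple": 1, "double": 1}, 2, 3, tmp_path / "src", canvas=(96, 96))
        split = dio.stratified_plant_split(m, 0.5, 1)
        dio.write_voc_layout(m, split, tmp_path / "voc")
        m2, split2 = dio.read_voc_layout(tmp_path / "voc")
        assert sorted(r.plant_id for r in m2.records) == sorted(r.plant_id for r in m.records)
        assert {(r.plant_id, r.view_index) for r in m2.records} == {
            (r.plant_id, r.view_index) for r in m.records
        }
        assert split2.train_plants == split.train_plants
        assert split2.val_plants == split.val_plants
        assert (tmp_path / "voc" / "JPEGImages").is_dir()
        assert (tmp_path / "voc" / "SegmentationClass").is_dir()

    def test_validation_listing_counts_views(self, tmp_path):
        m = sg.build_manifest(
            {"simple": 150, "double": 120, "complex": 80}, 4, 11, tmp_path / "d", render=False
        )
        split = dio.stratified_plant_split(m, 0.8, 11)
        dio.write_voc_layout(m, split, tmp_path / "voc")
        val_lines = (tmp_path / "voc" / "ImageSets" / "Segmentation" / "val.txt").read_text().split()
        assert len(val_lines) == 70 * 4

    def test_read_missing_layout_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            dio.read_voc_layout(tmp_path / "nope")
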