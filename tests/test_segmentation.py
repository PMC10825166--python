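"""Segmentation primitives against geometric oracles: rasterized disks and
ellipses with known pixel counts and closed-form eccentricities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cicsquant import (
    ChannelImage,
    FieldOfView,
    compute_morphometrics,
    filter_by_eccentricity,
    identify_primary_objects,
    line_profile,
    mask_image_by_objects,
    mask_objects,
    relate_objects,
)
from cicsquant.errors import DimensionMismatchError
from cicsquant.segmentation import LabelMap, SegmentationParams
from tests.conftest import label_map_from_masks, rasterize_ellipse

PARAMS = SegmentationParams(min_diameter=8, max_diameter=60, smoothing_sigma=0)


class TestIdentifyPrimaryObjects:
    def test_all_zero_image(self):
        with pytest.warns(UserWarning, match="constant"):
            out = identify_primary_objects(ChannelImage(np.zeros((50, 50)), "bec"), PARAMS)
        assert out.n_objects == 0

    def test_two_disks_area_within_2pc(self, disk_image):
        """Oracle: pixel count of each rasterized disk of radius 15."""
        truth_area = int(rasterize_ellipse((200, 200), (50, 50), 15, 15).sum())
        out = identify_primary_objects(disk_image, PARAMS)
        assert out.n_objects == 2
        areas = np.bincount(out.labels.ravel())[1:]
        assert np.all(np.abs(areas - truth_area) <= 0.02 * truth_area)

    def test_declump_splits_touching_disks(self):
        img = np.zeros((120, 120))
        m1 = rasterize_ellipse((120, 120), (60, 45), 18, 18)
        m2 = rasterize_ellipse((120, 120), (60, 72), 18, 18)
        img[m1 | m2] = 100.0
        ch = ChannelImage(img, "bec")
        merged = identify_primary_objects(ch, PARAMS)
        assert merged.n_objects == 1
        split = identify_primary_objects(
            ch, SegmentationParams(min_diameter=8, max_diameter=60,
                                   smoothing_sigma=0, declump="shape"))
        assert split.n_objects == 2

    def test_fill_holes(self):
        img = np.zeros((80, 80))
        ring = rasterize_ellipse((80, 80), (40, 40), 20, 20)
        hole = rasterize_ellipse((80, 80), (40, 40), 8, 8)
        img[ring] = 100.0
        img[hole] = 0.0
        ch = ChannelImage(img, "bec")
        filled = identify_primary_objects(
            ch, SegmentationParams(min_diameter=8, max_diameter=60,
                                   smoothing_sigma=0, fill_holes=True))
        assert filled.footprint[40, 40]

    def test_diameter_filter(self):
        img = np.zeros((100, 100))
        img[rasterize_ellipse((100, 100), (30, 30), 3, 3)] = 100.0   # too small
        img[rasterize_ellipse((100, 100), (70, 70), 12, 12)] = 100.0
        out = identify_primary_objects(ChannelImage(img, "bec"), PARAMS)
        assert out.n_objects == 1

    def test_border_discard(self):
        img = np.zeros((100, 100))
        img[rasterize_ellipse((100, 100), (0, 50), 10, 10)] = 100.0
        img[rasterize_ellipse((100, 100), (50, 50), 10, 10)] = 100.0
        out = identify_primary_objects(
            ChannelImage(img, "bec"),
            SegmentationParams(min_diameter=8, max_diameter=60,
                               smoothing_sigma=0, border_policy="discard"))
        assert out.n_objects == 1


class TestMasking:
    def test_mask_image_empty_and_full(self, disk_image):
        empty = LabelMap(np.zeros(disk_image.shape, dtype=np.int32))
        assert np.all(mask_image_by_objects(disk_image, empty).pixels == 0)
        full = LabelMap(np.ones(disk_image.shape, dtype=np.int32))
        np.testing.assert_array_equal(
            mask_image_by_objects(disk_image, full).pixels, disk_image.pixels)

    def test_mask_image_idempotent(self, disk_image):
        mask = label_map_from_masks(
            disk_image.shape, [rasterize_ellipse(disk_image.shape, (50, 50), 20, 20)])
        once = mask_image_by_objects(disk_image, mask)
        twice = mask_image_by_objects(once, mask)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_mask_objects_noop_and_removal(self):
        shape = (100, 100)
        objs = label_map_from_masks(shape, [
            rasterize_ellipse(shape, (25, 25), 10, 10),
            rasterize_ellipse(shape, (70, 70), 10, 10),
        ])
        far = label_map_from_masks(shape, [rasterize_ellipse(shape, (25, 80), 5, 5)])
        out = mask_objects(objs, far, invert=True)  # mask misses both objects
        assert out.n_objects == 2
        covering = label_map_from_masks(shape, [rasterize_ellipse(shape, (70, 70), 14, 14)])
        out = mask_objects(objs, covering, invert=True)  # deletes object 2 only
        assert out.n_objects == 1
        assert out.footprint[25, 25] and not out.footprint[70, 70]

    def test_full_frame_mask_is_identity(self):
        shape = (60, 60)
        objs = label_map_from_masks(shape, [rasterize_ellipse(shape, (30, 30), 10, 10)])
        full = LabelMap(np.ones(shape, dtype=np.int32))
        np.testing.assert_array_equal(mask_objects(objs, full).labels, objs.labels)

    def test_bisected_disk_remnant_more_eccentric(self):
        """Oracle: second-moment eccentricity of the rasterized half-disk
        exceeds that of the intact disk."""
        shape = (100, 100)
        disk = rasterize_ellipse(shape, (50, 50), 20, 20)
        objs = label_map_from_masks(shape, [disk])
        half_plane = np.zeros(shape, dtype=np.int32)
        half_plane[:, 50:] = 1
        remnant = mask_objects(objs, LabelMap(half_plane), invert=True)
        ecc_disk = compute_morphometrics(objs)["eccentricity"].iloc[0]
        ecc_half = compute_morphometrics(remnant)["eccentricity"].iloc[0]
        half_mask = disk & (np.arange(100)[None, :] < 50)
        oracle = compute_morphometrics(label_map_from_masks(shape, [half_mask]))
        assert ecc_half == pytest.approx(oracle["eccentricity"].iloc[0])
        assert ecc_half > ecc_disk

    def test_dimension_mismatch(self, disk_image):
        small = LabelMap(np.zeros((8, 8), dtype=np.int32))
        with pytest.raises(DimensionMismatchError):
            mask_image_by_objects(disk_image, small)


class TestMorphometrics:
    def test_disk_eccentricity_near_zero(self):
        shape = (80, 80)
        lm = label_map_from_masks(shape, [rasterize_ellipse(shape, (40, 40), 20, 20)])
        assert compute_morphometrics(lm)["eccentricity"].iloc[0] < 0.05

    @pytest.mark.parametrize("a,b", [(40, 20), (40, 30), (30, 15)])
    def test_ellipse_matches_closed_form(self, a, b):
        """Eccentricity of a rasterized ellipse within 0.02 of sqrt(1-(b/a)^2)."""
        shape = (2 * a + 21, 2 * a + 21)
        lm = label_map_from_masks(shape, [rasterize_ellipse(shape, (a + 10, a + 10), a, b)])
        expected = np.sqrt(1 - (b / a) ** 2)
        assert compute_morphometrics(lm)["eccentricity"].iloc[0] == pytest.approx(
            expected, abs=0.02)

    def test_area_scaling(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[5:15, 5:15] = 1
        df = compute_morphometrics(LabelMap(labels), pixel_size=0.65)
        assert df["area_px"].iloc[0] == 100
        assert df["area_um2"].iloc[0] == pytest.approx(42.25)

    def test_degenerate_conventions(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[3, 3] = 1          # single pixel -> 0
        labels[10, 2:12] = 2      # collinear -> 1
        df = compute_morphometrics(LabelMap(labels)).set_index("label")
        assert df.loc[1, "eccentricity"] == 0.0
        assert df.loc[2, "eccentricity"] == 1.0


class TestEccentricityFilter:
    def test_threshold_is_inclusive(self):
        """Objects over 0.92 are removed; at or below 0.92 are kept."""
        shape = (200, 90)
        lo = rasterize_ellipse(shape, (45, 45), 30, 14)    # ecc ~0.885
        hi = rasterize_ellipse(shape, (140, 45), 30, 8)    # ecc ~0.964
        lm = label_map_from_masks(shape, [lo, hi])
        eccs = compute_morphometrics(lm).set_index("label")["eccentricity"]
        assert eccs.loc[1] < 0.92 < eccs.loc[2]
        out = filter_by_eccentricity(lm, 0.92)
        assert out.n_objects == 1
        assert out.footprint[45, 45] and not out.footprint[140, 45]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_on_random_maps(self, seed):
        """Survivor set equals explicit per-object comparison, any label map."""
        rng = np.random.default_rng(seed)
        shape = (120, 120)
        masks, occupied = [], np.zeros(shape, dtype=bool)
        for _ in range(rng.integers(1, 6)):
            a = rng.uniform(4, 18)
            b = a * rng.uniform(0.15, 1.0)
            m = rasterize_ellipse(
                shape, (rng.uniform(20, 100), rng.uniform(20, 100)),
                a, b, rng.uniform(0, np.pi)) & ~occupied
            if m.sum() >= 2:
                masks.append(m)
                occupied |= m
        if not masks:
            return
        lm = label_map_from_masks(shape, masks)
        morpho = compute_morphometrics(lm)
        expected = set(morpho.loc[morpho["eccentricity"] <= 0.92, "label"])
        out = filter_by_eccentricity(lm, 0.92)
        assert out.n_objects == len(expected)
        for old in expected:  # survivors keep their footprints
            centroid = morpho.set_index("label").loc[old]
            r, c = int(centroid["centroid_row"]), int(centroid["centroid_col"])
            if lm.labels[r, c] == old:
                assert out.labels[r, c] > 0


class TestRelateObjects:
    def test_no_overlap_unassigned(self):
        shape = (60, 60)
        children = label_map_from_masks(shape, [rasterize_ellipse(shape, (10, 10), 4, 4)])
        parents = label_map_from_masks(shape, [rasterize_ellipse(shape, (45, 45), 8, 8)])
        assignments, counts = relate_objects(children, parents)
        assert (assignments == 0).all()
        assert (counts == 0).all()

    def test_nested_children_counted(self):
        shape = (80, 80)
        parents = label_map_from_masks(shape, [
            rasterize_ellipse(shape, (20, 20), 12, 12),
            rasterize_ellipse(shape, (60, 60), 12, 12),
        ])
        children = label_map_from_masks(shape, [
            rasterize_ellipse(shape, (20, 20), 3, 3),
            rasterize_ellipse(shape, (18, 24), 3, 3),
            rasterize_ellipse(shape, (60, 60), 3, 3),
        ])
        assignments, counts = relate_objects(children, parents)
        assert assignments.tolist() == [1, 1, 2]
        assert counts.tolist() == [2, 1]

    def test_majority_overlap_wins(self):
        """Oracle: explicit pixel counting for a child straddling two parents."""
        shape = (40, 60)
        p = np.zeros(shape, dtype=np.int32)
        p[:, :24] = 1   # child covers cols 20..39: 4 px in parent 1
        p[:, 24:] = 2   # and 16 px in parent 2
        child = np.zeros(shape, dtype=np.int32)
        child[10, 20:40] = 1
        assignments, _ = relate_objects(LabelMap(child), LabelMap(p))
        overlap1 = int(((child == 1) & (p == 1)).sum())
        overlap2 = int(((child == 1) & (p == 2)).sum())
        assert overlap2 > overlap1
        assert assignments.loc[1] == 2


class TestLineProfile:
    @pytest.fixture
    def ramp_fov(self):
        ramp = np.tile(np.arange(64, dtype=float), (64, 1))
        return FieldOfView("f", {"bec": ChannelImage(ramp, "bec"),
                                 "tcell": ChannelImage(np.full((64, 64), 7.0), "tcell")})

    def test_constant_and_ramp(self, ramp_fov):
        prof = line_profile(ramp_fov, (10, 5), (10, 55), ["bec", "tcell"])
        np.testing.assert_allclose(prof["tcell"], 7.0)
        np.testing.assert_allclose(np.diff(prof["bec"]), 1.0)

    def test_sample_count_contract(self, ramp_fov):
        prof = line_profile(ramp_fov, (5, 5), (35, 45), ["bec"])
        length = np.hypot(30, 40)
        assert len(prof["bec"]) == int(np.floor(length)) + 1

    def test_out_of_bounds(self, ramp_fov):
        with pytest.raises(ValueError, match="outside"):
            line_profile(ramp_fov, (0, 0), (80, 80), ["bec"])


def test_labels_always_contiguous():
    with pytest.raises(ValueError, match="contiguous"):
        LabelMap(np.array([[0, 2], [0, 2]]))
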