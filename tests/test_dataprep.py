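"""Data preparation: rasterization, merging, crops, grouped splits."""

import numpy as np
import pytest
import shapely

from segfuse import (
    DatasetIndex,
    LabelMap,
    binarize_mask,
    group_split,
    merge_class_masks,
    rasterize_boundary,
    slice_crops,
)


class TestRasterize:
    def test_axis_aligned_rectangle_with_boundary(self):
        mask = rasterize_boundary([(1, 1), (4, 1), (4, 3), (1, 3)], 8, 6)
        assert mask.sum() == 12  # x in 1..4, y in 1..3, boundary included
        assert mask[1:4, 1:5].all()

    def test_triangle_covering_single_pixel_center(self):
        mask = rasterize_boundary([(1.6, 1.6), (2.4, 1.6), (2.0, 2.4)], 6, 6)
        assert mask.sum() == 1
        assert mask[2, 2] == 1

    def test_reverse_vertex_order_gives_identical_mask(self):
        poly = [(1, 1), (5, 2), (4, 6), (0, 4)]
        np.testing.assert_array_equal(
            rasterize_boundary(poly, 8, 8),
            rasterize_boundary(poly[::-1], 8, 8),
        )

    @pytest.mark.parametrize(
        "poly",
        [
            [(1, 1), (2, 2)],  # too few vertices
            [(1, 1), (2, 2), (3, 3)],  # collinear, zero area
        ],
    )
    def test_degenerate_polygons_rejected(self, poly):
        with pytest.raises(ValueError):
            rasterize_boundary(poly, 8, 8)

    def test_out_of_bounds_vertices_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            rasterize_boundary([(0, 0), (10, 0), (5, 5)], 8, 8)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_shapely_on_simple_polygons(self, seed):
        # independent geometric cross-check: interior ∪ boundary coverage
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        r = rng.uniform(3, 9)
        cx, cy = rng.uniform(10, 14, 2)
        poly = [(cx + r * np.cos(a), cy + r * np.sin(a)) for a in angles]
        mask = rasterize_boundary(poly, 28, 28)
        sp = shapely.Polygon(poly)
        xs, ys = np.meshgrid(np.arange(28), np.arange(28))
        want = shapely.intersects_xy(sp, xs.ravel(), ys.ravel()).reshape(28, 28)
        np.testing.assert_array_equal(mask.astype(bool), want)


class TestMergeAndBinarize:
    def test_disjoint_masks_union_with_labels(self):
        m1 = np.array([[1, 0, 0]])
        m2 = np.array([[0, 0, 1]])
        merged, overlap = merge_class_masks({1: m1, 2: m2})
        np.testing.assert_array_equal(merged.labels, [[1, 0, 2]])
        assert overlap == 0

    def test_all_zero_masks_merge_to_background(self):
        merged, overlap = merge_class_masks({1: np.zeros((2, 2)), 2: np.zeros((2, 2))})
        assert not merged.labels.any() and overlap == 0

    def test_overlap_goes_to_lowest_class_and_is_counted(self):
        merged, overlap = merge_class_masks(
            {1: np.array([[1, 1]]), 2: np.array([[0, 1]])}
        )
        np.testing.assert_array_equal(merged.labels, [[1, 1]])
        assert overlap == 1

    def test_binarize_examples(self):
        labels = LabelMap(np.array([[0, 1, 2, 1]]))
        np.testing.assert_array_equal(binarize_mask(labels, 1), [[0, 1, 0, 1]])
        np.testing.assert_array_equal(binarize_mask(labels, 3), [[0, 0, 0, 0]])
        with pytest.raises(ValueError, match="unknown class"):
            binarize_mask(labels, 5)

    def test_binarized_masks_partition_the_foreground(self, random_label_arrays):
        arr, _ = random_label_arrays(4)
        labels = LabelMap(arr)
        total = sum(binarize_mask(labels, c) for c in (1, 2, 3))
        np.testing.assert_array_equal(total.astype(bool), labels.foreground)

    def test_rasterize_merge_binarize_round_trip(self):
        p1 = [(2, 2), (10, 2), (10, 6), (2, 6)]
        p2 = [(14, 10), (20, 10), (20, 16), (14, 16)]
        m1 = rasterize_boundary(p1, 24, 20)
        m2 = rasterize_boundary(p2, 24, 20)
        merged, overlap = merge_class_masks({1: m1, 2: m2})
        assert overlap == 0
        np.testing.assert_array_equal(binarize_mask(merged, 1), m1)
        np.testing.assert_array_equal(binarize_mask(merged, 2), m2)


def _blob_labels(H=648, W=1340, cy=300, cx=700, r=60):
    yy, xx = np.ogrid[:H, :W]
    arr = (((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2).astype(int)
    return LabelMap(arr, (1, 2, 3))


class TestSliceCrops:
    def test_default_configuration_on_full_size_frame(self):
        labels = _blob_labels()
        image = np.zeros((648, 1340, 3), np.uint8)
        crops = slice_crops(image, labels, seed=5)
        assert len(crops) == 24
        total = np.count_nonzero(labels.labels)
        for crop_img, crop_lab, win in crops:
            assert crop_img.shape[:2] == (512, 512)
            # independent re-count of the constraint
            assert np.count_nonzero(crop_lab.labels) >= total / 3
            assert 0 <= win.x <= 1340 - 512 and 0 <= win.y <= 648 - 512

    def test_identical_seeds_reproduce_identical_windows(self):
        labels = _blob_labels(H=600, W=800, cx=400, cy=300)
        image = np.zeros((600, 800), np.uint8)
        a = slice_crops(image, labels, seed=9)
        b = slice_crops(image, labels, seed=9)
        assert [(w.x, w.y) for *_, w in a] == [(w.x, w.y) for *_, w in b]
        c = slice_crops(image, labels, seed=10)
        assert [(w.x, w.y) for *_, w in a] != [(w.x, w.y) for *_, w in c]

    def test_exact_size_image_yields_identical_full_frame_crops(self):
        labels = _blob_labels(H=512, W=512, cy=256, cx=256, r=40)
        crops = slice_crops(np.zeros((512, 512), np.uint8), labels, seed=0)
        assert len(crops) == 24
        assert all((w.x, w.y) == (0, 0) for *_, w in crops)
        assert all(w.labeled_fraction == 1.0 for *_, w in crops)

    def test_small_image_rejected(self):
        labels = _blob_labels(H=100, W=100, cy=50, cx=50, r=10)
        with pytest.raises(ValueError, match="smaller"):
            slice_crops(np.zeros((100, 100)), labels, side=512)

    def test_all_background_rejected(self):
        labels = LabelMap(np.zeros((600, 600), int))
        with pytest.raises(ValueError, match="background"):
            slice_crops(np.zeros((600, 600)), labels)

    def test_unsatisfiable_fraction_reported(self):
        # two far-apart blobs: no 512-window can hold 90% of the labels
        arr = np.zeros((648, 1340), int)
        arr[50:150, 50:150] = 1
        arr[500:600, 1200:1300] = 2
        with pytest.raises(ValueError, match="unsatisfiable|fallback"):
            slice_crops(np.zeros((648, 1340)), LabelMap(arr), min_fraction=0.9, seed=0)


class TestGroupSplit:
    def _index(self, sizes: dict[str, int]) -> DatasetIndex:
        records = {
            f"{vid}_f{i}": vid for vid, n in sizes.items() for i in range(n)
        }
        return DatasetIndex(records)

    def test_equal_videos_balance_exactly(self):
        index = self._index({f"v{i}": 4 for i in range(10)})
        out = group_split(index, k=5, seed=0)
        per_fold = {}
        for vid, fold in out.assignments.items():
            per_fold.setdefault(fold, []).append(vid)
        assert len(per_fold) == 5
        assert all(len(v) == 2 for v in per_fold.values())

    def test_no_video_spans_two_assignments(self):
        index = self._index({f"v{i}": i % 5 + 1 for i in range(12)})
        out = group_split(index, k=3, test_videos=("v0", "v1"), seed=2)
        for img, vid in out.records.items():
            assert out.split_of(img) == out.assignments[vid]
        assert out.assignments["v0"] == out.assignments["v1"] == "test"

    def test_full_scale_split_38_videos_4_test_5_folds(self):
        rng = np.random.default_rng(0)
        index = self._index({f"v{i:02d}": int(rng.integers(5, 30)) for i in range(38)})
        test = ("v00", "v05", "v11", "v30")
        out = group_split(index, k=5, test_videos=test, seed=1)
        folds = {}
        for vid, a in out.assignments.items():
            folds.setdefault(a, 0)
            folds[a] += len([i for i, v in index.records.items() if v == vid])
        assert set(folds) == {"test", *(f"fold_{i}" for i in range(5))}
        largest_video = max(
            len([i for i, v in index.records.items() if v == vid])
            for vid in index.videos()
            if vid not in test
        )
        sizes = [folds[f"fold_{i}"] for i in range(5)]
        assert max(sizes) - min(sizes) <= largest_video

    def test_too_few_videos_rejected(self):
        index = self._index({"v0": 3, "v1": 3, "v2": 3})
        with pytest.raises(ValueError, match="folds"):
            group_split(index, k=5)

    def test_seed_reproducibility(self):
        index = self._index({f"v{i}": i + 1 for i in range(9)})
        assert group_split(index, 4, seed=7).assignments == group_split(
            index, 4, seed=7
        ).assignments
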