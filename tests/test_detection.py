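"""Segmentation, morphology, particle analysis and the per-frame pipeline,
each checked against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import trapcam as tc
from trapcam.detection import (
    label_and_filter,
    open_close,
    threshold,
    to_8bit,
)

# ---------------------------------------------------------------- oracles


def otsu_oracle_mask(image):
    """Exhaustive scan of all 256 thresholds, maximising between-class
    variance; foreground is ``image >= t``."""
    image = np.asarray(image)
    best_t, best_var = 0, -1.0
    for t in range(256):
        fg = image >= t
        w1 = fg.mean()
        w0 = 1 - w1
        if w0 == 0 or w1 == 0:
            continue
        var = w0 * w1 * (image[~fg].mean() - image[fg].mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return image >= best_t


def erode_oracle(m, r=1):
    h, w = m.shape
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            out[i, j] = all(
                m[a, b]
                for a in range(max(0, i - r), min(h, i + r + 1))
                for b in range(max(0, j - r), min(w, j + r + 1))
            )
    return out


def dilate_oracle(m, r=1):
    h, w = m.shape
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            out[i, j] = any(
                m[a, b]
                for a in range(max(0, i - r), min(h, i + r + 1))
                for b in range(max(0, j - r), min(w, j + r + 1))
            )
    return out


def flood_fill_areas(mask):
    """Iterative 8-connected flood fill; returns component pixel counts."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, area = [(i, j)], 0
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    area += 1
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            p, q = a + da, b + db
                            if 0 <= p < h and 0 <= q < w and mask[p, q] and not seen[p, q]:
                                seen[p, q] = True
                                stack.append((p, q))
                areas.append(area)
    return areas


# ------------------------------------------------------------------ tests


class TestTo8Bit:
    def test_constant_image_maps_to_zero(self):
        assert (to_8bit(np.full((5, 5), 42.0)) == 0).all()

    def test_three_level_rescale(self):
        out = to_8bit(np.array([[0.0, 2.0, 4.0]]))
        assert out.tolist() == [[0, 128, 255]]

    def test_matches_elementwise_oracle(self, rng):
        img = rng.uniform(-30, 400, size=(14, 9))
        out = to_8bit(img)
        lo, hi = img.min(), img.max()
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                expected = int(np.floor(255 * (img[i, j] - lo) / (hi - lo) + 0.5))
                assert out[i, j] == expected


class TestThreshold:
    def test_fixed_zero_selects_everything(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        assert threshold(img, "fixed", fixed_value=0).mask.all()

    def test_otsu_separates_two_valued_image(self, rng):
        img = np.full(100, 10, dtype=np.uint8)
        img[:10] = 200
        rng.shuffle(img)
        img = img.reshape(10, 10)
        result = threshold(img, "otsu")
        assert np.array_equal(result.mask, img == 200)
        assert np.array_equal(result.mask, otsu_oracle_mask(img))

    def test_otsu_matches_exhaustive_scan_on_random_images(self, rng):
        for _ in range(25):
            img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            assert np.array_equal(threshold(img, "otsu").mask, otsu_oracle_mask(img))

    def test_degenerate_constant_image_flagged_not_raised(self):
        result = threshold(np.full((6, 6), 77, dtype=np.uint8), "otsu")
        assert result.degenerate
        assert result.mask.sum() in (0, result.mask.size)

    def test_fixed_value_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold(np.zeros((3, 3), dtype=np.uint8), "fixed", fixed_value=300)


class TestOpenClose:
    def test_radius_zero_is_identity(self, rng):
        m = rng.random((10, 10)) < 0.4
        assert np.array_equal(open_close(m, radius=0), m)

    def test_isolated_pixel_removed_by_opening(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert open_close(m, radius=1).sum() == 0

    def test_one_pixel_gap_bridged_by_closing(self):
        m = np.zeros((30, 50), dtype=bool)
        m[5:25, 5:25] = True
        m[5:25, 26:46] = True  # 1-px vertical gap at column 25
        out = open_close(m, radius=1)
        assert len(flood_fill_areas(out)) == 1

    def test_matches_set_arithmetic_oracle(self, rng):
        for _ in range(10):
            m = rng.random((16, 16)) < 0.5
            expected = erode_oracle(dilate_oracle(dilate_oracle(erode_oracle(m))))
            assert np.array_equal(open_close(m, radius=1), expected)

    def test_empirical_idempotence(self, rng):
        for _ in range(20):
            m = rng.random((24, 24)) < 0.45
            once = open_close(m, radius=1)
            assert np.array_equal(open_close(once, radius=1), once)


class TestLabelAndFilter:
    @pytest.mark.parametrize(
        "side,expected", [(9, 0), (23, 1)]  # areas 81 (below gate) and 529 (within)
    )
    def test_area_gate(self, side, expected):
        m = np.zeros((40, 40), dtype=bool)
        m[2 : 2 + side, 2 : 2 + side] = True
        recs = label_and_filter(m, 150, 950)
        assert len(recs) == expected
        if expected:
            assert recs[0].area == side * side

    def test_gate_bounds_are_inclusive(self):
        m = np.zeros((40, 120), dtype=bool)
        m[0:10, 0:20] = True     # 200 px: inside
        m[0:24, 30:70] = True    # 960 px: just above
        m[0:10, 80:95] = True    # 150 px: at the lower bound
        recs = label_and_filter(m, 150, 950)
        assert sorted(r.area for r in recs) == [150, 200]

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(200):
            m = rng.random((32, 32)) < 0.45
            areas = flood_fill_areas(m)
            for lo, hi in ((1, 1024), (5, 50), (10, 20)):
                expected = sum(lo <= a <= hi for a in areas)
                assert len(label_and_filter(m, lo, hi)) == expected

    @given(
        mask=arrays(bool, (24, 24), elements=st.booleans()),
        lo=st.integers(1, 40),
        widen=st.integers(0, 40),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_widening_the_gate_never_loses_detections(self, mask, lo, widen):
        hi = lo + 30
        narrow = label_and_filter(mask, lo, hi) if mask.any() else []
        wide = label_and_filter(mask, max(1, lo - widen), hi + widen) if mask.any() else []
        assert len(wide) >= len(narrow)

    def test_roi_restricts_detections(self):
        m = np.zeros((60, 60), dtype=bool)
        m[5:20, 5:20] = True    # 225 px inside roi
        m[35:50, 35:50] = True  # 225 px outside roi
        roi = tc.RegionOfInterest(0, 0, 30, 30)
        recs = label_and_filter(m, 150, 950, roi=roi)
        assert len(recs) == 1
        assert recs[0].centroid[0] < 30

    def test_bbox_contains_centroid(self, rng):
        m = rng.random((32, 32)) < 0.5
        for rec in label_and_filter(m, 1, 1024):
            r0, c0, r1, c1 = rec.bbox
            assert r0 <= rec.centroid[0] < r1
            assert c0 <= rec.centroid[1] < c1


class TestCountFlies:
    def test_empty_scene_counts_zero(self):
        cfg = tc.SimConfig(n_frames=60, arrival_rate=0.0, noise_sd=0.0, seed=1)
        stack, _ = tc.generate_image_sequence(cfg)
        counts = tc.count_flies(stack)
        assert (counts["count"] == 0).all()

    def test_noiseless_stack_recovers_ground_truth_exactly(self, noiseless_stack):
        stack, truth = noiseless_stack
        counts = tc.count_flies(stack)
        assert (counts["count"].to_numpy() == truth.counts).all()
        assert truth.counts.max() >= 2  # the scene actually exercised multi-fly frames

    def test_noisy_stack_matches_ground_truth_most_frames(self):
        cfg = tc.SimConfig(
            n_frames=500, seed=17, noise_sd=4.0, arrival_rate=0.1, departure_rate=0.05
        )
        stack, truth = tc.generate_image_sequence(cfg)
        counts = tc.count_flies(stack)["count"].to_numpy()
        assert (counts == truth.counts).mean() >= 0.95

    def test_image_set_counts_sum_across_surfaces(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "timestamp": [0.0, 6.0, 0.0, 6.0],
                "surface": ["east", "east", "west", "west"],
                "count": [1, 2, 3, 4],
            }
        )
        sets = tc.image_set_counts(df)
        assert sets["set_count"].tolist() == [4, 6]
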