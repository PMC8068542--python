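import numpy as np
import pytest
from skimage.filters import threshold_otsu

from fundustex import RunConfig
from fundustex.detect import (CorrelationScorer, detect_exudates,
                              estimate_background, gamma_transform,
                              intersect_candidates, otsu_threshold, otsu_value,
                              segment_vessels)
from fundustex.quantize import ExtremaRange, QuantizedImage


def qimg(bins, level):
    return QuantizedImage(np.asarray(bins), level, ExtremaRange(0, 255))


class TestGammaTransform:
    def test_rho_one_gives_constant(self):
        q = qimg([[1, 4, 8]], 8)
        assert np.ptp(gamma_transform(q, 1.0)) == 0

    def test_bright_polarity_hand_values(self):
        # L=4, rho=0.5: reversed bins x~ = 5 - x, y = (x~^0.5 - 1)/(4^0.5 - 1)
        q = qimg([[1, 2, 3, 4]], 4)
        out = gamma_transform(q, 0.5, polarity="bright")
        xs = 5.0 - np.array([1.0, 2.0, 3.0, 4.0])
        y = (np.sqrt(xs) - 1.0) / (np.sqrt(4.0) - 1.0)
        expected = np.clip(np.rint(255.0 * (1.0 - y)), 0, 255)
        assert np.array_equal(out[0], expected)

    def test_dark_polarity_hand_values(self):
        q = qimg([[1, 2, 3, 4]], 4)
        out = gamma_transform(q, 0.5, polarity="dark")
        y = (np.sqrt([1.0, 2.0, 3.0, 4.0]) - 1.0) / (np.sqrt(4.0) - 1.0)
        expected = np.clip(np.rint(255.0 * (1.0 - y)), 0, 255)
        assert np.array_equal(out[0], expected)

    @pytest.mark.parametrize("rho", [0.5, 0.7, 0.95])
    def test_monotone_structure_bright(self, rho):
        bins = np.arange(1, 129).reshape(1, -1)
        bright = gamma_transform(qimg(bins, 128), rho, polarity="bright")
        assert (np.diff(bright[0].astype(int)) >= 0).all()
        dark = gamma_transform(qimg(bins, 128), rho, polarity="dark")
        assert (np.diff(dark[0].astype(int)) <= 0).all()

    def test_scale_constant_cancels(self):
        q = qimg([[1, 3, 7, 8]], 8)
        assert np.array_equal(gamma_transform(q, 0.8, c=1.0),
                              gamma_transform(q, 0.8, c=5.0))

    def test_contract_errors(self):
        q = qimg([[1, 2]], 8)
        with pytest.raises(ValueError):
            gamma_transform(q, 0.4)
        with pytest.raises(ValueError):
            gamma_transform(q, 0.8, c=0.0)
        with pytest.raises(ValueError):
            gamma_transform(q, 0.8, polarity="sideways")


def brute_force_otsu(img):
    """Exhaustive between-class-variance search, written independently."""
    vals = img.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_bimodal_perfect_separation(self):
        img = np.array([[10] * 8, [200] * 8], dtype=np.uint8)
        mask = otsu_threshold(img)
        assert np.array_equal(mask, (img == 200).astype(np.uint8))

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, (9, 9)).astype(np.uint8)
            assert otsu_value(img) == brute_force_otsu(img)

    def test_matches_skimage_mask(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (17, 13)).astype(np.uint8)
            t_sk = threshold_otsu(img)
            assert np.array_equal(otsu_threshold(img), (img > t_sk).astype(np.uint8))

    def test_constant_image_empty_mask(self):
        assert otsu_threshold(np.full((4, 4), 9, dtype=np.uint8)).sum() == 0

    def test_inversion_flips_mask(self):
        img = np.array([[10, 10, 240, 240], [10, 240, 10, 240]], dtype=np.uint8)
        m = otsu_threshold(img)
        m_inv = otsu_threshold(255 - img)
        assert np.array_equal(m_inv, 1 - m)

    def test_exclude_mask_drives_threshold(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:2] = 200
        img[2:] = np.array([[90, 110, 90, 110], [110, 90, 110, 90]])
        exclude = np.zeros((4, 4), dtype=bool)
        exclude[:2] = True
        m = otsu_threshold(img, exclude=exclude)
        assert not m[:2].any()                # excluded never candidates
        assert m[2:].sum() == 4               # splits 90 vs 110


class TestIntersect:
    def test_zero_mask_absorbs(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        assert intersect_candidates([m, np.zeros_like(m)]).sum() == 0

    def test_idempotent(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        assert np.array_equal(intersect_candidates([m, m]), m)

    def test_matches_elementwise_and(self, rng):
        masks = [(rng.random((6, 6)) > 0.4).astype(np.uint8) for _ in range(4)]
        expected = masks[0] & masks[1] & masks[2] & masks[3]
        assert np.array_equal(intersect_candidates(masks), expected)

    def test_monotone_adding_masks_never_adds_pixels(self, rng):
        masks = [(rng.random((6, 6)) > 0.3).astype(np.uint8) for _ in range(4)]
        prev = intersect_candidates(masks[:1])
        for k in range(2, 5):
            cur = intersect_candidates(masks[:k])
            assert not (cur & ~prev).any()
            prev = cur

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            intersect_candidates([np.zeros((2, 2)), np.zeros((3, 3))])
        with pytest.raises(ValueError):
            intersect_candidates([])


class TestBackground:
    def test_channel_sum_rule(self):
        rgb = np.array([[[0, 0, 0], [40, 40, 40], [30, 30, 30]]], dtype=np.uint8)
        bg = estimate_background(rgb, 100)
        assert bg.mask.tolist() == [[0, 1, 0]]    # 0, 120, 90 vs 100

    def test_maximal_threshold_all_background(self, rng):
        rgb = rng.integers(0, 256, (5, 5, 3), dtype=np.uint8)
        assert estimate_background(rgb, 765).mask.sum() == 0

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((4, 4), dtype=np.uint8))


class _ForcedScorer:
    def __init__(self, value):
        self.value = value

    def score_grid(self, grid):
        return np.full(grid.n_segments, self.value)


class TestDetect:
    def test_no_gated_segment_gives_empty_mask(self, rng, small_config):
        img = rng.integers(0, 256, (64, 96)).astype(np.uint8)
        res = detect_exudates(img, _ForcedScorer(0.0), small_config)
        assert res.mask.shape == (64, 96)
        assert res.mask.sum() == 0

    def test_rho_one_degenerates_to_empty(self, rng, small_config):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        res = detect_exudates(img, _ForcedScorer(1.0), small_config)
        assert res.mask.sum() == 0

    def test_mask_zero_outside_gated_segments(self, rng, small_config):
        img = rng.integers(0, 256, (96, 96)).astype(np.uint8)

        class HalfScorer:
            def score_grid(self, grid):
                s = np.zeros(grid.n_segments)
                s[0] = 0.8
                return s

        res = detect_exudates(img, HalfScorer(), small_config)
        w = small_config.window
        assert res.mask[w:, :].sum() == 0
        assert res.mask[:w, w:].sum() == 0

    def test_mask_shape_strips_padding(self, rng, small_config):
        img = rng.integers(0, 256, (70, 45)).astype(np.uint8)
        res = detect_exudates(img, _ForcedScorer(0.8), small_config)
        assert res.mask.shape == (70, 45)

    def test_planted_blob_recovered_with_oracle_scorer(self):
        """A bright blob on a noisy field is found by the full chain."""
        from fundustex.image_io import green_channel
        from fundustex.metrics import confusion
        from fundustex.synthetic import SyntheticSpec, make_fundus, make_labeled_grids

        cfg = RunConfig()
        specs = [SyntheticSpec(seed=500 + k) for k in range(3)]
        batch = make_labeled_grids(specs, cfg, target="exudate")
        scorer = CorrelationScorer(batch.benchmark, batch.scaler)
        tp = fn = 0
        for spec in specs:
            rgb, _, emask = make_fundus(spec)
            bg = estimate_background(rgb, cfg.background_threshold)
            res = detect_exudates(green_channel(rgb), scorer, cfg,
                                  field_mask=bg.mask)
            c = confusion(res.mask, emask)
            tp += c.tp
            fn += c.fn
        assert tp / (tp + fn) > 0.7


class TestVessels:
    def test_all_background_image_empty(self, small_config):
        rgb = np.zeros((64, 64, 3), dtype=np.uint8)
        res = segment_vessels(rgb, _ForcedScorer(0.9), small_config)
        assert res.mask.sum() == 0

    def test_no_candidates_outside_aperture(self, small_config):
        rng = np.random.default_rng(3)
        rgb = np.zeros((96, 96, 3), dtype=np.uint8)
        rgb[20:76, 20:76] = rng.integers(60, 200, (56, 56, 3), dtype=np.uint8)
        res = segment_vessels(rgb, _ForcedScorer(0.8), small_config)
        bg = estimate_background(rgb, small_config.background_threshold)
        assert (res.mask & (1 - bg.mask)).sum() == 0
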