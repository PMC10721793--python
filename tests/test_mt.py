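"""Unit and property tests of the trichrome fibrosis-score pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fibroquant import (
    MTParams,
    MTSceneParams,
    MTStepError,
    estimate_background,
    extract_collagen_mask,
    estimate_fibrotic_region,
    estimate_lung_region,
    fibrosis_score,
    fill_edges,
    generate_mt_image,
    moving_average_density,
    run_mt_pipeline,
    segment_alveolar_walls,
)

from _oracles import brute_density


def solid(shape, color):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = color
    return img


class TestBackground:
    def test_uniform_image_is_all_background(self):
        img = solid((20, 30), (240, 240, 240))
        mask, mean = estimate_background(img)
        assert mask.all()
        np.testing.assert_allclose(mean, [240, 240, 240])

    def test_chromatic_half_is_excluded(self):
        # right half saturated blue: CoV = sd/mean is large, fails the cutoff
        img = solid((10, 20), (245, 245, 245))
        img[:, 10:] = (40, 40, 220)
        mask, mean = estimate_background(img, cov_threshold=0.05, brightness_floor=200)
        assert mask[:, :10].all() and not mask[:, 10:].any()
        np.testing.assert_allclose(mean, [245, 245, 245])

    def test_no_background_raises_naming_thresholds(self):
        img = solid((5, 5), (40, 40, 220))
        with pytest.raises(MTStepError, match="cov_threshold.*brightness_floor"):
            estimate_background(img)

    def test_synthetic_lung_rarely_flagged_as_background(self, mt_scene):
        _, img, truth = mt_scene
        mask, _ = estimate_background(img)
        overlap = (mask & truth.lung_mask).sum() / truth.lung_mask.sum()
        assert overlap < 0.01


class TestFillEdges:
    def test_zero_border_is_identity(self):
        img = solid((8, 8), (10, 20, 30))
        out = fill_edges(img, np.array([200.0, 200.0, 200.0]), 0)
        np.testing.assert_array_equal(out, img)

    def test_exactly_the_frame_changes(self):
        img = solid((10, 10), (0, 0, 0))
        out = fill_edges(img, np.array([200.0, 200.0, 200.0]), 1)
        changed = (out != img).any(axis=2)
        assert changed.sum() == 36  # the 1-px frame of a 10x10 image
        assert changed[0].all() and changed[-1].all()
        assert changed[:, 0].all() and changed[:, -1].all()

    @given(border=st.integers(min_value=0, max_value=7))
    def test_interior_untouched(self, border):
        rng = np.random.default_rng(border)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        out = fill_edges(img, np.array([123.0, 45.0, 67.0]), border)
        if border:
            np.testing.assert_array_equal(
                out[border:-border, border:-border], img[border:-border, border:-border]
            )
        else:
            np.testing.assert_array_equal(out, img)

    def test_too_wide_border_rejected(self):
        with pytest.raises(ValueError):
            fill_edges(solid((10, 10), (0, 0, 0)), np.zeros(3), 5)


class TestWallSegmentation:
    def test_all_white_gives_empty_mask(self):
        img = solid((10, 10), (245, 245, 245))
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_alveolar_walls(img, np.array([245.0] * 3))
        assert not mask.any()

    def test_fixed_threshold_selects_dark_stripe_exactly(self):
        img = solid((20, 20), (245, 245, 245))
        img[8:12, :] = (50, 50, 50)
        mask = segment_alveolar_walls(img, np.array([245.0] * 3), method=120)
        expected = np.zeros((20, 20), dtype=bool)
        expected[8:12, :] = True
        np.testing.assert_array_equal(mask, expected)

    def test_synthetic_wall_recall_and_precision(self, mt_scene):
        _, img, truth = mt_scene
        _, bg = estimate_background(img)
        mask = segment_alveolar_walls(img, bg)
        tp = (mask & truth.wall_mask).sum()
        assert tp / truth.wall_mask.sum() >= 0.95  # recall
        assert tp / mask.sum() >= 0.95  # precision


class TestLungRegion:
    def test_closing_is_identity_on_filled_disk(self):
        yy, xx = np.ogrid[:80, :80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 25 ** 2
        out = estimate_lung_region(disk, dilation_radius=7, min_contour_area=10)
        np.testing.assert_array_equal(out, disk)

    def test_small_speck_is_discarded(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5, 5:8] = True  # 3-px speck
        out = estimate_lung_region(mask, dilation_radius=1, min_contour_area=50)
        assert not out.any()

    def test_empty_input_gives_empty_output(self):
        out = estimate_lung_region(np.zeros((10, 10), dtype=bool), 3, 10)
        assert not out.any()

    def test_synthetic_lung_recovered(self, mt_scene):
        _, img, truth = mt_scene
        _, bg = estimate_background(img)
        wall = segment_alveolar_walls(img, bg)
        lung = estimate_lung_region(wall, 10, 262)
        cover = (lung & truth.lung_mask).sum() / truth.lung_mask.sum()
        assert cover >= 0.99
        assert abs(lung.sum() - truth.lung_mask.sum()) / truth.lung_mask.sum() < 0.05


class TestFibroticRegion:
    def test_sparse_lattice_below_threshold_is_empty(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[::10, :] = True  # exact density 0.1 along rows
        out = estimate_fibrotic_region(mask, density_window=5, density_threshold=0.5)
        assert not out.any()

    def test_all_true_mask_passes_in_the_interior(self):
        mask = np.ones((30, 30), dtype=bool)
        out = estimate_fibrotic_region(mask, density_window=5, density_threshold=0.9)
        assert out[2:-2, 2:-2].all()

    def test_dense_patch_recovered_and_density_matches_bruteforce(self, rng):
        mask = rng.random((64, 64)) < 0.1
        mask[20:44, 20:44] = rng.random((24, 24)) < 0.6
        window = 7
        density = moving_average_density(mask, window)
        np.testing.assert_allclose(density, brute_density(mask, window), atol=1e-12)
        patch = np.zeros_like(mask)
        patch[20:44, 20:44] = True
        fib = estimate_fibrotic_region(mask, window, 0.35)
        jac = (fib & patch).sum() / (fib | patch).sum()
        assert jac >= 0.7  # noisy small instance; the planted patch dominates

    @given(st.integers(0, 500))
    def test_density_equals_bruteforce_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 20, size=2)
        window = int(rng.choice([3, 5, 7]))
        mask = rng.random((h, w)) < rng.random()
        np.testing.assert_allclose(
            moving_average_density(mask, window), brute_density(mask, window), atol=1e-12
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average_density(np.zeros((5, 5), dtype=bool), 4)


BLUE = (70, 90, 185)
RED = (200, 85, 95)


def two_color_scene(frac_blue: float, n: int = 400, seed: int = 0):
    """Noise-free candidates: a frac_blue : (1-frac_blue) blue/red mixture."""
    rng = np.random.default_rng(seed)
    h = w = int(np.ceil(np.sqrt(n)))
    img = np.zeros((h, w, 3), dtype=np.uint8)
    is_blue = np.zeros(h * w, dtype=bool)
    is_blue[: int(round(frac_blue * n))] = True
    rng.shuffle(is_blue)
    flat = img.reshape(-1, 3)
    flat[is_blue] = BLUE
    flat[~is_blue] = RED
    cand = np.ones((h, w), dtype=bool)
    return img, cand, is_blue.reshape(h, w)


class TestCollagenUnmixing:
    def test_single_color_is_degenerate(self):
        img = solid((10, 10), BLUE)
        cand = np.ones((10, 10), dtype=bool)
        with pytest.warns(UserWarning, match="rank-deficient"):
            mask, sel, _, pol = extract_collagen_mask(img, cand, cand)
        assert not mask.any() and sel == 0 and pol == 0

    def test_too_few_candidates_is_degenerate(self):
        img = solid((10, 10), BLUE)
        cand = np.zeros((10, 10), dtype=bool)
        cand[0, :5] = True
        with pytest.warns(UserWarning, match="candidate"):
            mask, *_ = extract_collagen_mask(img, cand, cand)
        assert not mask.any()

    @pytest.mark.parametrize("frac_blue", [0.3, 0.5, 0.7])
    def test_mask_equals_blue_pixels(self, frac_blue):
        img, cand, is_blue = two_color_scene(frac_blue)
        mask, sel, loading, pol = extract_collagen_mask(img, cand, cand)
        np.testing.assert_array_equal(mask, is_blue)
        assert pol in (-1, 1)

    def test_polarity_invariant_under_mixture_swap(self):
        # 30/70 and 70/30 mixtures flip the raw PC sign; the mask must not flip
        for frac in (0.3, 0.7):
            img, cand, is_blue = two_color_scene(frac, seed=3)
            mask, *_ = extract_collagen_mask(img, cand, cand)
            np.testing.assert_array_equal(mask, is_blue)

    def test_invariant_under_pixel_permutation(self):
        img, cand, is_blue = two_color_scene(0.4, seed=1)
        h, w, _ = img.shape
        rng = np.random.default_rng(9)
        perm = rng.permutation(h * w)
        img2 = img.reshape(-1, 3)[perm].reshape(h, w, 3)
        is_blue2 = is_blue.reshape(-1)[perm].reshape(h, w)
        mask2, *_ = extract_collagen_mask(img2, cand, cand)
        np.testing.assert_array_equal(mask2, is_blue2)


class TestScore:
    def test_empty_collagen_scores_zero(self):
        lung = np.ones((10, 10), dtype=bool)
        assert fibrosis_score(np.zeros_like(lung), lung) == 0.0

    def test_full_collagen_scores_one(self):
        lung = np.ones((10, 10), dtype=bool)
        assert fibrosis_score(lung, lung) == 1.0

    def test_ratio_arithmetic(self):
        lung = np.zeros((40, 40), dtype=bool)
        lung[:25, :40] = True  # 1000 px
        collagen = np.zeros_like(lung)
        collagen[:10, :25] = True  # 250 px inside lung
        assert fibrosis_score(collagen, lung) == 0.25

    def test_empty_lung_raises(self):
        with pytest.raises(MTStepError, match="lung"):
            fibrosis_score(np.zeros((5, 5), dtype=bool), np.zeros((5, 5), dtype=bool))


class TestPipeline:
    def test_no_collagen_scores_near_zero(self):
        img, truth = generate_mt_image(MTSceneParams(collagen_patch_fraction=0.0, seed=1))
        res = run_mt_pipeline(img)
        assert truth.planted_score == 0.0
        assert res.fibrosis_score <= 0.01

    def test_planted_score_recovered(self, mt_scene):
        _, img, truth = mt_scene
        res = run_mt_pipeline(img)
        assert abs(res.fibrosis_score - truth.planted_score) <= 0.05
        # nesting invariants
        assert not (res.collagen_mask & ~(res.fibrotic_mask & res.wall_mask)).any()
        assert 0.0 <= res.fibrosis_score <= 1.0

    def test_scores_increase_with_planted_fraction(self):
        scores = []
        for f in (0.10, 0.30, 0.50):
            img, _ = generate_mt_image(MTSceneParams(collagen_patch_fraction=f, seed=21))
            scores.append(run_mt_pipeline(img).fibrosis_score)
        assert scores[0] < scores[1] < scores[2]

    def test_deterministic(self, mt_scene):
        _, img, _ = mt_scene
        a = run_mt_pipeline(img)
        b = run_mt_pipeline(img)
        assert a.fibrosis_score == b.fibrosis_score
        np.testing.assert_array_equal(a.collagen_mask, b.collagen_mask)

    def test_step_failure_names_the_step(self):
        img = solid((32, 32), (40, 40, 220))  # no achromatic background anywhere
        with pytest.raises(MTStepError, match=r"\[estimate_background\]|\[background\]"):
            run_mt_pipeline(img)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cov_threshold": 0.0},
            {"density_window": 4},
            {"density_window": 1},
            {"density_threshold": 1.5},
            {"connectivity": 6},
            {"pca_components": (4,)},
            {"wall_threshold": "median"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MTParams(**kwargs)

    def test_default_min_contour_area_scales_with_image(self):
        assert MTParams().resolved_min_contour_area((512, 512)) == 262
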