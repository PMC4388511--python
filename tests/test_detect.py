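import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from conftest import render_spot
from qendosomes import (
    Candidate,
    DetectionParams,
    EndosomeDetector,
    ImageStack,
    detect_endosomes,
    find_candidates,
    fit_gaussian_sigma,
    gaussian_template,
    max_project,
    score_candidate,
    smooth_plane,
)


class TestSmoothing:
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.5])
    def test_constant_plane_preserved(self, sigma):
        plane = np.full((30, 30), 7.5)
        assert np.allclose(smooth_plane(plane, sigma), 7.5)

    def test_impulse_response_peak_matches_normalized_kernel(self):
        plane = np.zeros((31, 31))
        plane[15, 15] = 1.0
        out = smooth_plane(plane, 1.0)
        # center of a unit-mass 2D Gaussian of sigma 1: 1/(2*pi)
        assert out[15, 15] == pytest.approx(1.0 / (2.0 * np.pi), abs=1e-3)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_spot_width_grows_by_variance_addition(self):
        """sigma-2.07 spot smoothed with sigma 1 reads sigma sqrt(2.07^2+1) ~ 2.30."""
        spot = render_spot(shape=(31, 31), sigma=2.07, amplitude=1.0, background=0.0)
        fitted = fit_gaussian_sigma(smooth_plane(spot, 1.0))
        assert fitted == pytest.approx(np.hypot(2.07, 1.0), abs=0.01)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_plane(np.zeros((10, 10)), 0.0)


class TestMaxProject:
    def test_single_plane_equals_smoothed_plane(self):
        plane = render_spot()
        stack = ImageStack(plane[None])
        assert np.allclose(max_project(stack, 1.0), smooth_plane(plane, 1.0))

    def test_spot_plane_dominates_zero_plane(self):
        spot = render_spot(background=0.0)
        stack = ImageStack(np.stack([np.zeros_like(spot), spot]))
        assert np.allclose(max_project(stack, 1.0), smooth_plane(spot, 1.0))

    def test_spots_from_different_planes_both_appear(self):
        vol = np.zeros((15, 61, 61))
        vol[3] = render_spot(shape=(61, 61), center=(15, 15), background=0.0)
        vol[9] = render_spot(shape=(61, 61), center=(45, 45), background=0.0)
        proj = max_project(ImageStack(vol), 1.0)
        m = proj.max()
        assert proj[15, 15] == pytest.approx(m, rel=1e-6)
        assert proj[45, 45] == pytest.approx(m, rel=1e-6)


class TestFindCandidates:
    def test_constant_image_has_no_candidates(self, default_params):
        assert find_candidates(np.full((50, 50), 3.0), default_params) == []

    def test_bright_peak_passes_background_threshold(self, default_params):
        img = np.full((21, 21), 100.0)
        img[10, 10] = 2000.0
        (cand,) = find_candidates(img, default_params)
        assert (cand.row, cand.col) == (10, 10)
        assert cand.peak_intensity == 2000.0
        assert cand.local_background == 100.0

    def test_dim_peak_rejected(self, default_params):
        img = np.full((21, 21), 100.0)
        img[10, 10] = 150.0  # 150 < 1.9 * 100
        assert find_candidates(img, default_params) == []

    def test_border_maxima_discarded(self, default_params):
        img = np.full((21, 21), 100.0)
        img[1, 1] = 5000.0  # within patch_radius of the border
        assert find_candidates(img, default_params) == []

    def test_plateau_keeps_single_lexicographically_smallest_pixel(self, default_params):
        img = np.full((21, 21), 100.0)
        img[10:12, 10:12] = 2000.0  # 2x2 flat top
        cands = find_candidates(img, default_params)
        assert [(c.row, c.col) for c in cands] == [(10, 10)]

    def test_sorted_by_descending_peak(self, default_params):
        img = np.full((41, 41), 100.0)
        img[10, 10] = 900.0
        img[30, 30] = 1800.0
        peaks = [c.peak_intensity for c in find_candidates(img, default_params)]
        assert peaks == sorted(peaks, reverse=True)

    def test_range_threshold_mode(self):
        params = DetectionParams(background_threshold_pct=90, threshold_mode="range")
        img = np.full((31, 31), 100.0)
        img[10, 10] = 2000.0
        img[20, 20] = 1500.0
        # global dynamic range 1900: peaks must exceed 100 + 0.9*1900 = 1810
        cands = find_candidates(img, params)
        assert [(c.row, c.col) for c in cands] == [(10, 10)]


class TestGaussianTemplate:
    def test_center_and_corner_values(self):
        t = gaussian_template(2.30, 4)
        assert t[4, 4] == 1.0
        assert t[0, 0] == pytest.approx(np.exp(-32.0 / (2.0 * 2.30**2)), rel=1e-12)
        assert t[0, 0] == pytest.approx(0.0486, abs=5e-4)

    @given(sigma=st.floats(0.3, 20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fourfold_rotational_symmetry(self, sigma):
        t = gaussian_template(sigma, 4)
        assert np.allclose(t, np.rot90(t))
        assert np.allclose(t, t.T)

    def test_large_sigma_tends_to_one(self):
        assert np.allclose(gaussian_template(1e6, 4), 1.0, atol=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            gaussian_template(0.0, 4)
        with pytest.raises(ValueError):
            gaussian_template(2.3, 0)


class TestScoreCandidate:
    def test_exact_template_scores_one(self, default_params):
        img = np.zeros((21, 21))
        img[6:15, 6:15] = gaussian_template(2.30, 4)
        c = Candidate(10, 10, 1.0, 0.0)
        assert score_candidate(img, c, default_params) == pytest.approx(1.0, abs=1e-12)

    def test_affine_rescaling_leaves_score_unchanged(self, default_params):
        img = np.zeros((21, 21))
        img[6:15, 6:15] = 500.0 * gaussian_template(2.30, 4) + 100.0
        img += 100.0
        c = Candidate(10, 10, float(img[10, 10]), 100.0)
        assert score_candidate(img, c, default_params) == pytest.approx(1.0, abs=1e-12)

    def test_membrane_ridge_scores_below_cutoff(self, default_params):
        yy, xx = np.mgrid[0:21, 0:21].astype(float)
        ridge = np.exp(-((xx - 10.0) ** 2) / (2.0 * 5.15**2))
        c = Candidate(10, 10, 1.0, 0.0)
        assert score_candidate(ridge, c, default_params) < 0.75

    def test_zero_variance_patch_scores_zero(self, default_params):
        img = np.full((21, 21), 5.0)
        c = Candidate(10, 10, 5.0, 5.0)
        assert score_candidate(img, c, default_params) == 0.0

    def test_border_candidate_rejected(self, default_params):
        with pytest.raises(ValueError):
            score_candidate(np.zeros((21, 21)), Candidate(1, 1, 1.0, 0.0), default_params)


class TestDetectEndosomes:
    def test_zero_stack_yields_nothing(self, default_params):
        assert detect_endosomes(ImageStack(np.zeros((3, 30, 30))), default_params) == []

    def test_single_rendered_spot_detected_at_center(self, default_params):
        img = render_spot(shape=(41, 41), sigma=2.07, amplitude=1652.0)
        dets = detect_endosomes(ImageStack(img[None]), default_params)
        assert len(dets) == 1
        assert (dets[0].row, dets[0].col) == (20, 20)
        assert dets[0].correlation > 0.9

    def test_membrane_ridge_rejected_spot_kept(self, default_params):
        img = np.full((61, 61), 100.0)
        yy, xx = np.mgrid[0:61, 0:61].astype(float)
        img += 800.0 * np.exp(-((xx - 12.0) ** 2) / (2.0 * 5.15**2))
        img += 1652.0 * np.exp(-((yy - 30.0) ** 2 + (xx - 42.0) ** 2) / (2.0 * 2.07**2))
        # noise perturbation so the ridge crest produces discrete maxima
        rng = np.random.default_rng(0)
        img = np.clip(img + rng.normal(0, 10.0, img.shape), 0, None)
        dets = detect_endosomes(ImageStack(img[None]), default_params)
        assert len(dets) == 1
        assert abs(dets[0].row - 30) <= 1 and abs(dets[0].col - 42) <= 1

    def test_deterministic(self, default_params):
        rng = np.random.default_rng(5)
        img = np.clip(rng.normal(100, 30, (1, 80, 80)), 0, None)
        a = detect_endosomes(ImageStack(img), default_params)
        b = detect_endosomes(ImageStack(img.copy()), default_params)
        assert a == b

    def test_timestamp_propagates(self, default_params):
        img = render_spot(shape=(41, 41))
        dets = detect_endosomes(ImageStack(img[None], timestamp=7.0), default_params)
        assert dets and dets[0].timestamp == 7.0

    def test_raising_correlation_cutoff_shrinks_detection_set(self):
        rng = np.random.default_rng(11)
        img = np.clip(rng.normal(100, 40, (90, 90)), 0, None)
        yy, xx = np.mgrid[0:90, 0:90].astype(float)
        for r, c in [(20, 20), (40, 70), (70, 30)]:
            img += 1652 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 2.07**2))
        stack = ImageStack(img[None])
        sets = []
        for cmin in (0.0, 0.5, 0.75, 0.9):
            dets = detect_endosomes(stack, DetectionParams(correlation_min=cmin))
            sets.append({(d.row, d.col) for d in dets})
        for tighter, looser in zip(sets[1:], sets[:-1]):
            assert tighter <= looser

    def test_intensity_scaling_invariance(self, default_params):
        rng = np.random.default_rng(13)
        img = np.clip(rng.normal(100, 30, (80, 80)), 0, None)
        yy, xx = np.mgrid[0:80, 0:80].astype(float)
        img += 1652 * np.exp(-((yy - 40) ** 2 + (xx - 40) ** 2) / (2 * 2.07**2))
        a = detect_endosomes(ImageStack(img[None]), default_params)
        b = detect_endosomes(ImageStack((3.7 * img)[None]), default_params)
        assert [(d.row, d.col) for d in a] == [(d.row, d.col) for d in b]
        assert np.allclose(
            [d.correlation for d in a], [d.correlation for d in b], atol=1e-9
        )


class TestEndosomeDetector:
    def test_sklearn_params_roundtrip_and_clone(self):
        det = EndosomeDetector(correlation_min=0.8, patch_radius=3)
        assert det.get_params()["correlation_min"] == 0.8
        cloned = clone(det)
        assert cloned.get_params() == det.get_params()
        det.set_params(smooth_sigma=2.0)
        assert det.smooth_sigma == 2.0

    def test_fit_exposes_pipeline_results(self, spot_image):
        det = EndosomeDetector().fit(spot_image)
        assert det.projection_.shape == spot_image.shape
        assert det.n_detections_ == len(det.detections_) == 1
        assert det.n_candidates_ >= det.n_detections_

    def test_fit_predict_returns_positions(self, spot_image):
        pos = EndosomeDetector().fit_predict(spot_image)
        assert pos.shape == (1, 2)
        assert tuple(pos[0]) == (20, 20)


class TestValidation:
    def test_image_stack_rejects_bad_input(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((10, 10)))  # 2D
        with pytest.raises(ValueError):
            ImageStack(-np.ones((1, 10, 10)))
        with pytest.raises(ValueError):
            ImageStack(np.full((1, 10, 10), np.nan))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"smooth_sigma": -1.0},
            {"template_sigma": 0.0},
            {"patch_radius": 1},
            {"background_threshold_pct": -5.0},
            {"correlation_min": 1.5},
            {"threshold_mode": "weird"},
        ],
    )
    def test_detection_params_invariants(self, kwargs):
        with pytest.raises(ValueError):
            DetectionParams(**kwargs)

    def test_candidate_peak_must_exceed_background(self):
        with pytest.raises(ValueError):
            Candidate(5, 5, 10.0, 20.0)
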