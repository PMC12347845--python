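"""ROI detection and Gaussian PSF fitting (least squares + MLEwG)."""

import math

import numpy as np
import pytest
from scipy.special import erf

from beadcal import (
    ROI,
    FitResult,
    PrecisionInputs,
    detect_rois,
    fit_ls,
    fit_mlewg,
    fit_stack,
    mortensen_precision,
)
from beadcal.camera import PhotoelectronStack

from conftest import PIXEL_NM, make_sim_config

A_NM = 108.0
S_NM = 130.0


def render_roi(x_px, y_px, s_px, N, b, size=11):
    """Independent pixel-integrated Gaussian renderer (erf-based)."""
    edges = np.arange(size + 1, dtype=float)

    def masses(c):
        cdf = 0.5 * (1.0 + erf((edges - c) / (s_px * math.sqrt(2.0))))
        return cdf[1:] - cdf[:-1]

    return N * np.outer(masses(y_px), masses(x_px)) + b


def make_roi(pixels, x0=0, y0=0, frame_index=0):
    return ROI(frame_index=frame_index, x0=x0, y0=y0, size=pixels.shape[0],
               pixels=pixels)


class TestDetectRois:
    def test_uniform_background_yields_nothing(self):
        rng = np.random.default_rng(3)
        frame = rng.poisson(5.0, (64, 64)).astype(float)
        assert detect_rois(frame) == []

    def test_single_spot_detected_once(self):
        rng = np.random.default_rng(4)
        frame = rng.poisson(
            render_roi(32.5, 32.5, S_NM / A_NM, 5000.0, 5.0, size=64)
        ).astype(float)
        rois = detect_rois(frame)
        assert len(rois) == 1
        r = rois[0]
        assert r.x0 <= 32 < r.x0 + r.size and r.y0 <= 32 < r.y0 + r.size

    def test_two_distant_spots_two_rois(self):
        rng = np.random.default_rng(5)
        mu = (
            render_roi(22.5, 32.5, S_NM / A_NM, 5000.0, 0.0, size=64)
            + render_roi(42.5, 32.5, S_NM / A_NM, 5000.0, 5.0, size=64)
        )
        rois = detect_rois(rng.poisson(mu).astype(float))
        assert len(rois) == 2
        (r1, r2) = rois
        # brute-force overlap rule check
        assert abs(r1.x0 - r2.x0) >= r1.size or abs(r1.y0 - r2.y0) >= r1.size

    def test_close_spots_discarded_as_overlapping(self):
        mu = (
            render_roi(28.5, 32.5, S_NM / A_NM, 5000.0, 0.0, size=64)
            + render_roi(36.5, 32.5, S_NM / A_NM, 5000.0, 5.0, size=64)
        )
        assert detect_rois(mu) == []


class TestFitLS:
    def test_noiseless_exact_recovery(self):
        truth = (5.3, 5.8, S_NM / A_NM, 4000.0, 5.0)
        fit = fit_ls(make_roi(render_roi(*truth)), A_NM)
        assert fit.converged
        assert fit.x_m == pytest.approx(truth[0] * A_NM, rel=1e-6)
        assert fit.y_m == pytest.approx(truth[1] * A_NM, rel=1e-6)
        assert fit.s_nm == pytest.approx(S_NM, rel=1e-6)
        assert fit.n_photons == pytest.approx(4000.0, rel=1e-6)
        assert fit.bg_per_pixel == pytest.approx(5.0, rel=1e-4)

    def test_centered_spot_lands_on_pixel_center(self):
        fit = fit_ls(make_roi(render_roi(5.5, 5.5, 1.2, 3000.0, 2.0)), A_NM)
        assert fit.x_m == pytest.approx(5.5 * A_NM, abs=1e-6)
        assert fit.y_m == pytest.approx(5.5 * A_NM, abs=1e-6)

    def test_all_zero_roi_flags_failure(self):
        fit = fit_ls(make_roi(np.zeros((11, 11))), A_NM)
        assert not fit.converged

    def test_poisson_noise_centroid_within_5_sigma(self):
        rng = np.random.default_rng(6)
        truth_px = (5.4, 5.6)
        mu = render_roi(*truth_px, S_NM / A_NM, 10000.0, 5.0)
        p = PrecisionInputs(n_photons=10000, s_nm=S_NM, pixel_nm=A_NM, bg_photons=5.0)
        bound = 5.0 * mortensen_precision(p)
        for _ in range(5):
            fit = fit_ls(make_roi(rng.poisson(mu).astype(float)), A_NM)
            assert abs(fit.x_m - truth_px[0] * A_NM) < bound
            assert abs(fit.y_m - truth_px[1] * A_NM) < bound


class TestFitMLE:
    def test_noiseless_self_consistency(self):
        truth = (5.2, 5.9, S_NM / A_NM, 3000.0, 5.0)
        roi = make_roi(render_roi(*truth))
        fit = fit_mlewg(roi, fit_ls(roi, A_NM), A_NM)
        assert fit.converged
        assert fit.x_m == pytest.approx(truth[0] * A_NM, rel=1e-6)
        assert fit.n_photons == pytest.approx(3000.0, rel=1e-6)

    def test_loglik_never_below_seed(self):
        rng = np.random.default_rng(7)
        mu = render_roi(5.4, 5.6, S_NM / A_NM, 3000.0, 5.0)
        for _ in range(10):
            roi = make_roi(rng.poisson(mu).astype(float))
            seed = fit_ls(roi, A_NM)
            refined = fit_mlewg(roi, seed, A_NM)
            assert refined.loglik >= seed.loglik - 1e-9

    def test_displaced_init_reaches_same_optimum(self):
        roi = make_roi(render_roi(5.4, 5.6, S_NM / A_NM, 3000.0, 5.0))
        ref = fit_mlewg(roi, fit_ls(roi, A_NM), A_NM)
        for dx, dy in [(1, 0), (-1, 0), (0, 1), (1, 1)]:
            seed = FitResult(
                x_m=(5.4 + dx) * A_NM, y_m=(5.6 + dy) * A_NM, s_nm=S_NM,
                n_photons=3000.0, bg_per_pixel=5.0, converged=True,
            )
            fit = fit_mlewg(roi, seed, A_NM)
            assert fit.x_m == pytest.approx(ref.x_m, abs=1e-3)
            assert fit.y_m == pytest.approx(ref.y_m, abs=1e-3)

    def test_unconverged_seed_rejected(self):
        roi = make_roi(render_roi(5.5, 5.5, 1.2, 3000.0, 5.0))
        bad = FitResult(0, 0, 1.0, 1.0, 0.0, converged=False)
        with pytest.raises(ValueError):
            fit_mlewg(roi, bad, A_NM)

    def test_translation_equivariance(self):
        """Shifting the spot by one pixel shifts x_m by exactly one
        pixel size."""
        base = fit_ls(make_roi(render_roi(4.4, 5.5, 1.2, 3000.0, 5.0)), A_NM)
        shifted = fit_ls(make_roi(render_roi(5.4, 5.5, 1.2, 3000.0, 5.0)), A_NM)
        assert shifted.x_m - base.x_m == pytest.approx(PIXEL_NM, abs=1e-6)
        assert shifted.y_m == pytest.approx(base.y_m, abs=1e-6)


class TestMLEVarianceAttainsBound:
    def test_centroid_variance_matches_mortensen(self):
        """Across 2000 Poisson realizations at N=3000, b^2=5, s=130 nm,
        a=108 nm, the empirical MLE centroid variance is within 10% of
        the Mortensen prediction."""
        rng = np.random.default_rng(8)
        truth = (5.35, 5.62)
        mu = render_roi(*truth, S_NM / A_NM, 3000.0, 5.0)
        devs = []
        for _ in range(2000):
            roi = make_roi(rng.poisson(mu).astype(float))
            seed = fit_ls(roi, A_NM)
            if not seed.converged:
                continue
            fit = fit_mlewg(roi, seed, A_NM)
            devs.append((fit.x_m - truth[0] * A_NM, fit.y_m - truth[1] * A_NM))
        devs = np.asarray(devs)
        emp_var = devs.var(axis=0, ddof=1).mean()  # pool x and y
        p = PrecisionInputs(n_photons=3000, s_nm=S_NM, pixel_nm=A_NM, bg_photons=5.0)
        theo_var = mortensen_precision(p) ** 2
        assert emp_var == pytest.approx(theo_var, rel=0.10)


class TestFitStack:
    def test_two_beads_all_frames(self, ideal_cam):
        from beadcal import counts_to_photoelectrons, simulate_stack

        cfg = make_sim_config(
            ideal_cam,
            beads=[(1404.0, 2592.0), (3780.0, 2592.0)],
            n_frames=100, seed=12,
        )
        stack, _ = simulate_stack(cfg)
        tracks = fit_stack(counts_to_photoelectrons(stack, ideal_cam), ideal_cam)
        assert len(tracks) == 2
        assert all(len(t.fits) == 100 for t in tracks)
        assert all(len(t.frames) == 100 for t in tracks)

    def test_vanishing_bead_dropped(self, ideal_cam):
        """A bead emitting in only half the frames fails the 90% rule."""
        from beadcal import counts_to_photoelectrons, simulate_stack

        both = make_sim_config(
            ideal_cam, beads=[(1404.0, 2592.0), (3780.0, 2592.0)],
            n_frames=100, seed=13,
        )
        only_first = make_sim_config(
            ideal_cam, beads=[(1404.0, 2592.0)], n_frames=100, seed=14,
        )
        s_both, _ = simulate_stack(both)
        s_one, _ = simulate_stack(only_first)
        spliced = np.concatenate([s_both[:50], s_one[50:]])
        tracks = fit_stack(counts_to_photoelectrons(spliced, ideal_cam), ideal_cam)
        assert len(tracks) == 1

    def test_single_frame_rejected(self, ideal_cam):
        with pytest.raises(ValueError, match="frames"):
            fit_stack(PhotoelectronStack(np.zeros((1, 32, 32))), ideal_cam)

    def test_empty_field_is_diagnosed(self, ideal_cam):
        rng = np.random.default_rng(15)
        stack = PhotoelectronStack(rng.poisson(5.0, (10, 32, 32)).astype(float))
        with pytest.raises(ValueError, match="no beads"):
            fit_stack(stack, ideal_cam)

    def test_deterministic(self, ideal_cam):
        from beadcal import counts_to_photoelectrons, simulate_stack

        cfg = make_sim_config(
            ideal_cam, beads=[(1404.0, 2592.0), (3780.0, 2592.0)],
            n_frames=60, seed=16,
        )
        stack, _ = simulate_stack(cfg)
        pe = counts_to_photoelectrons(stack, ideal_cam)
        t1 = fit_stack(pe, ideal_cam)
        t2 = fit_stack(pe, ideal_cam)
        for a, b in zip(t1, t2):
            for fa, fb in zip(a.fits, b.fits):
                assert (fa is None) == (fb is None)
                if fa is not None:
                    assert fa.x_m == fb.x_m and fa.y_m == fb.y_m
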