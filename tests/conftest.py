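"""Shared fixtures: camera configs and small simulated movies."""

import pytest

from beadcal import (
    CameraConfig,
    SimConfig,
    counts_to_photoelectrons,
    fit_stack,
    simulate_stack,
)

PIXEL_NM = 108.0
PSF_S_NM = 130.0
BG_PHOTONS = 5.0

# four beads on a square, well inside a 48x48 frame and far apart
FOUR_BEADS_NM = [(1404.0, 1404.0), (1404.0, 3780.0), (3780.0, 1404.0), (3780.0, 3780.0)]
TWO_BEADS_NM = [(1404.0, 2592.0), (3780.0, 2592.0)]


@pytest.fixture
def ideal_cam():
    return CameraConfig(
        bias=100.0, sensitivity=1.0, em_gain=1.0,
        pixel_size_nm=PIXEL_NM, noise_model="ideal",
    )


@pytest.fixture
def emccd_cam():
    return CameraConfig(
        bias=100.0, sensitivity=4.5, em_gain=300.0,
        pixel_size_nm=PIXEL_NM, noise_model="emccd",
    )


def make_sim_config(cam, beads=None, photons=3000.0, n_frames=100, seed=7,
                    drift=None, frame_shape=(48, 48)):
    return SimConfig(
        frame_shape=frame_shape,
        pixel_size_nm=cam.pixel_size_nm,
        bead_positions_nm=beads if beads is not None else FOUR_BEADS_NM,
        photons_per_bead=photons,
        psf_sigma_nm=PSF_S_NM,
        bg_photons_per_pixel=BG_PHOTONS,
        n_frames=n_frames,
        camera=cam,
        seed=seed,
        drift_nm=drift,
    )


@pytest.fixture(scope="session")
def ideal_tracks_4beads():
    """Fitted tracks of a 4-bead, 200-frame ideal-camera movie."""
    cam = CameraConfig(
        bias=100.0, sensitivity=1.0, em_gain=1.0,
        pixel_size_nm=PIXEL_NM, noise_model="ideal",
    )
    cfg = make_sim_config(cam, n_frames=200, seed=21)
    stack, _ = simulate_stack(cfg)
    pe = counts_to_photoelectrons(stack, cam)
    return fit_stack(pe, cam), cam, cfg
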