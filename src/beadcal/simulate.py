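"""Synthetic bead-movie generator with explicit sensor noise models.

Generates multi-frame movies of immobilized sub-diffraction beads with
known ground truth, emulating the acquisitions used for localization
precision calibration.  Each frame is a pixel-integrated Gaussian spot per
bead plus a constant background, in expected photoelectrons; a sensor
model then converts expectations to noisy digital counts:

``ideal``
    Shot noise only: counts = Poisson(mu) / sensitivity + bias.
``emccd``
    Electron multiplication modelled by the standard Gamma approximation
    of the gain cascade: n ~ Poisson(mu), charge ~ Gamma(shape=n,
    scale=em_gain).  At any gain the output variance is 2 mu g^2 — the
    excess noise factor of 2 that doubles localization variance.
``scmos``
    Shot noise plus per-pixel Gaussian read noise (in electrons).

An optional per-frame drift trajectory translates all beads in common
mode, which by construction leaves interbead distances unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import ndtr

from .camera import CameraConfig

__all__ = ["SimConfig", "render_expected", "apply_sensor", "simulate_stack",
           "sinusoidal_drift"]

ADC_MAX = 2**16 - 1


@dataclass
class SimConfig:
    """Full generative specification of a synthetic bead movie.

    ``bg_photons_per_pixel`` is the expected background photoelectrons per
    pixel (b^2 in the precision formulas).  ``drift_nm`` is an optional
    (n_frames, 2) common-mode (dx, dy) trajectory in nm.  ``seed`` is
    mandatory: there is no silent global randomness.
    """

    frame_shape: Tuple[int, int]
    pixel_size_nm: float
    bead_positions_nm: Sequence[Tuple[float, float]]
    photons_per_bead: float | Sequence[float]
    psf_sigma_nm: float
    bg_photons_per_pixel: float
    n_frames: int
    camera: CameraConfig
    seed: int
    drift_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bg_photons_per_pixel < 0:
            raise ValueError("bg_photons_per_pixel must be >= 0")
        self.bead_positions_nm = [tuple(map(float, p)) for p in self.bead_positions_nm]
        n_beads = len(self.bead_positions_nm)
        if np.isscalar(self.photons_per_bead):
            self.photons_per_bead = [float(self.photons_per_bead)] * n_beads
        else:
            self.photons_per_bead = [float(v) for v in self.photons_per_bead]
        if len(self.photons_per_bead) != n_beads:
            raise ValueError("photons_per_bead must be scalar or one value per bead")
        if any(v <= 0 for v in self.photons_per_bead):
            raise ValueError("photons_per_bead must be > 0")
        if self.drift_nm is not None:
            self.drift_nm = np.asarray(self.drift_nm, dtype=float)
            if self.drift_nm.shape != (self.n_frames, 2):
                raise ValueError("drift_nm must have shape (n_frames, 2)")
        H, W = self.frame_shape
        a = self.pixel_size_nm
        margin = 3.0 * self.psf_sigma_nm
        for (x, y) in self.bead_positions_nm:
            if not (margin <= x <= W * a - margin and margin <= y <= H * a - margin):
                raise ValueError(
                    f"bead at ({x:.0f}, {y:.0f}) nm is within 3 PSF sigma of the edge"
                )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cam = CameraConfig(**raw.pop("camera"))
        drift = raw.pop("drift_nm", None)
        if drift is not None:
            drift = np.asarray(drift, dtype=float)
        return cls(
            frame_shape=tuple(raw.pop("frame_shape")),
            camera=cam,
            drift_nm=drift,
            **raw,
        )

    def to_yaml(self, path) -> None:
        raw = {
            "frame_shape": list(self.frame_shape),
            "pixel_size_nm": self.pixel_size_nm,
            "bead_positions_nm": [list(p) for p in self.bead_positions_nm],
            "photons_per_bead": list(self.photons_per_bead),
            "psf_sigma_nm": self.psf_sigma_nm,
            "bg_photons_per_pixel": self.bg_photons_per_pixel,
            "n_frames": self.n_frames,
            "seed": self.seed,
            "camera": self.camera.to_dict(),
        }
        if self.drift_nm is not None:
            raw["drift_nm"] = self.drift_nm.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def sinusoidal_drift(n_frames: int, amplitude_nm: float = 20.0,
                     period_frames: float = 400.0) -> np.ndarray:
    """A smooth +/- amplitude common-mode drift trajectory fixture."""
    t = np.arange(n_frames)
    return np.stack(
        [
            amplitude_nm * np.sin(2 * np.pi * t / period_frames),
            amplitude_nm * np.cos(2 * np.pi * t / (1.3 * period_frames)),
        ],
        axis=1,
    )


def _axis_masses(center_px: float, sigma_px: float, n: int) -> np.ndarray:
    edges = np.arange(n + 1, dtype=float)
    cdf = ndtr((edges - center_px) / sigma_px)
    return cdf[1:] - cdf[:-1]


def render_expected(cfg: SimConfig, frame_index: int) -> np.ndarray:
    """Noiseless expected photoelectron image of one frame.

    mu_k = sum over beads of N x (integrated Gaussian mass in pixel k,
    positions shifted by the frame's drift) + b^2.  Deterministic.
    """
    H, W = cfg.frame_shape
    a = cfg.pixel_size_nm
    s_px = cfg.psf_sigma_nm / a
    dx = dy = 0.0
    if cfg.drift_nm is not None:
        dx, dy = cfg.drift_nm[frame_index]
    mu = np.full((H, W), float(cfg.bg_photons_per_pixel))
    margin = 3.0 * cfg.psf_sigma_nm
    for (x_nm, y_nm), n_phot in zip(cfg.bead_positions_nm, cfg.photons_per_bead):
        x, y = x_nm + dx, y_nm + dy
        if not (margin <= x <= W * a - margin and margin <= y <= H * a - margin):
            raise ValueError("bead drifted within 3 PSF sigma of the frame edge")
        ex = _axis_masses(x / a, s_px, W)
        ey = _axis_masses(y / a, s_px, H)
        mu += n_phot * np.outer(ey, ex)
    return mu


def apply_sensor(
    expected: np.ndarray, cam: CameraConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample noisy digital counts from an expected photoelectron image."""
    mu = np.asarray(expected, dtype=float)
    if np.any(mu < 0):
        raise ValueError("expected image must be >= 0")
    if cam.noise_model == "ideal":
        pe = rng.poisson(mu).astype(float)
    elif cam.noise_model == "emccd":
        n = rng.poisson(mu)
        charge = np.zeros_like(mu)
        nz = n > 0
        # Gamma(shape=n, scale=g) is the high-gain limit of the EM cascade
        charge[nz] = rng.gamma(shape=n[nz], scale=cam.em_gain)
        if np.isscalar(cam.read_noise_e):
            if cam.read_noise_e > 0:
                charge = charge + rng.normal(0.0, cam.read_noise_e, size=mu.shape)
        else:
            charge = charge + rng.normal(0.0, 1.0, size=mu.shape) * np.asarray(
                cam.read_noise_e
            )
        pe = charge
    elif cam.noise_model == "scmos":
        pe = rng.poisson(mu).astype(float)
        rn = cam.read_noise_e
        if np.isscalar(rn):
            if rn > 0:
                pe = pe + rng.normal(0.0, rn, size=mu.shape)
        else:
            pe = pe + rng.normal(0.0, 1.0, size=mu.shape) * np.asarray(rn)
    else:  # pragma: no cover - CameraConfig validates
        raise ValueError(f"unknown noise_model {cam.noise_model!r}")
    counts = pe / cam.sensitivity + cam.bias
    return counts


def simulate_stack(cfg: SimConfig):
    """Simulate a full movie: (uint16 count stack, ground-truth table).

    The truth table has one row per bead per frame with the drift-shifted
    true position, true N, s and background.  Fully reproducible from
    ``cfg.seed``; counts are rounded and clipped to the 16-bit range on
    output while the truth is stored pre-rounding.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.frame_shape
    stack = np.empty((cfg.n_frames, H, W), dtype=np.uint16)
    rows = []
    for t in range(cfg.n_frames):
        mu = render_expected(cfg, t)
        counts = apply_sensor(mu, cfg.camera, rng)
        stack[t] = np.clip(np.rint(counts), 0, ADC_MAX).astype(np.uint16)
        dx = dy = 0.0
        if cfg.drift_nm is not None:
            dx, dy = cfg.drift_nm[t]
        for b, (x, y) in enumerate(cfg.bead_positions_nm):
            rows.append(
                {
                    "frame": t,
                    "bead_id": b,
                    "x_nm": x + dx,
                    "y_nm": y + dy,
                    "n_photons": cfg.photons_per_bead[b],
                    "s_nm": cfg.psf_sigma_nm,
                    "bg_photons_per_pixel": cfg.bg_photons_per_pixel,
                }
            )
    truth = pd.DataFrame(rows)
    return stack, truth


def write_simulation(cfg: SimConfig, out_dir) -> dict:
    """Simulate and write stack.tif, truth.csv and the echoed config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth = simulate_stack(cfg)
    paths = {
        "stack": out / "stack.tif",
        "truth": out / "truth.csv",
        "config": out / "sim_config.yaml",
    }
    tifffile.imwrite(paths["stack"], stack)
    truth.to_csv(paths["truth"], index=False)
    cfg.to_yaml(paths["config"])
    return paths
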