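"""Camera model: counts <-> photoelectrons and photon-transfer calibration.

A camera sensor reports digital counts.  The localization formulas work in
photoelectrons, so every analysis starts by inverting the sensor's affine
response

    counts = photoelectrons * em_gain / sensitivity + bias

where *sensitivity* is in photoelectrons per count, *em_gain* is the
electron-multiplication factor (1 when disabled) and *bias* is the dark
offset.  The calibration constants themselves can be measured from a
photon-transfer series (flat fields at several illumination levels): in the
shot-noise-limited regime the temporal variance of a pixel is proportional
to its mean signal, with slope 1/sensitivity in count units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "CameraConfig",
    "PhotoelectronStack",
    "CalibrationError",
    "counts_to_photoelectrons",
    "photon_transfer_calibrate",
]

NOISE_MODELS = ("ideal", "emccd", "scmos")

#: full-scale value of the 16-bit sensors handled here
ADC_FULL_SCALE = 2**16 - 1


@dataclass
class CameraConfig:
    """Sensor calibration constants and noise-model selector.

    Parameters
    ----------
    bias : float
        Dark offset in counts (>= 0).
    sensitivity : float
        Photoelectrons per count (> 0).
    em_gain : float
        Electron-multiplication factor; 1 disables EM amplification.
    pixel_size_nm : float
        Pixel size at the sample plane, in nm (symbol *a*).
    noise_model : {"ideal", "emccd", "scmos"}
        Which stochastic sensor model applies.
    read_noise_e : float or ndarray
        RMS read noise per pixel in photoelectrons; a scalar, or a
        per-pixel map for the sCMOS model.
    """

    bias: float
    sensitivity: float
    em_gain: float = 1.0
    pixel_size_nm: float = 100.0
    noise_model: str = "ideal"
    read_noise_e: Union[float, np.ndarray] = 0.0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.bias < 0:
            raise ValueError("bias must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise_model {self.noise_model!r}; "
                f"expected one of {NOISE_MODELS}"
            )

    @classmethod
    def from_yaml(cls, path) -> "CameraConfig":
        """Load a camera configuration from a YAML file.

        Required keys: ``bias``, ``sensitivity``.  Optional:
        ``em_gain``, ``pixel_size_nm``, ``noise_model``, ``read_noise_e``.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"camera config {path} is not a mapping")
        for key in ("bias", "sensitivity"):
            if key not in raw:
                raise ValueError(f"camera config missing required key {key!r}")
        known = {
            "bias", "sensitivity", "em_gain", "pixel_size_nm",
            "noise_model", "read_noise_e",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown camera config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        rn = self.read_noise_e
        return {
            "bias": float(self.bias),
            "sensitivity": float(self.sensitivity),
            "em_gain": float(self.em_gain),
            "pixel_size_nm": float(self.pixel_size_nm),
            "noise_model": self.noise_model,
            "read_noise_e": rn.tolist() if isinstance(rn, np.ndarray) else float(rn),
        }


@dataclass
class PhotoelectronStack:
    """Frames in photoelectron units.

    A thin wrapper whose type *is* the unit flag: passing one back through
    :func:`counts_to_photoelectrons` is a detectable double conversion.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("expected a (frames, H, W) stack or single frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]


class CalibrationError(RuntimeError):
    """Photon-transfer calibration failed; carries any partial result."""

    def __init__(self, message: str, bias: float | None = None):
        super().__init__(message)
        self.bias = bias


def counts_to_photoelectrons(stack, cam: CameraConfig) -> PhotoelectronStack:
    """Convert raw count frames to photoelectrons.

    Each pixel maps to ``(p - bias) * sensitivity / em_gain``; values that
    fall below zero after bias subtraction are clamped to zero so the
    result is a valid intensity for Poisson-likelihood fitting.

    Raises
    ------
    TypeError
        If *stack* is already a :class:`PhotoelectronStack`.
    ValueError
        If the stack contains non-finite pixels or is empty.
    """
    if isinstance(stack, PhotoelectronStack):
        raise TypeError("stack is already in photoelectron units (double conversion)")
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("stack must have >= 1 frame of 2D data")
    if not np.all(np.isfinite(arr)):
        raise ValueError("stack contains non-finite pixels")
    pe = (arr - cam.bias) * cam.sensitivity / cam.em_gain
    np.clip(pe, 0.0, None, out=pe)
    return PhotoelectronStack(pe)


@dataclass
class PhotonTransferResult:
    """Sensitivity/bias estimates from a photon-transfer (mean-variance) series."""

    sensitivity: float
    sensitivity_stderr: float
    bias: float
    bias_stderr: float
    n_levels_used: int
    levels_mean: np.ndarray = field(repr=False)
    levels_var: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "sensitivity_stderr": self.sensitivity_stderr,
            "bias": self.bias,
            "bias_stderr": self.bias_stderr,
            "n_levels_used": self.n_levels_used,
        }


def photon_transfer_calibrate(
    flat_series: Sequence[np.ndarray],
) -> PhotonTransferResult:
    """Estimate sensitivity and bias from flat-field series.

    Parameters
    ----------
    flat_series : sequence of ndarray
        One ``(n_frames, H, W)`` stack per illumination level, in counts.
        The level with the lowest mean is treated as the dark series; at
        least 3 distinct levels with >= 2 frames each are required.

    Returns
    -------
    PhotonTransferResult
        ``bias`` is the mean of the dark frames; ``sensitivity`` is the
        reciprocal slope of the temporal-variance-versus-mean regression
        over levels in the shot-noise-limited window (mean more than 10
        dark standard deviations above bias, below 95% of full scale).
    """
    stacks = [np.asarray(s, dtype=float) for s in flat_series]
    if len(stacks) < 3:
        raise CalibrationError(
            f"need >= 3 illumination levels, got {len(stacks)}",
            bias=float(stacks[np.argmin([s.mean() for s in stacks])].mean())
            if stacks else None,
        )
    for s in stacks:
        if s.ndim != 3 or s.shape[0] < 2:
            raise CalibrationError("each level needs >= 2 frames of 2D data")

    means = np.array([s.mean() for s in stacks])
    # per-level mean of the per-pixel temporal variance
    variances = np.array([s.var(axis=0, ddof=1).mean() for s in stacks])

    i_dark = int(np.argmin(means))
    dark = stacks[i_dark]
    bias = float(dark.mean())
    dark_std = float(dark.std(ddof=1))
    n_dark = dark.size
    bias_stderr = dark_std / np.sqrt(n_dark) if n_dark > 1 else 0.0

    if np.ptp(means) == 0:
        raise CalibrationError(
            "all illumination levels have identical mean (zero dynamic range)",
            bias=bias,
        )

    window = (means > bias + 10.0 * dark_std) & (means < 0.95 * ADC_FULL_SCALE)
    if window.sum() < 2:
        raise CalibrationError(
            "fewer than 2 illumination levels in the shot-noise window; "
            "sensitivity undefined",
            bias=bias,
        )

    reg = stats.linregress(means[window], variances[window])
    if reg.slope <= 0:
        raise CalibrationError(
            f"non-positive variance-vs-mean slope ({reg.slope:.4g}); "
            "input is not shot-noise limited",
            bias=bias,
        )
    sensitivity = 1.0 / reg.slope
    # delta method: se(1/m) = se(m) / m^2
    sens_stderr = float(reg.stderr / reg.slope**2) if reg.stderr is not None else np.nan
    return PhotonTransferResult(
        sensitivity=float(sensitivity),
        sensitivity_stderr=sens_stderr,
        bias=bias,
        bias_stderr=float(bias_stderr),
        n_levels_used=int(window.sum()),
        levels_mean=means,
        levels_var=variances,
    )
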