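"""Bead detection and 2D Gaussian PSF fitting.

Spots are modelled as a pixel-integrated symmetric 2D Gaussian plus a
constant background: the expected signal in pixel (i, j) is

    mu_ij = N * Ey_i(y, s) * Ex_j(x, s) + b

where Ex_j = Phi((j+1-x)/s) - Phi((j-x)/s) is the Gaussian mass falling
into the pixel's x-extent (Phi the standard normal CDF), matching the
camera's integration over each pixel rather than sampling the Gaussian at
pixel centers.  Pixel (i, j) spans [j, j+1) x [i, i+1) in pixel units (x
along columns, y along rows, 0-based), so a pixel's center is at +0.5.

Each spot is fitted twice: a fast least-squares fit seeded from image
moments, then a Poisson maximum-likelihood refinement (MLEwG) seeded from
the least-squares optimum.  The MLE maximizes sum_k [c_k ln mu_k - mu_k]
and, on shot-noise-limited data, attains the Cramér-Rao bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import ndtr  # standard normal CDF, vectorized
from skimage.feature import peak_local_max

from .camera import CameraConfig, PhotoelectronStack

__all__ = [
    "ROI",
    "FitResult",
    "BeadTrack",
    "FitSettings",
    "detect_rois",
    "fit_ls",
    "fit_mlewg",
    "fit_stack",
]

log = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class ROI:
    """A square region of interest around one candidate spot.

    ``x0``/``y0`` are the integer pixel origin (column/row) of the box in
    the full frame; the box is half-open, covering ``size`` pixels.
    """

    frame_index: int
    x0: int
    y0: int
    size: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.size < 5 or self.size % 2 == 0:
            raise ValueError("ROI size must be odd and >= 5")
        if self.pixels.shape != (self.size, self.size):
            raise ValueError("pixels must be a (size, size) array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("ROI pixels must be finite and >= 0")


@dataclass
class FitResult:
    """One spot's fitted parameters, in physical units.

    ``x_m``/``y_m`` are the centroid in nm in global frame coordinates,
    ``s_nm`` the fitted PSF standard deviation, ``n_photons`` the total
    signal in photoelectrons and ``bg_per_pixel`` the constant background
    per pixel in photoelectrons.
    """

    x_m: float
    y_m: float
    s_nm: float
    n_photons: float
    bg_per_pixel: float
    converged: bool
    loglik: float = np.nan
    method: str = ""


@dataclass
class BeadTrack:
    """One bead's fits linked across the frames of a movie."""

    bead_id: int
    fits: List[Optional[FitResult]]
    n_missing: int = 0

    @property
    def frames(self) -> np.ndarray:
        """Indices of frames with a converged fit."""
        return np.array(
            [i for i, f in enumerate(self.fits) if f is not None and f.converged],
            dtype=int,
        )


@dataclass
class FitSettings:
    """Detection and fitting settings for :func:`fit_stack`."""

    roi_size: int = 11
    threshold_k: float = 5.0
    min_fit_fraction: float = 0.9
    #: fits with less total signal than this are treated as failed
    #: (a bead that vanished leaves only background)
    min_signal_photons: float = 100.0


# ---------------------------------------------------------------------------
# pixel-integrated Gaussian model and derivatives


def _edge_masses(center: float, s: float, n: int):
    """Per-pixel Gaussian masses along one axis and their derivatives.

    Returns (E, dE/dcenter, dE/ds), each of length n, for pixels [k, k+1).
    """
    edges = np.arange(n + 1, dtype=float)
    u = (edges - center) / s
    cdf = ndtr(u)
    pdf = np.exp(-0.5 * u * u) / _SQRT2PI
    E = cdf[1:] - cdf[:-1]
    dE_dc = (pdf[:-1] - pdf[1:]) / s
    dE_ds = (pdf[:-1] * u[:-1] - pdf[1:] * u[1:]) / s
    return E, dE_dc, dE_ds


def _model_and_jac(params: np.ndarray, n: int, with_jac: bool = True):
    """Expected image mu (n x n) and d(mu)/d(x, y, s, N, b)."""
    x, y, s, N, b = params
    Ex, dEx_dx, dEx_ds = _edge_masses(x, s, n)
    Ey, dEy_dy, dEy_ds = _edge_masses(y, s, n)
    P = np.outer(Ey, Ex)
    mu = N * P + b
    if not with_jac:
        return mu, None
    jac = np.empty((5, n, n))
    jac[0] = N * np.outer(Ey, dEx_dx)
    jac[1] = N * np.outer(dEy_dy, Ex)
    jac[2] = N * (np.outer(dEy_ds, Ex) + np.outer(Ey, dEx_ds))
    jac[3] = P
    jac[4] = 1.0
    return mu, jac


def _moments_init(pixels: np.ndarray) -> np.ndarray:
    """Moment-based starting values (x, y, s, N, b) in pixel units."""
    n = pixels.shape[0]
    b0 = float(pixels.min())
    signal = pixels - b0
    total = float(signal.sum())
    if total <= 0:
        return np.array([n / 2, n / 2, 1.0, 0.0, b0])
    centers = np.arange(n) + 0.5
    x0 = float((signal.sum(axis=0) * centers).sum() / total)
    y0 = float((signal.sum(axis=1) * centers).sum() / total)
    vx = float((signal.sum(axis=0) * (centers - x0) ** 2).sum() / total)
    vy = float((signal.sum(axis=1) * (centers - y0) ** 2).sum() / total)
    s0 = np.sqrt(max((vx + vy) / 2.0, 0.25))
    s0 = float(np.clip(s0, 0.5, n / 2.0))
    return np.array([x0, y0, s0, total, b0])


def _bounds(n: int):
    lo = np.array([0.0, 0.0, 0.2, 1e-6, 0.0])
    hi = np.array([float(n), float(n), float(n), np.inf, np.inf])
    return lo, hi


def _poisson_loglik(params: np.ndarray, data: np.ndarray) -> float:
    """sum_k [c_k ln mu_k - mu_k] under the pixel-integrated model."""
    mu, _ = _model_and_jac(params, data.shape[0], with_jac=False)
    mu = np.maximum(mu, 1e-12)
    return float(np.sum(data * np.log(mu) - mu))


def _to_global(params: np.ndarray, roi: ROI, pixel_size_nm: float, **kw) -> FitResult:
    x, y, s, N, b = params
    return FitResult(
        x_m=(roi.x0 + x) * pixel_size_nm,
        y_m=(roi.y0 + y) * pixel_size_nm,
        s_nm=s * pixel_size_nm,
        n_photons=N,
        bg_per_pixel=b,
        **kw,
    )


def _to_local(fit: FitResult, roi: ROI, pixel_size_nm: float) -> np.ndarray:
    return np.array(
        [
            fit.x_m / pixel_size_nm - roi.x0,
            fit.y_m / pixel_size_nm - roi.y0,
            fit.s_nm / pixel_size_nm,
            fit.n_photons,
            fit.bg_per_pixel,
        ]
    )


# ---------------------------------------------------------------------------
# detection


def detect_rois(
    frame: np.ndarray, threshold_k: float = 5.0, roi_size: int = 11
) -> List[ROI]:
    """Find candidate spots in a single photoelectron image.

    Candidates are local maxima exceeding ``median + threshold_k * robust
    std`` (robust std = 1.4826 x MAD).  ROIs clipped by the frame border
    are discarded, as are *both* members of any overlapping pair (ambiguous
    multi-spot boxes would corrupt single-emitter fits).  The result is
    ordered by (y, x).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if roi_size % 2 == 0 or roi_size < 5:
        raise ValueError("roi_size must be odd and >= 5")
    med = np.median(frame)
    robust_std = 1.4826 * np.median(np.abs(frame - med))
    if robust_std == 0.0:
        # temporal-median images of quantized counts can be exactly flat in
        # the background; fall back to the spread of the dimmest 80% of
        # pixels (background-dominated for sparse fields)
        lower = frame[frame <= np.percentile(frame, 80)]
        robust_std = float(lower.std())
    threshold = med + threshold_k * robust_std
    half = roi_size // 2
    peaks = peak_local_max(
        frame,
        min_distance=half,
        threshold_abs=threshold,
        exclude_border=False,
    )
    boxes = []
    H, W = frame.shape
    for (py, px) in peaks:
        y0, x0 = py - half, px - half
        if y0 < 0 or x0 < 0 or y0 + roi_size > H or x0 + roi_size > W:
            continue  # clipped by the border
        boxes.append((int(y0), int(x0)))
    # drop every box that overlaps another
    keep = []
    for i, (yi, xi) in enumerate(boxes):
        overlapping = any(
            abs(yi - yj) < roi_size and abs(xi - xj) < roi_size
            for j, (yj, xj) in enumerate(boxes)
            if j != i
        )
        if not overlapping:
            keep.append((yi, xi))
    keep.sort()
    return [
        ROI(
            frame_index=0,
            x0=x0,
            y0=y0,
            size=roi_size,
            pixels=frame[y0 : y0 + roi_size, x0 : x0 + roi_size],
        )
        for (y0, x0) in keep
    ]


# ---------------------------------------------------------------------------
# fitting


def fit_ls(roi: ROI, pixel_size_nm: float) -> FitResult:
    """Least-squares fit of the pixel-integrated Gaussian to one ROI.

    Starting values come from image moments.  Optimizer failure is
    reported through ``converged=False``, never raised.
    """
    n = roi.size
    data = roi.pixels
    p0 = _moments_init(data)
    if p0[3] <= 0:
        return _to_global(p0, roi, pixel_size_nm, converged=False, method="ls")
    lo, hi = _bounds(n)
    p0 = np.clip(p0, lo + 1e-9, None)

    def resid(p):
        mu, _ = _model_and_jac(p, n, with_jac=False)
        return (mu - data).ravel()

    def jac(p):
        _, J = _model_and_jac(p, n, with_jac=True)
        return J.reshape(5, -1).T

    try:
        sol = least_squares(
            resid, p0, jac=jac, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=500,
        )
        ok = sol.success and sol.x[3] > 0 and sol.x[2] > 0
    except Exception:  # pragma: no cover - defensive
        return _to_global(p0, roi, pixel_size_nm, converged=False, method="ls")
    params = sol.x if ok else p0
    return _to_global(
        params,
        roi,
        pixel_size_nm,
        converged=bool(ok),
        loglik=_poisson_loglik(params, data),
        method="ls",
    )


def fit_mlewg(roi: ROI, init: FitResult, pixel_size_nm: float) -> FitResult:
    """Poisson maximum-likelihood refinement (MLEwG) of a seeded fit.

    Maximizes sum_k [c_k ln mu_k - mu_k].  The returned fit never has a
    lower likelihood than the seed evaluated under the same model: if the
    optimizer ends below the seed, the seed parameters are kept.
    """
    if not init.converged:
        raise ValueError("MLE requires a converged least-squares seed")
    n = roi.size
    data = roi.pixels
    p0 = _to_local(init, roi, pixel_size_nm)
    lo, hi = _bounds(n)
    lo[4] = 1e-9  # keep mu > 0 where the Gaussian tail underflows
    p0 = np.clip(p0, lo + 1e-12, None)

    def negloglik_and_grad(p):
        mu, J = _model_and_jac(p, n, with_jac=True)
        mu = np.maximum(mu, 1e-12)
        f = float(np.sum(mu - data * np.log(mu)))
        w = 1.0 - data / mu
        g = np.array([np.sum(w * J[k]) for k in range(5)])
        return f, g

    seed_ll = _poisson_loglik(p0, data)
    try:
        sol = minimize(
            negloglik_and_grad,
            p0,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        params, ll = sol.x, -float(sol.fun)
        ok = np.isfinite(ll)
    except Exception:
        params, ll, ok = p0, seed_ll, False
    if not ok:
        return _to_global(
            p0, roi, pixel_size_nm, converged=False, loglik=seed_ll, method="mlewg"
        )
    if ll < seed_ll:  # optimizer wandered; seed is the better MLE iterate
        params, ll = p0, seed_ll
    return _to_global(
        params, roi, pixel_size_nm, converged=True, loglik=ll, method="mlewg"
    )


def fit_stack(
    stack: PhotoelectronStack,
    cam: CameraConfig,
    settings: FitSettings | None = None,
) -> List[BeadTrack]:
    """Detect beads on the temporal median image and fit every frame.

    Detection runs once, on the median over frames (the beads are
    immobilized, so ROI positions are stable and pair identity is fixed by
    construction).  Every ROI is then fitted in every frame, least squares
    seeding maximum likelihood.  Tracks with fewer than
    ``min_fit_fraction`` successful fits are dropped.
    """
    settings = settings or FitSettings()
    if not isinstance(stack, PhotoelectronStack):
        stack = PhotoelectronStack(np.asarray(stack, dtype=float))
    if stack.n_frames < 2:
        raise ValueError("fit_stack needs >= 2 frames")
    median_img = np.median(stack.data, axis=0)
    rois = detect_rois(median_img, settings.threshold_k, settings.roi_size)
    if not rois:
        raise ValueError("no beads detected on the temporal median image")
    log.info("detected %d ROIs on the temporal median image", len(rois))

    n_frames = stack.n_frames
    a = cam.pixel_size_nm
    tracks: List[BeadTrack] = []
    for bead_id, roi in enumerate(rois):
        fits: List[Optional[FitResult]] = []
        n_missing = 0
        for t in range(n_frames):
            pix = stack.data[t, roi.y0 : roi.y0 + roi.size, roi.x0 : roi.x0 + roi.size]
            frame_roi = ROI(
                frame_index=t, x0=roi.x0, y0=roi.y0, size=roi.size, pixels=pix
            )
            ls = fit_ls(frame_roi, a)
            fit = fit_mlewg(frame_roi, ls, a) if ls.converged else ls
            if (
                not fit.converged
                or fit.n_photons < settings.min_signal_photons
                or fit.s_nm <= 0
            ):
                fits.append(None)
                n_missing += 1
            else:
                fits.append(fit)
        track = BeadTrack(bead_id=bead_id, fits=fits, n_missing=n_missing)
        frac = (n_frames - n_missing) / n_frames
        if frac < settings.min_fit_fraction:
            log.info(
                "dropping bead %d: only %.0f%% of frames fitted",
                bead_id,
                100 * frac,
            )
            continue
        tracks.append(track)
    log.info("fitted %d beads across %d frames", len(tracks), n_frames)
    return tracks
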