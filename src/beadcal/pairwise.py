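"""Pairwise distance analysis: sigma_exp, sigma_theo and their ratio.

The experimental localization precision of a microscope is measured
software-independently from repeated distances between pairs of
immobilized beads: the interbead distance is invariant under the
common-mode drift that all beads share, so its frame-to-frame spread
reflects pure localization error.  For each unordered pair, sigma_exp is
the spread of the distance series (a Gaussian is also fitted to the
distance histogram as a cross-check) and sigma_theo is the quadrature sum
of the two beads' per-axis formula precisions, each averaged over frames.
The per-setup calibration factor is the ratio sigma_exp / sigma_theo.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .camera import CameraConfig
from .fitting import BeadTrack
from .precision import (
    PrecisionInputs,
    mortensen_precision,
    pair_sigma_theo,
    thompson_precision,
)

__all__ = [
    "PairResult",
    "RatioReport",
    "GaussianFitDiagnostics",
    "distance_series",
    "sigma_exp",
    "build_pair_results",
]

log = logging.getLogger(__name__)

ESTIMATORS = ("thompson", "mortensen")

#: minimum number of common converged frames for a usable pair
MIN_COMMON_FRAMES = 50


@dataclass
class GaussianFitDiagnostics:
    """Health of the Gaussian fit to a distance histogram."""

    sigma_gauss_nm: float
    mu_gauss_nm: float
    n_bins: int
    healthy: bool
    degenerate: bool = False


@dataclass
class PairResult:
    """One bead pair's distance series and precision comparison."""

    bead_ids: tuple
    distances_nm: np.ndarray = field(repr=False)
    mean_distance_nm: float = 0.0
    sigma_exp_nm: float = 0.0  # Gaussian-fit std of the histogram
    sigma_exp_sample_nm: float = 0.0  # plain sample std
    sigma_theo_nm: float = 0.0
    ratio: float = np.nan
    n_frames_used: int = 0
    fit_healthy: bool = True


@dataclass
class RatioReport:
    """All pairs of a movie plus the summary calibration numbers."""

    pairs: List[PairResult]
    mean_ratio: float
    std_ratio: float
    linear_slope: float
    estimator_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bead_i": [p.bead_ids[0] for p in self.pairs],
                "bead_j": [p.bead_ids[1] for p in self.pairs],
                "mean_distance_nm": [p.mean_distance_nm for p in self.pairs],
                "sigma_exp_nm": [p.sigma_exp_nm for p in self.pairs],
                "sigma_exp_sample_nm": [p.sigma_exp_sample_nm for p in self.pairs],
                "sigma_theo_nm": [p.sigma_theo_nm for p in self.pairs],
                "ratio": [p.ratio for p in self.pairs],
                "n_frames_used": [p.n_frames_used for p in self.pairs],
            }
        )

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "std_ratio": self.std_ratio,
            "linear_slope": self.linear_slope,
            "estimator_name": self.estimator_name,
            "n_pairs": len(self.pairs),
        }


def distance_series(trackA: BeadTrack, trackB: BeadTrack) -> np.ndarray:
    """Per-frame Euclidean interbead distance (nm) over common frames.

    Frames where either bead lacks a converged fit are omitted.  Because
    any drift is shared by both beads, this series is unaffected by it.
    """
    framesA = set(trackA.frames.tolist())
    framesB = set(trackB.frames.tolist())
    common = sorted(framesA & framesB)
    if len(common) < MIN_COMMON_FRAMES:
        raise ValueError(
            f"pair ({trackA.bead_id}, {trackB.bead_id}): only {len(common)} "
            f"common converged frames (< {MIN_COMMON_FRAMES})"
        )
    d = np.empty(len(common))
    for k, t in enumerate(common):
        fa, fb = trackA.fits[t], trackB.fits[t]
        d[k] = math.hypot(fa.x_m - fb.x_m, fa.y_m - fb.y_m)
    return d


def _freedman_diaconis_bins(x: np.ndarray, minimum: int = 10) -> int:
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0:
        return minimum
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    n = int(np.ceil(np.ptp(x) / width)) if width > 0 else minimum
    return max(n, minimum)


def sigma_exp(
    distances: np.ndarray, n_bins: int | None = None
) -> tuple:
    """Experimental precision of a distance series.

    Fits a Gaussian to the distance histogram by least squares on the bin
    counts and returns ``(sigma_gauss, sigma_sample, diagnostics)``.  The
    fit is flagged healthy only when the Gaussian std and the plain sample
    std agree within 15% — a mismatch signals a non-Gaussian series
    (e.g., a bimodal one).  A zero-variance series returns 0 with a
    degeneracy flag.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < MIN_COMMON_FRAMES:
        raise ValueError(f"need >= {MIN_COMMON_FRAMES} distances, got {x.size}")
    s_sample = float(x.std(ddof=1))
    if s_sample == 0.0:
        diag = GaussianFitDiagnostics(0.0, float(x[0]), 0, healthy=True, degenerate=True)
        return 0.0, 0.0, diag
    if n_bins is None:
        n_bins = _freedman_diaconis_bins(x)
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, A, mu, sig):
        return A * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    p0 = [counts.max(), float(x.mean()), s_sample]
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=5000)
        s_gauss = abs(float(popt[2]))
        mu_gauss = float(popt[1])
        healthy = abs(s_gauss - s_sample) <= 0.15 * s_sample
    except RuntimeError:
        s_gauss, mu_gauss, healthy = s_sample, float(x.mean()), False
    diag = GaussianFitDiagnostics(
        sigma_gauss_nm=s_gauss,
        mu_gauss_nm=mu_gauss,
        n_bins=n_bins,
        healthy=healthy,
    )
    return s_gauss, s_sample, diag


def _track_sigma_theo(
    track: BeadTrack, cam: CameraConfig, estimator: str
) -> float:
    """Per-axis formula precision of one bead, averaged over its frames."""
    func = thompson_precision if estimator == "thompson" else mortensen_precision
    sigmas = []
    for f in track.fits:
        if f is None or not f.converged:
            continue
        p = PrecisionInputs(
            n_photons=f.n_photons,
            s_nm=f.s_nm,
            pixel_nm=cam.pixel_size_nm,
            bg_photons=max(f.bg_per_pixel, 0.0),
        )
        sigmas.append(func(p))
    return float(np.mean(sigmas))


def build_pair_results(
    tracks: Sequence[BeadTrack],
    cam: CameraConfig,
    estimator: str = "mortensen",
) -> RatioReport:
    """Analyse every unordered bead pair and summarize the ratio.

    The ratio reported per pair is ``sigma_exp_sample / sigma_theo`` (the
    binning-free sample std; the Gaussian-fit value is carried alongside
    as a cross-check).  ``linear_slope`` is the least-squares slope of
    sigma_exp versus sigma_theo constrained through the origin.  Pairs
    with too few common frames are skipped with a warning.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if len(tracks) < 2:
        raise ValueError("need >= 2 bead tracks")
    per_bead_sigma = {
        t.bead_id: _track_sigma_theo(t, cam, estimator) for t in tracks
    }
    pairs: List[PairResult] = []
    for ta, tb in itertools.combinations(tracks, 2):
        try:
            d = distance_series(ta, tb)
        except ValueError as exc:
            log.warning("skipping pair: %s", exc)
            continue
        s_gauss, s_sample, diag = sigma_exp(d)
        s_theo = pair_sigma_theo(per_bead_sigma[ta.bead_id], per_bead_sigma[tb.bead_id])
        pairs.append(
            PairResult(
                bead_ids=(ta.bead_id, tb.bead_id),
                distances_nm=d,
                mean_distance_nm=float(d.mean()),
                sigma_exp_nm=s_gauss,
                sigma_exp_sample_nm=s_sample,
                sigma_theo_nm=s_theo,
                ratio=s_sample / s_theo if s_theo > 0 else np.nan,
                n_frames_used=int(d.size),
                fit_healthy=diag.healthy,
            )
        )
    if not pairs:
        raise ValueError("no usable bead pairs")
    ratios = np.array([p.ratio for p in pairs])
    se = np.array([p.sigma_exp_sample_nm for p in pairs])
    st = np.array([p.sigma_theo_nm for p in pairs])
    slope = float(np.sum(se * st) / np.sum(st * st))
    report = RatioReport(
        pairs=pairs,
        mean_ratio=float(ratios.mean()),
        std_ratio=float(ratios.std(ddof=1)) if len(pairs) > 1 else 0.0,
        linear_slope=slope,
        estimator_name=estimator,
    )
    log.info(
        "analysed %d pairs: mean sigma_exp/sigma_theo = %.3f (slope %.3f)",
        len(pairs),
        report.mean_ratio,
        report.linear_slope,
    )
    return report
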