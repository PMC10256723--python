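"""Forecast evaluation: structural similarity (SSIM) and success criteria.

SSIM compares two images through local luminance, contrast and structure
statistics computed under a Gaussian window (sigma = 1.5, 11 x 11 support,
stabilizing constants K1 = 0.01, K2 = 0.03 — the standard choices):

    SSIM(x, y) = mean over windows of
        (2 mu_x mu_y + C1)(2 cov_xy + C2) / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

with C1 = (K1 L)^2, C2 = (K2 L)^2 and L the dynamic range.  Forecasts are
produced (and evaluated) in mean-subtracted frame space, so the dynamic
range is taken from the joint data range of the two images by default.

A movie-level "total SSIM" (default: mean of the per-frame values) scores a
whole forecast; a forecast counts as successful when the total is at least
0.9.  A noise-calibrated floor — the total SSIM between a movie and a
noise-corrupted copy of itself — provides the failure threshold used for
ablation controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stimuli import Movie

__all__ = [
    "ssim",
    "total_ssim",
    "per_frame_ssim",
    "smooth_curve",
    "calibrate_threshold",
    "is_success",
    "ForecastScore",
    "score_forecast",
    "SUCCESS_THRESHOLD",
]

SUCCESS_THRESHOLD = 0.9

# Gaussian window of sigma 1.5 truncated at 3.5 sigma -> 11 x 11 support,
# matching the window of the original SSIM reference.
_SIGMA = 1.5
_TRUNCATE = 3.5


def _joint_range(a: np.ndarray, b: np.ndarray) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    return float(hi - lo)


def ssim(
    img_a: np.ndarray,
    img_b: np.ndarray,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = _SIGMA,
    data_range: float | None = None,
) -> float:
    """Structural similarity index between two equal-shape grayscale images.

    ``data_range`` defaults to the joint max - min of both images (the images
    here live in centered, data-dependent units).  Returns a value in
    [-1, 1]; identical images give exactly 1.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if data_range is None:
        data_range = _joint_range(a, b)
    if data_range == 0:  # two identical constant images
        return 1.0
    C1 = (k1 * data_range) ** 2
    C2 = (k2 * data_range) ** 2

    def f(img):
        return gaussian_filter(img, sigma, mode="reflect", truncate=_TRUNCATE)

    mu_a, mu_b = f(a), f(b)
    var_a = f(a * a) - mu_a**2
    var_b = f(b * b) - mu_b**2
    cov = f(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + C1) * (2 * cov + C2)) / (
        (mu_a**2 + mu_b**2 + C1) * (var_a + var_b + C2)
    )
    # crop the filter's support radius so padded borders don't contribute
    pad = int(_TRUNCATE * sigma + 0.5)
    core = s[tuple(slice(pad, dim - pad) for dim in s.shape)]
    if core.size == 0:
        core = s
    return float(core.mean())


def per_frame_ssim(movie_a: Movie, movie_b: Movie, **kwargs) -> np.ndarray:
    """SSIM of each frame pair of two equal-length movies."""
    if len(movie_a) != len(movie_b):
        raise ValueError("movies must have equal length")
    return np.array(
        [ssim(fa, fb, **kwargs) for fa, fb in zip(movie_a.frames, movie_b.frames)]
    )


def total_ssim(movie_a: Movie, movie_b: Movie, mode: str = "mean", **kwargs) -> float:
    """Single SSIM for a whole movie.

    mode="mean": mean of the per-frame SSIM values (default).
    mode="global": frames of each movie concatenated along rows into one tall
    image, scored with a single SSIM.
    """
    if len(movie_a) != len(movie_b):
        raise ValueError("movies must have equal length")
    if mode == "mean":
        return float(per_frame_ssim(movie_a, movie_b, **kwargs).mean())
    if mode == "global":
        a = movie_a.frames.reshape(-1, movie_a.frame_shape[1])
        b = movie_b.frames.reshape(-1, movie_b.frame_shape[1])
        return ssim(a, b, **kwargs)
    raise ValueError(f"unknown mode {mode!r}")


def smooth_curve(series, width: int = 30):
    """Centered moving average with edge truncation, plus its error band.

    Returns ``(smoothed, band)`` where ``band = |smoothed - series|``.  At the
    edges the window is truncated to the available samples; width = 1 is the
    identity.
    """
    s = np.asarray(series, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    if width == 1:
        return s.copy(), np.zeros_like(s)
    n = s.size
    left = (width - 1) // 2
    right = width // 2
    csum = np.concatenate([[0.0], np.cumsum(s)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return smoothed, np.abs(smoothed - s)


def corrupt_with_noise(movie: Movie, rel_sigma: float, seed=None) -> Movie:
    """Add white Gaussian noise of std ``rel_sigma`` x the movie's frame std."""
    rng = np.random.default_rng(seed)
    scale = rel_sigma * float(movie.frames.std())
    return Movie(movie.frames + rng.normal(0.0, scale, size=movie.frames.shape))


def calibrate_threshold(
    movie: Movie,
    noise_levels=(0.25, 0.5, 1.0),
    seed=None,
    reference_level: float | None = None,
    full: bool = False,
):
    """Total SSIM of a movie against noise-corrupted copies of itself.

    ``noise_levels`` are noise standard deviations relative to the movie's
    own frame std.  Returns the total SSIM at the reference corruption
    (default: the largest level) — the failure floor for forecasts; with
    ``full=True`` returns the whole (level, total SSIM) curve instead.
    Deterministic under ``seed``.
    """
    levels = list(noise_levels)
    if not levels:
        raise ValueError("need at least one noise level")
    if reference_level is None:
        reference_level = max(levels)
    rng = np.random.default_rng(seed)
    values = {}
    for lv in levels:
        if lv == 0:
            values[lv] = 1.0
            continue
        noisy = corrupt_with_noise(movie, lv, seed=rng.integers(0, 2**31))
        values[lv] = total_ssim(movie, noisy)
    if full:
        return values
    return float(values[reference_level])


def is_success(total: float, threshold: float = SUCCESS_THRESHOLD) -> bool:
    """A forecast succeeds when its total SSIM is at least the threshold."""
    return bool(total >= threshold)


@dataclass
class ForecastScore:
    """Per-frame SSIM curve with smoothing, plus the movie-level score."""

    per_frame: np.ndarray
    smoothed: np.ndarray
    band: np.ndarray
    total: float
    success: bool


def score_forecast(
    forecast: Movie, truth: Movie, smooth_width: int = 30, threshold: float = SUCCESS_THRESHOLD
) -> ForecastScore:
    """Score a forecast against ground truth, both in centered frame space."""
    curve = per_frame_ssim(forecast, truth.centered())
    smoothed, band = smooth_curve(curve, smooth_width)
    total = float(curve.mean())
    return ForecastScore(
        per_frame=curve, smoothed=smoothed, band=band, total=total, success=is_success(total, threshold)
    )
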