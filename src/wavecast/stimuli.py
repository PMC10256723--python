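"""Synthetic movie generators and movie transforms.

All inputs used in the experiments are generated here: point-stimulus
sequences for the 20-class decoding task, the Lissajous moving-bump movie,
Fourier phase-shuffled control movies, temporal "bookending", mask-based
centering/cropping, and a small textured "walker" fixture that stands in for
natural human-action footage.  Every generator is a pure function of its
parameters and seed.

Frames live on a Cartesian grid [-2, 2] x [-2, 2] where that matters
(point stimuli, moving bump); intensities are arbitrary units since the
network read-in z-scores each frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Movie",
    "gaussian_frame",
    "point_stimulus_sequence",
    "quadrant_center",
    "lissajous_bump_movie",
    "bookend",
    "center_crop_with_masks",
    "phase_shuffle",
    "synthetic_walker",
]

#: Cartesian extent of the stimulus domain on each axis.
DOMAIN = (-2.0, 2.0)


class StimulusError(ValueError):
    """Invalid stimulus parameter."""


@dataclass
class Movie:
    """Ordered grayscale frames, shape (n_frames, rows, cols), float64."""

    frames: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise StimulusError("frames must be a (n_frames, rows, cols) array")
        if not np.all(np.isfinite(self.frames)):
            raise StimulusError("frames must be finite")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, t):
        return self.frames[t]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def centered(self) -> "Movie":
        """Subtract each frame's spatial mean (the regression convention)."""
        means = self.frames.mean(axis=(1, 2), keepdims=True)
        return Movie(self.frames - means)


def _cartesian_axes(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = DOMAIN
    ys = np.linspace(lo, hi, shape[0])
    xs = np.linspace(lo, hi, shape[1])
    return ys, xs


def gaussian_frame(center: tuple[float, float], std: float, shape: tuple[int, int]) -> np.ndarray:
    """Isotropic 2-D Gaussian (peak 1) at ``center`` = (x, y) on [-2, 2]^2.

    The amplitude is unnormalized (peak value 1): the read-in z-scores every
    frame, so absolute scale is immaterial.
    """
    if std <= 0:
        raise StimulusError("gaussian std must be > 0")
    ys, xs = _cartesian_axes(shape)
    xc, yc = center
    gx = np.exp(-((xs - xc) ** 2) / (2 * std**2))
    gy = np.exp(-((ys - yc) ** 2) / (2 * std**2))
    return np.outer(gy, gx)


def quadrant_center(quadrant: int) -> tuple[float, float]:
    """Center (x, y) of quadrant 1..4 of [-2, 2]^2.

    Quadrants are numbered in the standard orientation: 1 = upper right,
    2 = upper left, 3 = lower left, 4 = lower right.
    """
    if quadrant not in (1, 2, 3, 4):
        raise StimulusError(f"quadrant must be 1..4, got {quadrant}")
    sx = (1.0, -1.0, -1.0, 1.0)[quadrant - 1]
    sy = (1.0, 1.0, -1.0, -1.0)[quadrant - 1]
    return (sx, sy)


def point_stimulus_sequence(
    onset_frame: int,
    quadrant: int,
    n_frames: int = 6,
    shape: tuple[int, int] = (50, 50),
    std: float = 0.05,
    placement: str = "center",
    seed=None,
) -> Movie:
    """Six-frame sequence in which exactly one frame contains a point stimulus.

    The stimulus is an isotropic Gaussian of standard deviation ``std`` on the
    [-2, 2]^2 grid, lying in the chosen quadrant; all other frames are
    identically zero.  ``placement`` selects where inside the quadrant the
    stimulus sits: "center" (default) pins it to the quadrant center
    (+-1, +-1); "uniform" draws it uniformly at random within the quadrant
    (seeded).
    With 5 possible onsets and 4 quadrants the task has exactly 20 classes.
    """
    if not 1 <= onset_frame <= 5:
        raise StimulusError(f"onset_frame must be 1..5, got {onset_frame}")
    if quadrant not in (1, 2, 3, 4):
        raise StimulusError(f"quadrant must be 1..4, got {quadrant}")
    if placement == "center":
        center = quadrant_center(quadrant)
    elif placement == "uniform":
        rng = np.random.default_rng(seed)
        cx, cy = quadrant_center(quadrant)
        # uniform inside the 2x2 quadrant
        center = (cx + rng.uniform(-1.0, 1.0), cy + rng.uniform(-1.0, 1.0))
    else:
        raise StimulusError(f"unknown placement {placement!r}")
    frames = np.zeros((n_frames,) + tuple(shape))
    frames[onset_frame - 1] = gaussian_frame(center, std, shape)
    return Movie(frames)


def lissajous_bump_movie(
    n_cycles: int,
    frames_per_cycle: int = 100,
    shape: tuple[int, int] = (30, 30),
    std: float = 0.2,
) -> Movie:
    """Gaussian bump tracing the closed orbit (sin(t/3), cos(t/3)).

    The parametric curve has period 6*pi; time is sampled at
    t_k = 6*pi*k/frames_per_cycle so that one closed orbit spans exactly
    ``frames_per_cycle`` frames, and the movie repeats with that period.
    """
    if n_cycles < 1:
        raise StimulusError("n_cycles must be >= 1")
    if frames_per_cycle < 1:
        raise StimulusError("frames_per_cycle must be >= 1")
    n = n_cycles * frames_per_cycle
    k = np.arange(n)
    t = 6.0 * np.pi * k / frames_per_cycle
    frames = np.stack(
        [gaussian_frame((np.sin(ti / 3.0), np.cos(ti / 3.0)), std, shape) for ti in t]
    )
    return Movie(frames)


def bookend(movie: Movie) -> Movie:
    """Concatenate a movie with its temporal reverse.

    Doubles the length while preserving the spatiotemporal statistics; the
    result is a temporal palindrome (frames L+1..2L are frames L..1).
    """
    if len(movie) == 0:
        raise StimulusError("cannot bookend an empty movie")
    return Movie(np.concatenate([movie.frames, movie.frames[::-1]]))


def center_crop_with_masks(
    movie: Movie, masks: Movie, out_shape: tuple[int, int] = (80, 50)
) -> Movie:
    """Translate each frame so its mask centroid is centered, then crop/resize.

    ``masks`` holds one binary mask per frame (nonzero = foreground).  Each
    frame is shifted so the mask centroid lands at the frame center, then
    resized to ``out_shape`` (rows, cols).  Raises if any mask is empty,
    naming the offending frame.
    """
    if len(masks) != len(movie):
        raise StimulusError("masks and movie must have the same number of frames")
    from skimage.transform import resize

    out = []
    for t in range(len(movie)):
        mask = masks.frames[t] > 0
        if not mask.any():
            raise StimulusError(f"empty mask in frame {t}")
        cr, cc = ndimage.center_of_mass(mask)
        rows, cols = movie.frame_shape
        shift = ((rows - 1) / 2.0 - cr, (cols - 1) / 2.0 - cc)
        frame = ndimage.shift(movie.frames[t], shift, order=1, mode="constant", cval=0.0)
        if tuple(frame.shape) != tuple(out_shape):
            frame = resize(frame, out_shape, order=1, mode="edge", anti_aliasing=False)
        out.append(frame)
    return Movie(np.stack(out))


def phase_shuffle(movie: Movie, seed=None) -> Movie:
    """Fourier phase-randomized surrogate of a movie.

    The 3-D (time x space) Fourier amplitude spectrum is preserved exactly;
    phases are drawn uniformly with Hermitian symmetry so the output is real.
    Destroys the specific spatiotemporal correlations while keeping the
    power spectrum (hence per-movie variance, by Parseval).
    """
    if len(movie) < 2:
        raise StimulusError("phase shuffle needs at least 2 frames")
    rng = np.random.default_rng(seed)
    F = np.fft.fftn(movie.frames)
    amp = np.abs(F)
    # Random phases with exact Hermitian symmetry: take the phase field of a
    # real white-noise array of the same shape (Hermitian by construction).
    noise = rng.standard_normal(size=F.shape)
    rand_phase = np.angle(np.fft.fftn(noise))
    out = np.fft.ifftn(amp * np.exp(1j * rand_phase)).real
    return Movie(out)


def synthetic_walker(
    n_cycles: int = 3,
    out_shape: tuple[int, int] = (80, 50),
    frames_per_half_cycle: int = 70,
    seed: int = 0,
) -> Movie:
    """Desk-scale stand-in for a centered natural human-action movie (synthetic).

    An articulated, textured figure — torso, two swinging legs, two counter
    swinging arms, a bobbing head — deforms through a gait cycle while
    staying centered in the frame (as mask-based centering would leave a
    real walker).  Texture is a fixed seeded random field *attached to each
    moving part* (sampled in part-local coordinates), so limb motion carries
    fine image structure with it rather than revealing a static pattern.
    The half cycle is bookended; one full cycle spans
    ``2 * frames_per_half_cycle`` frames and the movie is periodic with that
    cycle length.
    """
    rng = np.random.default_rng(seed)
    rows, cols = out_shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0

    def _texture(shape, smooth):
        t = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
        return 0.3 + 0.7 * (t - t.min()) / (np.ptp(t) + 1e-12)

    # oversized texture fields so rotated sampling never leaves the support
    big = (2 * rows, 2 * cols)
    tex_torso = _texture(big, 0.9)
    tex_limb = _texture(big, 0.6)
    tex_arm = _texture(big, 0.6)
    tex_bg = _texture((rows, cols), 2.5)

    def _limb(frame, hip_y, hip_x, length, width, angle, tex):
        """Textured bar from a joint, rotated by ``angle``; texture moves with it."""
        dy, dx = yy - hip_y, xx - hip_x
        u = np.cos(angle) * dy + np.sin(angle) * dx  # along the limb
        w = -np.sin(angle) * dy + np.cos(angle) * dx  # across the limb
        mask = (u >= 0) & (u <= length) & (np.abs(w) <= width)
        ui = np.clip(u[mask] + rows * 0.5, 0, big[0] - 1)
        wi = np.clip(w[mask] + cols * 0.5, 0, big[1] - 1)
        frame[mask] = tex[ui.astype(int), wi.astype(int)]

    frames = []
    for k in range(frames_per_half_cycle):
        ph = 2.0 * np.pi * k / frames_per_half_cycle
        bob = 1.5 * np.sin(2 * ph)
        frame = 0.02 * tex_bg.copy()  # near-black background, figure dominates
        # legs swing in antiphase below the hip
        hip_y = cy + rows * 0.08 + bob
        for sgn in (-1.0, 1.0):
            angle = 0.7 * sgn * np.sin(ph)
            _limb(frame, hip_y, cx + 1.5 * sgn, rows * 0.38, cols * 0.075, angle, tex_limb)
        # torso: textured ellipse, sampled with the vertical bob
        t_cy = cy - rows * 0.12 + bob
        mask = (((yy - t_cy) / (rows * 0.22)) ** 2 + ((xx - cx) / (cols * 0.16)) ** 2) <= 1.0
        ti = np.clip(yy[mask] - bob + rows * 0.5, 0, big[0] - 1).astype(int)
        tj = np.clip(xx[mask] + cols * 0.5, 0, big[1] - 1).astype(int)
        frame[mask] = tex_torso[ti, tj]
        # arms counter-swing in front of the torso
        sh_y = cy - rows * 0.25 + bob
        for sgn in (-1.0, 1.0):
            angle = -0.8 * sgn * np.sin(ph)
            _limb(frame, sh_y, cx + 3.0 * sgn, rows * 0.28, cols * 0.055, angle, tex_arm)
        # bobbing head
        h_cy = cy - rows * 0.42 + bob
        mask = ((yy - h_cy) ** 2 + (xx - cx) ** 2) <= (rows * 0.07) ** 2
        frame[mask] = tex_torso[(yy[mask] + rows * 0.6).astype(int), (xx[mask] + cols * 0.6).astype(int)]
        frames.append(frame)
    half = Movie(np.stack(frames))
    cycle = bookend(half)
    return Movie(np.tile(cycle.frames, (n_cycles, 1, 1)))
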