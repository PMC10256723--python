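"""File handling: HDF5 containers, image frame stacks, CSV metrics, YAML config.

Conventions
-----------
* Topology -> HDF5 group with datasets ``weights`` and ``delays`` and
  attributes ``alpha``, ``beta``, ``gamma``, ``v``, ``n_side``,
  ``grid_kernel``.
* Movie -> HDF5 dataset ``frames`` (T x H x W float), or a multi-page TIFF /
  numbered PNG directory.
* ReadoutModel -> HDF5 datasets ``V_real`` / ``V_imag`` (complex split into
  real pairs) with centering and frame-shape attributes.
* StateHistory -> complex arrays stored as paired real/imag datasets;
  cos(phase) exportable as a TIFF stack for visualization.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import StateHistory
from .readout import ReadoutModel
from .stimuli import Movie
from .topology import GridSpec, NetParams, Topology, build_grid

__all__ = [
    "save_topology",
    "load_topology",
    "save_movie_h5",
    "load_movie_h5",
    "save_movie_stack",
    "load_movie_stack",
    "save_readout",
    "load_readout",
    "save_history",
    "load_history",
    "scores_to_csv",
    "load_config",
    "ConfigError",
]


# ---------------------------------------------------------------------------
# HDF5


def _as_group(target, mode: str):
    """Accept a path (opened as file root) or an open h5py Group."""
    if isinstance(target, (str, os.PathLike)):
        return h5py.File(target, mode), True
    return target, False


def save_topology(target, top: Topology) -> None:
    grp, close = _as_group(target, "w")
    try:
        grp.create_dataset("weights", data=top.weights, compression="gzip")
        grp.create_dataset("delays", data=top.delays, compression="gzip")
        p = top.params
        grp.attrs.update(
            alpha=p.alpha, beta=p.beta, gamma=p.gamma, v=p.v,
            n_side=top.grid.n_side, grid_kernel=top.grid_kernel,
        )
    finally:
        if close:
            grp.close()


def load_topology(target) -> Topology:
    grp, close = _as_group(target, "r")
    try:
        params = NetParams(
            alpha=float(grp.attrs["alpha"]),
            beta=float(grp.attrs["beta"]),
            gamma=float(grp.attrs["gamma"]),
            v=float(grp.attrs["v"]),
        )
        grid = build_grid(int(grp.attrs["n_side"]))
        return Topology(
            weights=grp["weights"][...],
            delays=grp["delays"][...],
            params=params,
            grid=grid,
            grid_kernel=bool(grp.attrs.get("grid_kernel", False)),
        )
    finally:
        if close:
            grp.close()


def save_movie_h5(target, movie: Movie) -> None:
    grp, close = _as_group(target, "w")
    try:
        grp.create_dataset("frames", data=movie.frames, compression="gzip")
    finally:
        if close:
            grp.close()


def load_movie_h5(target) -> Movie:
    grp, close = _as_group(target, "r")
    try:
        return Movie(grp["frames"][...])
    finally:
        if close:
            grp.close()


def save_readout(target, model: ReadoutModel) -> None:
    grp, close = _as_group(target, "w")
    try:
        grp.create_dataset("V_real", data=model.V.real, compression="gzip")
        grp.create_dataset("V_imag", data=model.V.imag, compression="gzip")
        grp.attrs.update(
            centering=model.centering,
            frame_rows=model.frame_shape[0],
            frame_cols=model.frame_shape[1],
        )
    finally:
        if close:
            grp.close()


def load_readout(target) -> ReadoutModel:
    grp, close = _as_group(target, "r")
    try:
        V = grp["V_real"][...] + 1j * grp["V_imag"][...]
        return ReadoutModel(
            V=V,
            frame_shape=(int(grp.attrs["frame_rows"]), int(grp.attrs["frame_cols"])),
            centering=str(grp.attrs["centering"]),
        )
    finally:
        if close:
            grp.close()


def save_history(target, history: StateHistory) -> None:
    grp, close = _as_group(target, "w")
    try:
        grp.create_dataset("states_real", data=history.states.real, compression="gzip")
        grp.create_dataset("states_imag", data=history.states.imag, compression="gzip")
        grp.create_dataset("inputs", data=np.asarray(history.inputs, float), compression="gzip")
        if history.recurrence is not None:
            grp.create_dataset("rec_real", data=history.recurrence.real, compression="gzip")
            grp.create_dataset("rec_imag", data=history.recurrence.imag, compression="gzip")
    finally:
        if close:
            grp.close()


def load_history(target) -> StateHistory:
    grp, close = _as_group(target, "r")
    try:
        states = grp["states_real"][...] + 1j * grp["states_imag"][...]
        rec = None
        if "rec_real" in grp:
            rec = grp["rec_real"][...] + 1j * grp["rec_imag"][...]
        return StateHistory(states=states, inputs=grp["inputs"][...], recurrence=rec)
    finally:
        if close:
            grp.close()


# ---------------------------------------------------------------------------
# image stacks


def save_movie_stack(path, movie: Movie, fmt: str | None = None) -> None:
    """Write a movie as a multi-page TIFF (``.tif``) or a PNG directory.

    TIFF keeps float intensities; PNG frames are rescaled to uint8 over the
    movie's global range (PNG is for visualization, not round-tripping).
    """
    path = Path(path)
    if fmt is None:
        fmt = "png" if path.suffix == "" else path.suffix.lstrip(".")
    if fmt in ("tif", "tiff"):
        import tifffile

        tifffile.imwrite(path, movie.frames.astype(np.float32))
    elif fmt == "png":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        lo, hi = movie.frames.min(), movie.frames.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        for t, frame in enumerate(movie.frames):
            img = ((frame - lo) * scale).astype(np.uint8)
            iio.imwrite(path / f"frame_{t:05d}.png", img)
    else:
        raise ValueError(f"unknown movie format {fmt!r}")


def load_movie_stack(path) -> Movie:
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png")) or sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames under {path}")
        return Movie(np.stack([iio.imread(f).astype(float) for f in files]))
    import tifffile

    return Movie(tifffile.imread(path).astype(float))


# ---------------------------------------------------------------------------
# metrics + config


def scores_to_csv(path, score, extra: dict | None = None) -> None:
    """Write a per-frame SSIM table (frame, ssim, smoothed, band) as CSV."""
    df = pd.DataFrame(
        {
            "frame": np.arange(score.per_frame.size),
            "ssim": score.per_frame,
            "smoothed": score.smoothed,
            "band": score.band,
        }
    )
    for key, val in (extra or {}).items():
        df[key] = val
    df.to_csv(path, index=False)


class ConfigError(ValueError):
    """Invalid or incomplete experiment configuration."""


#: Recognized configuration keys and their defaults (None = required when used).
CONFIG_DEFAULTS = {
    "alpha": 0.02,
    "beta": 0.05,
    "gamma": 0.02,
    "v": 0.05,
    "n_side": 50,
    "frames_per_cycle": 100,
    "n_train_cycles": 3,
    "n_forecast_cycles": 2,
    "seed": 0,
    "n_train": 2000,
    "n_test": 100,
    "n_samples": 32,
    "eta": 0.1,
    "out_dir": "results",
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge YAML config (optional) and overrides onto the defaults.

    Unknown keys raise :class:`ConfigError` naming the key, so typos fail
    loudly instead of silently running defaults.
    """
    cfg = dict(CONFIG_DEFAULTS)
    layers = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        layers.append(loaded)
    if overrides:
        layers.append({k: v for k, v in overrides.items() if v is not None})
    for layer in layers:
        for key, value in layer.items():
            if key not in CONFIG_DEFAULTS:
                raise ConfigError(f"unknown config key: {key!r}")
            cfg[key] = value
    return cfg
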