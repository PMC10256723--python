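"""Linear readout: one-shot minimum-norm regression and closed-loop forecasting.

Only the readout is trained (reservoir-computing style).  The decoded output
frame is linear in the network state,

    y[t] = V a[t]',

where the prime denotes mean subtraction (by default the spatial mean of the
vector's entries, per time step, for both the activation vector and the
target frame — this removes the need for an intercept).  Training stacks
centered states A = [a[t0]' ... a[t0+T-1]'] against the one-step-ahead
centered frames D = [f[t0+1] ... f[t0+T]] and solves

    V = D A⁺

with the complex pseudoinverse; since there are far fewer training columns
than pixels, the problem is underdetermined and the pseudoinverse picks the
exact minimizer of ||VA - D|| with minimal Frobenius norm of V.

During closed-loop forecasting the network receives no ground truth: the
first forecast input is the corresponding true video frame, and afterwards
the frame decoded at step t is fed (through the full read-in) as the input
at the following step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import SimulationError, Simulator, StateHistory, read_in
from .stimuli import Movie
from .topology import Topology

__all__ = [
    "RegressionData",
    "ReadoutModel",
    "center_states",
    "assemble_regression",
    "train_readout",
    "decode_frame",
    "closed_loop_forecast",
    "ForecastResult",
]

_CENTERINGS = ("spatial", "temporal", "none")


def _center_cols(M: np.ndarray, centering: str) -> np.ndarray:
    """Center the columns of an (n, T) matrix per the chosen convention."""
    if centering == "spatial":  # per-column mean over entries
        return M - M.mean(axis=0, keepdims=True)
    if centering == "temporal":  # per-row mean over columns
        return M - M.mean(axis=1, keepdims=True)
    if centering == "none":
        return M
    raise ValueError(f"unknown centering {centering!r}; expected one of {_CENTERINGS}")


def center_states(a: np.ndarray, centering: str = "spatial") -> np.ndarray:
    """Center a single state vector (spatial convention subtracts its mean)."""
    if centering == "spatial":
        return a - a.mean()
    if centering == "none":
        return a
    raise ValueError("per-vector centering is only defined for 'spatial' or 'none'")


@dataclass
class RegressionData:
    """Aligned regression matrices: column k of D is the frame one step ahead
    of the state in column k of A."""

    A: np.ndarray  # (N, T) complex, centered states
    D: np.ndarray  # (M, T) real, centered one-step-ahead frames
    frame_shape: tuple[int, int]
    centering: str = "spatial"

    @property
    def n_samples(self) -> int:
        return self.A.shape[1]


@dataclass
class ReadoutModel:
    """Trained linear readout V (M x N complex) with its centering convention."""

    V: np.ndarray
    frame_shape: tuple[int, int]
    centering: str = "spatial"

    @property
    def n_pixels(self) -> int:
        return self.V.shape[0]


def assemble_regression(
    history: StateHistory,
    movie: Movie,
    start: int,
    T: int,
    centering: str = "spatial",
) -> RegressionData:
    """Build (A, D) from a recorded trajectory and the driving movie.

    In the recorded trajectory, ``states[t]`` is the state right after
    consuming frame t-1.  Column k pairs the centered state that has just
    consumed frame ``start + k`` with the centered one-step-ahead frame
    ``f[start + k + 1]``, for k = 0..T-1: the readout decodes, from the
    current network state, the frame about to arrive.  ``start`` is the
    number of discarded transient frames.
    """
    if centering not in _CENTERINGS:
        raise ValueError(f"unknown centering {centering!r}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if start + T + 1 > history.states.shape[0]:
        raise ValueError("trajectory too short for the requested window")
    if start + T + 1 > len(movie):
        raise ValueError(
            f"movie supplies {len(movie)} frames; need frames up to {start + T}"
        )
    A = history.states[start + 1 : start + T + 1].T.astype(np.complex128)
    frames = movie.frames[start + 1 : start + T + 1]
    M = frames.shape[1] * frames.shape[2]
    D = frames.reshape(T, M).T
    return RegressionData(
        A=_center_cols(A, centering),
        D=_center_cols(D, centering),
        frame_shape=movie.frame_shape,
        centering=centering,
    )


def train_readout(data: RegressionData, rcond: Optional[float] = None) -> ReadoutModel:
    """One-shot minimum-norm least squares: V = D A⁺.

    Among all exact minimizers of ||V A - D||_F, the pseudoinverse solution
    has minimal Frobenius norm.  ``rcond`` is the relative singular-value
    cutoff (default max(N, T) * machine epsilon).
    """
    A, D = data.A, data.D
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(D))):
        raise ValueError("non-finite entries in regression data")
    if rcond is None:
        rcond = max(A.shape) * np.finfo(float).eps
    V = D @ np.linalg.pinv(A, rcond=rcond)
    return ReadoutModel(V=V, frame_shape=data.frame_shape, centering=data.centering)


def decode_frame(model: ReadoutModel, a: np.ndarray) -> np.ndarray:
    """Decode one frame from a raw state vector: real part of V a', reshaped.

    The state is centered with the model's convention before projection; the
    emitted frame lives in the centered (mean-subtracted) frame space.
    """
    if a.shape[0] != model.V.shape[1]:
        raise ValueError(
            f"state length {a.shape[0]} does not match readout width {model.V.shape[1]}"
        )
    y = model.V @ center_states(a, model.centering)
    return np.real(y).reshape(model.frame_shape)


@dataclass
class ForecastResult:
    """Closed-loop forecast frames plus the recurrence/input records needed
    for the balance diagnostic over forecast times."""

    movie: Movie
    recurrence: np.ndarray  # (n_steps, N) complex
    inputs: np.ndarray  # (n_steps, N)


def closed_loop_forecast(
    top: Topology,
    model: ReadoutModel,
    primer: Movie,
    seed_frame: np.ndarray,
    n_steps: int,
    gamma: Optional[float] = None,
    phase_mode: str = "literal",
    sim: Optional[Simulator] = None,
) -> ForecastResult:
    """Prime the network on ``primer`` and forecast ``n_steps`` frames closed-loop.

    The network is driven with the primer frames (the training movie), then
    forecasting starts: at the first forecast step the input is
    ``seed_frame`` (the ground-truth frame following the primer); at every
    subsequent step the frame decoded at the previous step serves as the
    input, passed through the full read-in.  Forecast frame k approximates
    ground-truth frame len(primer) + 1 + k, in centered frame space.

    A pre-primed ``sim`` may be supplied; otherwise a fresh simulator is
    primed here on the primer movie.
    """
    if gamma is None:
        gamma = top.params.gamma
    n_side = top.grid.n_side
    if sim is None:
        sim = Simulator(top, phase_mode=phase_mode)
        for frame in primer.frames:
            sim.step(read_in(frame, n_side, gamma))
    frames = np.empty((n_steps,) + tuple(model.frame_shape))
    rec = np.empty((n_steps, top.n_nodes), dtype=np.complex128)
    X = np.empty((n_steps, top.n_nodes))
    next_input = np.asarray(seed_frame, dtype=float)
    for k in range(n_steps):
        x = read_in(next_input, n_side, gamma)
        sim.step(x)
        rec[k] = sim.last_recurrence
        X[k] = x
        y = decode_frame(model, sim.state)
        if not np.all(np.isfinite(y)):
            raise SimulationError(f"non-finite forecast value at step {k}")
        frames[k] = y
        next_input = y
    return ForecastResult(movie=Movie(frames), recurrence=rec, inputs=X)
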