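"""Competitive switching between stored readout matrices.

After training separate readouts V1 and V2 on two movies with the *same*
recurrent network, both are stored in an aggregate readout

    V_agg = c * V1 + (1 - c) * V2,        c in [0, 1],

and the mixing coefficient c adapts online from the similarity between the
current input frame and the decoded output frame, S[t]:

    c := c + dc,   dc = -eta * sgn(S[t] - S[t-1])        (literal rule)

with learning rate eta = 0.1 and c clipped to [0, 1].  The literal rule has
no direction memory; a "directional" variant performs a sign-based hill
climb, dc = eta * sgn(dS) * sgn(dc_prev), which keeps moving c in a
direction while similarity improves and reverses otherwise.  Driving the
network with a stored movie pulls c toward the extreme selecting that
movie's readout; closed-loop forecasting then replays the recalled movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .dynamics import Simulator, read_in
from .evaluation import ssim
from .readout import ReadoutModel, decode_frame
from .stimuli import Movie
from .topology import Topology

__all__ = ["SwitchState", "aggregate_readout", "update_c", "run_switch_experiment", "SwitchTrace"]


@dataclass
class SwitchState:
    """Mixing coefficient over two stored readouts with SSIM feedback."""

    V1: ReadoutModel
    V2: ReadoutModel
    c: float = 0.5  # start uncommitted
    eta: float = 0.1
    rule: str = "literal"  # or "directional"
    S_prev: Optional[float] = None
    dc_prev: float = field(default=1.0)  # direction memory for the hill-climb variant

    def __post_init__(self):
        if self.V1.V.shape != self.V2.V.shape:
            raise ValueError("stored readouts must have the same shape")
        if self.rule not in ("literal", "directional"):
            raise ValueError(f"unknown update rule {self.rule!r}")
        self.c = float(np.clip(self.c, 0.0, 1.0))


def aggregate_readout(state: SwitchState) -> ReadoutModel:
    """Convex combination c*V1 + (1-c)*V2 of the stored readout matrices."""
    V = state.c * state.V1.V + (1.0 - state.c) * state.V2.V
    return ReadoutModel(V=V, frame_shape=state.V1.frame_shape, centering=state.V1.centering)


def update_c(state: SwitchState, S_now: float) -> SwitchState:
    """One update of the mixing coefficient from the latest similarity value.

    The first call only records S (no previous value to difference against).
    sgn(0) = 0, so an unchanged similarity leaves c unchanged under the
    literal rule.
    """
    if state.S_prev is None:
        return replace(state, S_prev=float(S_now))
    dS = float(S_now) - state.S_prev
    if state.rule == "literal":
        dc = -state.eta * np.sign(dS)
    else:
        dc = state.eta * np.sign(dS) * np.sign(state.dc_prev)
    new_c = float(np.clip(state.c + dc, 0.0, 1.0))
    return replace(
        state,
        c=new_c,
        S_prev=float(S_now),
        dc_prev=dc if dc != 0 else state.dc_prev,
    )


@dataclass
class SwitchTrace:
    """Per-step record of the switching experiment."""

    step: np.ndarray
    c: np.ndarray
    S: np.ndarray
    mode: list  # "drive" or "forecast"
    frames: Movie


def run_switch_experiment(
    top: Topology,
    models: tuple[ReadoutModel, ReadoutModel],
    movies: tuple[Movie, Movie],
    schedule,
    gamma: Optional[float] = None,
    eta: float = 0.1,
    rule: str = "literal",
    initial_c: float = 0.5,
) -> SwitchTrace:
    """Drive/forecast phases with online adaptation of the mixing coefficient.

    ``schedule`` is a list of (movie_index, n_drive, n_forecast) phases: the
    network is driven with that movie's frames for n_drive steps (c adapting
    each step from the input/output SSIM), then forecasts closed-loop for
    n_forecast steps with the aggregate readout frozen at its current mix.
    Switching to the next phase feeds the other movie's frames immediately.
    """
    if gamma is None:
        gamma = top.params.gamma
    n_side = top.grid.n_side
    state = SwitchState(V1=models[0], V2=models[1], c=initial_c, eta=eta, rule=rule)
    sim = Simulator(top)
    steps, cs, Ss, modes, out_frames = [], [], [], [], []
    t = 0
    last_output = None
    for movie_idx, n_drive, n_forecast in schedule:
        movie = movies[movie_idx]
        for k in range(n_drive):
            frame = movie.frames[k % len(movie)]
            y = decode_frame(aggregate_readout(state), sim.state)
            centered = frame - frame.mean()
            S_now = ssim(centered, y)
            state = update_c(state, S_now)
            sim.step(read_in(frame, n_side, gamma))
            steps.append(t)
            cs.append(state.c)
            Ss.append(S_now)
            modes.append("drive")
            out_frames.append(y)
            last_output = y
            t += 1
        model = aggregate_readout(state)
        next_input = last_output if last_output is not None else movie.frames[0]
        for _ in range(n_forecast):
            y = decode_frame(model, sim.state)
            sim.step(read_in(next_input, n_side, gamma))
            next_input = y
            steps.append(t)
            cs.append(state.c)
            Ss.append(np.nan)
            modes.append("forecast")
            out_frames.append(y)
            last_output = y
            t += 1
    return SwitchTrace(
        step=np.asarray(steps),
        c=np.asarray(cs),
        S=np.asarray(Ss),
        mode=modes,
        frames=Movie(np.stack(out_frames)),
    )
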