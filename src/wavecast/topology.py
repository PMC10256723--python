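"""Network topology: node grid, Gaussian recurrent weights, conduction delays.

The recurrent layer is a square grid of N = n_side**2 nodes on the unit
square, a discretized cortical sheet.  Connection strength between two nodes
falls off as a Gaussian of their Euclidean distance,

    w_ij = alpha * exp(-d_ij**2 / (2 * beta**2)),

where ``alpha`` is the recurrent strength and ``beta`` (the recurrent length,
a fraction of the side length) is the kernel's standard deviation.  Every
weight is strictly positive, the matrix is symmetric and the diagonal equals
``alpha`` (self-weights are not zeroed).  Signals between nodes travel at a
finite conduction speed ``v`` (side lengths per time step), giving integer
time delays tau_ij = round(d_ij / v).

Shuffled and speed-scaled variants of a topology serve as controls that
destroy (or distort) the distance structure while preserving the weight and
delay value distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "GridSpec",
    "NetParams",
    "Topology",
    "build_grid",
    "gaussian_weights",
    "delays",
    "build_topology",
    "shuffle_topology",
    "scale_speed",
]


class TopologyError(ValueError):
    """Invalid grid or network parameter."""


@dataclass(frozen=True)
class GridSpec:
    """Square node grid on the unit square, row-major node order."""

    n_side: int
    coordinates: np.ndarray = field(repr=False)  # (N, 2), rows are (row, col) positions

    @property
    def n_nodes(self) -> int:
        return self.n_side**2

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix, (N, N)."""
        return cdist(self.coordinates, self.coordinates)


@dataclass(frozen=True)
class NetParams:
    """Free parameters of the network.

    alpha : recurrent strength (0 disables recurrence)
    beta  : recurrent length, kernel std as a fraction of the side length
    gamma : input strength applied after image read-in
    v     : conduction speed, side lengths per time step
    """

    alpha: float
    beta: float
    gamma: float
    v: float

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "v"):
            if not np.isfinite(getattr(self, name)):
                raise TopologyError(f"parameter {name!r} must be finite")
        if self.beta <= 0:
            raise TopologyError("recurrent length beta must be > 0")
        if self.v <= 0:
            raise TopologyError("conduction speed v must be > 0")
        if self.alpha < 0:
            raise TopologyError("recurrent strength alpha must be >= 0")
        if self.gamma < 0:
            raise TopologyError("input strength gamma must be >= 0")


@dataclass(frozen=True)
class Topology:
    """Recurrent weights and integer conduction delays on a node grid.

    ``grid_kernel`` is True while the weights/delays are exactly the radial
    functions of grid displacement built by :func:`build_topology`; it permits
    the fast convolution-based simulation engine.  Any operation that breaks
    the displacement structure (shuffling) clears the flag.
    """

    weights: np.ndarray  # (N, N) float
    delays: np.ndarray  # (N, N) int
    params: NetParams
    grid: GridSpec
    grid_kernel: bool = True

    @property
    def n_nodes(self) -> int:
        return self.grid.n_nodes

    @property
    def max_delay(self) -> int:
        return int(self.delays.max(initial=0))


def build_grid(n_side: int) -> GridSpec:
    """Evenly spaced n_side x n_side grid spanning the unit square.

    Node (r, c) sits at (r/(n_side-1), c/(n_side-1)); corner-to-corner
    distance is exactly sqrt(2).
    """
    if n_side < 2:
        raise TopologyError(f"n_side must be >= 2, got {n_side}")
    ticks = np.linspace(0.0, 1.0, n_side)
    rr, cc = np.meshgrid(ticks, ticks, indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    return GridSpec(n_side=int(n_side), coordinates=coords)


def gaussian_weights(grid: GridSpec, alpha: float, beta: float) -> np.ndarray:
    """Gaussian distance-dependent weight matrix; diagonal equals alpha."""
    if beta <= 0:
        raise TopologyError("recurrent length beta must be > 0")
    d2 = squareform(pdist(grid.coordinates, "sqeuclidean"))
    return alpha * np.exp(-d2 / (2.0 * beta**2))


def delays(grid: GridSpec, v: float) -> np.ndarray:
    """Integer conduction delays tau_ij = round(d_ij / v)."""
    if v <= 0:
        raise TopologyError("conduction speed v must be > 0")
    d = grid.distances()
    return np.rint(d / v).astype(np.int64)


def build_topology(n_side: int, params: NetParams) -> Topology:
    """Assemble the full topology for a grid and parameter set."""
    grid = build_grid(n_side)
    W = gaussian_weights(grid, params.alpha, params.beta)
    T = delays(grid, params.v)
    return Topology(weights=W, delays=T, params=params, grid=grid, grid_kernel=True)


_SHUFFLE_MODES = ("weights_and_delays", "delays_only")


def shuffle_topology(
    top: Topology,
    mode: str = "weights_and_delays",
    seed: int | None = 0,
    symmetric: bool = False,
) -> Topology:
    """Randomly permute off-diagonal weights and/or delays.

    The multiset of off-diagonal entries of each shuffled matrix is preserved;
    the diagonal (self-terms) is never touched.  With ``symmetric=False`` the
    upper and lower triangles are permuted jointly as one pool, so the result
    is in general not symmetric; with ``symmetric=True`` the upper triangle is
    permuted and mirrored.  Weights and delays are permuted independently
    (their pairing is not preserved).
    """
    if mode not in _SHUFFLE_MODES:
        raise TopologyError(f"unknown shuffle mode {mode!r}; expected one of {_SHUFFLE_MODES}")
    rng = np.random.default_rng(seed)
    N = top.n_nodes

    def _permute(mat: np.ndarray) -> np.ndarray:
        out = mat.copy()
        if symmetric:
            iu = np.triu_indices(N, k=1)
            vals = rng.permutation(out[iu])
            out[iu] = vals
            out.T[iu] = vals
        else:
            off = ~np.eye(N, dtype=bool)
            out[off] = rng.permutation(out[off])
        return out

    W = _permute(top.weights) if mode == "weights_and_delays" else top.weights.copy()
    T = _permute(top.delays)
    return replace(top, weights=W, delays=T, grid_kernel=False)


def scale_speed(top: Topology, factor: float) -> Topology:
    """Rebuild delays with conduction speed v' = factor * v.

    factor = 0.5 halves the speed (doubles d/v before rounding); weights are
    unchanged.  Only valid for topologies whose delays still follow the grid
    distances (i.e. not delay-shuffled ones).
    """
    if factor <= 0:
        raise TopologyError("speed factor must be > 0")
    new_params = replace(top.params, v=top.params.v * factor)
    T = delays(top.grid, new_params.v)
    return replace(top, delays=T, params=new_params)
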