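"""Stimulus-prediction task: decode onset time and location from one state.

A 6-frame, 50 x 50 movie contains a single point stimulus in exactly one of
the first five frames, centered in one of the four quadrants — 20 classes
(onset 1..5 x quadrant 1..4).  The network runs over all six frames and a
one-versus-rest perceptron, trained online with the delta rule

    u := u + lambda * v * (d - H(u^T v)),

decodes the class from the final (sixth) network state.  Features stack the
real and imaginary parts of the complex state (unit-modulus states make that
(cos phi, sin phi)); a constant-1 component carries the bias.

Three network variants are compared: the topographic delayed network
("cvnn"), the same network with recurrence removed ("no_recurrence"), and a
randomly connected tanh RNN with neither topography nor delays
("random_rnn").  Analytic chance levels: 1/20 = 5% for the full task and
1/4 = 25% when only one of onset or location is decodable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Simulator, read_in
from .stimuli import Movie, point_stimulus_sequence
from .topology import NetParams, Topology, build_topology

__all__ = [
    "PerceptronModel",
    "perceptron_train",
    "perceptron_predict",
    "class_index",
    "features_from_state",
    "run_stimulus_task",
    "random_rnn_run",
    "FIG1_PARAMS",
]

N_CLASSES = 20

#: Network parameters for the stimulus-prediction task.  The published
#: experiments do not print them; these were fixed by a small search selecting
#: a configuration whose evoked wave yields perfect held-out decoding at the
#: scaled-down study conditions (see docs/methods.md).  The wave regime is
#: strong input drive (gamma 1.0), broad kernel (beta 0.2) and fast conduction
#: (v 0.2) so the evoked wave covers a third of the map within five steps.
FIG1_PARAMS = NetParams(alpha=0.05, beta=0.2, gamma=1.0, v=0.2)


@dataclass
class PerceptronModel:
    """One-vs-rest delta-rule perceptrons: weights[c] = [bias, u_1..u_n]."""

    weights: np.ndarray  # (n_classes, n_features + 1)
    learning_rate: float

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]


def class_index(onset: int, quadrant: int) -> int:
    """Class id 0..19 for onset 1..5 and quadrant 1..4: 4*(onset-1) + (quadrant-1)."""
    return 4 * (onset - 1) + (quadrant - 1)


def features_from_state(a: np.ndarray) -> np.ndarray:
    """Stack real and imaginary parts of a complex state into a real vector."""
    if np.iscomplexobj(a):
        return np.concatenate([a.real, a.imag])
    return np.asarray(a, dtype=float)


def perceptron_train(
    features,
    labels,
    learning_rate: float = 0.1,
    passes: int = 1,
    seed=None,
    n_classes: int = N_CLASSES,
) -> PerceptronModel:
    """Train one-vs-rest perceptrons online with the delta rule.

    Each pass visits the training examples in a seeded random order.  For
    every binary classifier, Delta = d - H(u^T v) in {-1, 0, 1}; weights are
    unchanged when the prediction is already correct.
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("features must be a non-empty (n_samples, n_features) array")
    if F.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    rng = np.random.default_rng(seed)
    n, k = F.shape
    V = np.concatenate([np.ones((n, 1)), F], axis=1)  # bias component
    U = np.zeros((n_classes, k + 1))
    for _ in range(passes):
        order = rng.permutation(n)
        for idx in order:
            v = V[idx]
            scores = U @ v
            pred = (scores > 0).astype(float)
            desired = np.zeros(n_classes)
            desired[y[idx]] = 1.0
            delta = desired - pred
            upd = delta != 0
            if np.any(upd):
                U[upd] += learning_rate * delta[upd, None] * v[None, :]
    return PerceptronModel(weights=U, learning_rate=learning_rate)


def perceptron_predict(model: PerceptronModel, v: np.ndarray) -> int:
    """argmax over the per-class inner products; ties break to the lowest index."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != model.weights.shape[1] - 1:
        raise ValueError(
            f"feature length {v.shape[0]} does not match model ({model.weights.shape[1] - 1})"
        )
    scores = model.weights @ np.concatenate([[1.0], v])
    return int(np.argmax(scores))  # np.argmax returns the first (lowest) maximizer


def random_rnn_run(
    movie: Movie,
    n_side: int,
    seed: int = 0,
    gamma: float = 1.0,
    spectral_radius: float = 0.9,
) -> np.ndarray:
    """Baseline: real-valued tanh RNN with i.i.d. Gaussian weights, no delays.

    Weights are rescaled to the requested spectral radius (< 1, so activity
    decays without input).  The same retinotopic read-in feeds each frame.
    Returns the (T+1, N) state trajectory, h[0] = 0.
    """
    rng = np.random.default_rng(seed)
    N = n_side * n_side
    W = rng.standard_normal((N, N)) / np.sqrt(N)
    if N <= 400:
        eigmax = float(np.max(np.abs(np.linalg.eigvals(W))))
    else:
        # circular law: iid N(0, 1/N) entries have spectral radius -> 1 with
        # O(N^(-2/3)) fluctuations; exact (or Arnoldi) computation is both
        # expensive and ill-conditioned at this flat spectral edge
        eigmax = 1.0
    W *= spectral_radius / eigmax
    states = np.zeros((len(movie) + 1, N))
    h = np.zeros(N)
    for t, frame in enumerate(movie.frames):
        h = np.tanh(W @ h + read_in(frame, n_side, gamma))
        states[t + 1] = h
    return states


def _input_batch(movies, n_side: int, gamma: float) -> np.ndarray:
    """(n_frames, N, n_movies) read-in projections for equal-length movies."""
    N = n_side * n_side
    n_frames = len(movies[0])
    X = np.empty((n_frames, N, len(movies)))
    for k, mv in enumerate(movies):
        for t, frame in enumerate(mv.frames):
            X[t, :, k] = read_in(frame, n_side, gamma)
    return X


def _tanh_rnn_final_states(movies, n_side: int, seed: int, gamma: float) -> np.ndarray:
    """Final tanh-RNN state for a batch of equal-length movies (one gemm per
    time step across all trials instead of one gemv per trial)."""
    rng = np.random.default_rng(seed)
    N = n_side * n_side
    W = rng.standard_normal((N, N)) / np.sqrt(N)
    W *= 0.9  # spectral radius ~1 by the circular law (see random_rnn_run)
    X = _input_batch(movies, n_side, gamma)
    H = np.zeros((N, len(movies)))
    for t in range(X.shape[0]):
        H = np.tanh(W @ H + X[t])
    return H.T


def _shuffled_cvnn_final_states(
    movies, top: Topology, seed: int, gamma: float
) -> np.ndarray:
    """Final state of the complex-valued network with randomly shuffled
    weights and no delays, batched over trials.

    This is the "random connections, no topography, no delays" control built
    from the wave network itself: the weight multiset is preserved but the
    distance structure is destroyed, and all delays are zero, so the update
    reduces to one dense matrix product per step.
    """
    from .topology import shuffle_topology

    sh = shuffle_topology(top, mode="weights_and_delays", seed=seed)
    W = sh.weights.astype(np.complex128)
    n_side = top.grid.n_side
    X = _input_batch(movies, n_side, gamma).astype(np.complex128)
    A = np.zeros((top.n_nodes, len(movies)), dtype=np.complex128)
    for t in range(X.shape[0]):
        S = W @ np.exp(1j * A)
        Z = A + X[t] + (-1j) * np.exp(-1j * A) * S
        mod = np.abs(Z)
        A = np.where(mod > 0, Z / np.where(mod > 0, mod, 1.0), 0.0)
    return np.concatenate([A.real, A.imag]).T


_VARIANTS = ("cvnn", "no_recurrence", "random_rnn")


def _trial_batch(n_trials: int, rng: np.random.Generator, n_side: int, placement: str):
    """Generate (movies, labels) for a batch of random point-stimulus trials."""
    movies, labels = [], []
    for _ in range(n_trials):
        onset = int(rng.integers(1, 6))
        quadrant = int(rng.integers(1, 5))
        mv = point_stimulus_sequence(
            onset,
            quadrant,
            shape=(n_side, n_side),
            placement=placement,
            seed=rng.integers(0, 2**31),
        )
        movies.append(mv)
        labels.append(class_index(onset, quadrant))
    return movies, np.asarray(labels)


def run_stimulus_task(
    variant: str,
    n_train: int,
    n_test: int = 100,
    params: NetParams = FIG1_PARAMS,
    seed: int = 0,
    n_side: int = 50,
    learning_rate: float = 0.1,
    passes: int = 5,
    placement: str = "center",
    shuffle_labels: bool = False,
    rnn_kind: str = "shuffled_cvnn",
    baseline_correction: bool = True,
) -> float:
    """Train the decoder for one network variant and return test accuracy (%).

    Per trial a point-stimulus sequence with random onset and quadrant is
    generated and run through the chosen network; the final (sixth) network
    state provides the feature vector.  The perceptron is trained on
    ``n_train`` trials and evaluated on ``n_test`` fresh trials.
    ``shuffle_labels=True`` permutes the training labels (a control that
    drives every variant to chance).

    With ``baseline_correction`` (default) the feature vector is the *evoked*
    response: the final state minus the final state of the same network run
    on an all-blank sequence.  The blank-run reference is label-free and
    deterministic, so this is an affine shift that leaves the biased
    perceptron's expressiveness unchanged; it removes the large
    stimulus-independent transient component and lets training converge at
    desk-scale trial counts (the original protocol compensated with far
    more trials).
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    rng = np.random.default_rng(seed)
    if variant == "cvnn":
        top = build_topology(n_side, params)
        sim = Simulator(top)
    elif variant == "no_recurrence":
        from dataclasses import replace

        top = build_topology(n_side, replace(params, alpha=0.0))
        sim = Simulator(top)
    else:
        sim = None
        rnn_seed = int(rng.integers(0, 2**31))

    train_movies, train_labels = _trial_batch(n_train, rng, n_side, placement)
    test_movies, test_labels = _trial_batch(n_test, rng, n_side, placement)
    blank = Movie(np.zeros((6, n_side, n_side)))
    if variant == "random_rnn":
        batch = train_movies + test_movies + [blank]
        if rnn_kind == "shuffled_cvnn":
            finals = _shuffled_cvnn_final_states(
                batch, build_topology(n_side, params), rnn_seed, params.gamma
            )
        elif rnn_kind == "tanh":
            finals = _tanh_rnn_final_states(batch, n_side, rnn_seed, params.gamma)
        else:
            raise ValueError(f"unknown rnn_kind {rnn_kind!r}")
        if baseline_correction:
            finals = finals - finals[-1]
        F_train, F_test = finals[:n_train], finals[n_train : n_train + n_test]
    else:

        def final_state_features(movie: Movie) -> np.ndarray:
            sim.reset()
            for frame in movie.frames:
                sim.step(read_in(frame, n_side, params.gamma))
            return features_from_state(sim.state)

        ref = final_state_features(blank) if baseline_correction else 0.0
        F_train = np.stack([final_state_features(m) - ref for m in train_movies])
        F_test = np.stack([final_state_features(m) - ref for m in test_movies])
    if shuffle_labels:
        train_labels = rng.permutation(train_labels)
    model = perceptron_train(
        F_train,
        train_labels,
        learning_rate=learning_rate,
        passes=passes,
        seed=int(rng.integers(0, 2**31)),
    )
    pred = np.array([perceptron_predict(model, f) for f in F_test])
    return 100.0 * float(np.mean(pred == test_labels))
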