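import numpy as np
import pytest

from wavecast import NetParams, build_topology


@pytest.fixture(scope="session")
def small_params():
    return NetParams(alpha=0.08, beta=0.12, gamma=0.07, v=0.07)


@pytest.fixture(scope="session")
def top4(small_params):
    """4 x 4 grid topology used for exact oracle comparisons."""
    return build_topology(4, small_params)


def naive_step_oracle(X, top):
    """Literal double-loop evaluation of the delayed complex-valued update.

    Independent of the vectorized engines: indexes the weight/delay matrices
    entry by entry and applies the update equation directly.
    """
    W, T = top.weights, top.delays
    N = W.shape[0]
    hist = [np.zeros(N, complex)]
    for t in range(X.shape[0]):
        a = hist[t]
        new = np.zeros(N, complex)
        for i in range(N):
            acc = 0.0 + 0.0j
            for j in range(N):
                tpast = t - T[i, j]
                a_j = hist[tpast][j] if tpast >= 0 else 0.0 + 0.0j
                acc += W[i, j] * np.exp(1j * (a_j - a[i]))
            z = a[i] + X[t, i] - 1j * acc
            m = abs(z)
            new[i] = z / m if m > 0 else 0.0
        hist.append(new)
    return np.array(hist)
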