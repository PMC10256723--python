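import numpy as np
import pytest

from wavecast import (
    Movie,
    NetParams,
    build_topology,
    closed_loop_forecast,
    decode_frame,
    run,
    train_readout,
)
from wavecast.readout import ReadoutModel, RegressionData, assemble_regression


def _random_regression(rng, N=30, T=8, M=12):
    A = rng.normal(size=(N, T)) + 1j * rng.normal(size=(N, T))
    D = rng.normal(size=(M, T))
    return RegressionData(A=A, D=D, frame_shape=(3, 4), centering="none")


class TestTrainReadout:
    def test_rank_one_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=6) + 1j * rng.normal(size=6)
        d = rng.normal(size=4)
        data = RegressionData(A=a[:, None], D=d[:, None], frame_shape=(2, 2), centering="none")
        V = train_readout(data).V
        expected = np.outer(d, a.conj()) / np.vdot(a, a).real
        assert np.allclose(V, expected, atol=1e-12)

    def test_exact_fit_when_underdetermined(self):
        rng = np.random.default_rng(1)
        data = _random_regression(rng)
        V = train_readout(data).V
        resid = np.linalg.norm(V @ data.A - data.D) / np.linalg.norm(data.D)
        assert resid < 1e-8

    def test_matches_hand_assembled_svd_pseudoinverse(self):
        # independent oracle: build A+ from an explicit SVD on a 6x4 instance
        rng = np.random.default_rng(2)
        A = rng.normal(size=(6, 4)) + 1j * rng.normal(size=(6, 4))
        D = rng.normal(size=(5, 4))
        data = RegressionData(A=A, D=D, frame_shape=(1, 5), centering="none")
        V = train_readout(data).V
        U, s, Vh = np.linalg.svd(A, full_matrices=False)
        pinv = Vh.conj().T @ np.diag(1.0 / s) @ U.conj().T
        assert np.allclose(V, D @ pinv, atol=1e-8)

    def test_minimum_norm_among_exact_solutions(self):
        # adding any row-space-orthogonal perturbation keeps the fit exact
        # but increases the Frobenius norm
        rng = np.random.default_rng(3)
        data = _random_regression(rng, N=20, T=5, M=6)
        V = train_readout(data).V
        null = np.linalg.svd(data.A)[0][:, 5:]  # directions unseen by A
        perturbed = V + 0.1 * (rng.normal(size=(6, 15)) @ null.conj().T)
        assert np.linalg.norm(perturbed @ data.A - data.D) < 1e-8 * np.linalg.norm(data.D) + 1e-8
        assert np.linalg.norm(V) < np.linalg.norm(perturbed)

    def test_non_finite_rejected(self):
        rng = np.random.default_rng(4)
        data = _random_regression(rng)
        data.A[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_readout(data)


class TestDecodeFrame:
    def test_training_columns_reconstructed(self):
        rng = np.random.default_rng(5)
        data = _random_regression(rng, N=25, T=6, M=12)
        model = train_readout(data)
        for k in range(6):
            frame = decode_frame(model, data.A[:, k])
            assert np.allclose(frame.ravel(), data.D[:, k], atol=1e-8)

    def test_zero_readout_gives_zero_frame(self):
        model = ReadoutModel(V=np.zeros((6, 10), complex), frame_shape=(2, 3), centering="none")
        assert np.all(decode_frame(model, np.ones(10, complex)) == 0)

    def test_imaginary_residual_small_in_exact_fit(self):
        rng = np.random.default_rng(6)
        data = _random_regression(rng, N=25, T=6, M=12)
        model = train_readout(data)
        for k in range(6):
            y = model.V @ data.A[:, k]
            assert np.linalg.norm(y.imag) / np.linalg.norm(y) < 1e-6

    def test_shape_mismatch(self):
        model = ReadoutModel(V=np.zeros((6, 10), complex), frame_shape=(2, 3), centering="none")
        with pytest.raises(ValueError):
            decode_frame(model, np.ones(11, complex))


class TestAssembleRegression:
    @pytest.fixture(scope="class")
    def small_setup(self):
        params = NetParams(alpha=0.05, beta=0.1, gamma=0.05, v=0.1)
        top = build_topology(8, params)
        rng = np.random.default_rng(7)
        movie = Movie(rng.random((30, 8, 8)))
        history = run(movie, top)
        return top, movie, history

    def test_alignment_one_column(self, small_setup):
        top, movie, history = small_setup
        data = assemble_regression(history, movie, start=3, T=1)
        # single column: state that consumed frame 3, target frame 4
        assert data.A.shape == (64, 1)
        expected_state = history.states[4] - history.states[4].mean()
        assert np.allclose(data.A[:, 0], expected_state)
        f = movie.frames[4]
        assert np.allclose(data.D[:, 0], (f - f.mean()).ravel())

    def test_spatial_centering_zeroes_column_sums(self, small_setup):
        _, movie, history = small_setup
        data = assemble_regression(history, movie, start=0, T=10)
        assert np.allclose(data.A.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(data.D.sum(axis=0), 0, atol=1e-9)

    def test_cycle_protocol_column_count(self, small_setup):
        # discard 1 cycle, train 3 cycles at 100 frames/cycle -> 300 columns
        params = NetParams(alpha=0.05, beta=0.1, gamma=0.05, v=0.1)
        top = build_topology(6, params)
        movie = Movie(np.random.default_rng(8).random((401, 6, 6)))
        history = run(movie, top)
        data = assemble_regression(history, movie, start=100, T=300)
        assert data.A.shape[1] == 300

    def test_insufficient_frames(self, small_setup):
        _, movie, history = small_setup
        with pytest.raises(ValueError):
            assemble_regression(history, movie, start=25, T=10)


class TestClosedLoopForecast:
    def test_constant_movie_is_a_fixed_point(self):
        params = NetParams(alpha=0.05, beta=0.1, gamma=0.05, v=0.1)
        top = build_topology(8, params)
        movie = Movie(np.ones((40, 8, 8)) * 2.5)
        history = run(movie, top)
        data = assemble_regression(history, movie, start=5, T=20)
        model = train_readout(data)
        primer = Movie(movie.frames[:26])
        res = closed_loop_forecast(top, model, primer, movie.frames[26], n_steps=8)
        # centered constant frames are identically zero
        assert np.allclose(res.movie.frames, 0.0, atol=1e-8)

    def test_forecast_deterministic(self):
        params = NetParams(alpha=0.03, beta=0.08, gamma=0.03, v=0.08)
        top = build_topology(8, params)
        rng = np.random.default_rng(9)
        movie = Movie(rng.random((40, 8, 8)))
        history = run(movie, top)
        data = assemble_regression(history, movie, start=4, T=30)
        model = train_readout(data)
        primer = Movie(movie.frames[:35])
        f1 = closed_loop_forecast(top, model, primer, movie.frames[35], 5)
        f2 = closed_loop_forecast(top, model, primer, movie.frames[35], 5)
        assert np.array_equal(f1.movie.frames, f2.movie.frames)
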