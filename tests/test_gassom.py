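"""Windowing and GASSOM subspace coding."""

import numpy as np
import pytest

from echoroll import acoustics as A
from echoroll import gassom as G


def _random_unit_windows(n, dim, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    return X / np.linalg.norm(X, axis=1, keepdims=True)


@pytest.fixture(scope="module")
def small_dict():
    cfg = G.GassomConfig(n_units=16, dim=20, grid_shape=(4, 4), total_steps=100)
    return G.GassomDictionary(cfg, seed=0)


class TestExtractWindows:
    def test_fine_window_count(self):
        echo = A.BinauralEcho(np.random.default_rng(0).normal(size=1000),
                              np.random.default_rng(1).normal(size=1000))
        w = G.extract_windows(echo)
        assert w[("fine", "binaural")].shape[0] == 191  # (1000-50)/5 + 1

    def test_binaural_dimension_is_100_at_both_scales(self):
        echo = A.BinauralEcho(np.random.default_rng(0).normal(size=600),
                              np.random.default_rng(1).normal(size=600))
        w = G.extract_windows(echo)
        assert w[("fine", "binaural")].shape[1] == 100
        assert w[("coarse", "binaural")].shape[1] == 100
        assert w[("fine", "left")].shape[1] == 50
        assert w[("coarse", "right")].shape[1] == 50

    def test_windows_unit_norm(self):
        echo = A.BinauralEcho(np.random.default_rng(2).normal(size=700),
                              np.random.default_rng(3).normal(size=700))
        for W in G.extract_windows(echo).values():
            np.testing.assert_allclose(np.linalg.norm(W, axis=1), 1.0,
                                       atol=1e-9)

    def test_zero_echo_drops_all_windows(self):
        echo = A.BinauralEcho(np.zeros(500), np.zeros(500))
        w = G.extract_windows(echo)
        assert all(v.shape[0] == 0 for v in w.values())

    def test_binaural_is_left_right_concatenation(self):
        left = np.random.default_rng(4).normal(size=400)
        right = np.random.default_rng(5).normal(size=400)
        echo = A.BinauralEcho(left, right)
        w = G.extract_windows(echo)
        fine_b = w[("fine", "binaural")][0] * np.linalg.norm(
            np.r_[left[:50], right[:50]]
        )
        np.testing.assert_allclose(fine_b, np.r_[left[:50], right[:50]])


class TestEncode:
    def test_window_inside_subspace(self, small_dict):
        x = small_dict.bases[3] @ np.array([0.6, 0.8])
        enc = small_dict.encode(x[None, :])
        assert enc.responses[0, 3] == pytest.approx(1.0, abs=1e-12)
        assert enc.errors[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_window_orthogonal_to_subspace(self, small_dict):
        B = small_dict.bases[0]
        x = np.random.default_rng(0).normal(size=20)
        x -= B @ (B.T @ x)
        x /= np.linalg.norm(x)
        enc = small_dict.encode(x[None, :])
        assert enc.responses[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert enc.errors[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_explicit_projection_matrices(self, small_dict):
        X = _random_unit_windows(100, 20, seed=1)
        enc = small_dict.encode(X)
        for j in range(small_dict.config.n_units):
            P = small_dict.bases[j] @ small_dict.bases[j].T
            brute = np.einsum("nd,nd->n", X @ P, X @ P)
            np.testing.assert_allclose(enc.responses[:, j], brute, atol=1e-10)

    def test_pythagoras_identity(self, small_dict):
        X = _random_unit_windows(50, 20, seed=2)
        enc = small_dict.encode(X)
        np.testing.assert_allclose(
            enc.responses + enc.errors,
            np.broadcast_to(enc.norms_sq[:, None], enc.responses.shape),
            atol=1e-9,
        )

    def test_posterior_is_distribution(self, small_dict):
        X = _random_unit_windows(30, 20, seed=3)
        enc = small_dict.encode(X)
        np.testing.assert_allclose(enc.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert enc.posterior.min() >= 0

    def test_sticky_assignment_persists_on_repeats(self, small_dict):
        x = small_dict.bases[7] @ np.array([1.0, 0.0])
        X = np.tile(x, (10, 1))
        enc = small_dict.encode(X)
        assert np.all(enc.winners == 7)

    def test_dimension_mismatch_rejected(self, small_dict):
        with pytest.raises(ValueError):
            small_dict.encode(np.ones((3, 7)))


class TestUpdate:
    def test_zero_learning_rate_leaves_dictionary(self):
        cfg = G.GassomConfig(n_units=16, dim=20, grid_shape=(4, 4),
                             lr_start=0.0, lr_end=0.0, total_steps=10)
        d = G.GassomDictionary(cfg, seed=1)
        before = d.bases.copy()
        d.update(_random_unit_windows(20, 20, seed=4))
        np.testing.assert_array_equal(d.bases, before)

    def test_convergence_to_fixed_subspace(self):
        cfg = G.GassomConfig(n_units=16, dim=30, grid_shape=(4, 4),
                             total_steps=300)
        d = G.GassomDictionary(cfg, seed=2)
        rng = np.random.default_rng(5)
        B0 = np.linalg.qr(rng.normal(size=(30, 2)))[0]
        for _ in range(300):
            X = rng.normal(size=(30, 2)) @ B0.T
            X /= np.linalg.norm(X, axis=1, keepdims=True)
            d.update(X)
        enc = d.encode(X)
        assert enc.errors.min(axis=1).mean() < 1e-3

    def test_bases_stay_orthonormal_over_many_updates(self):
        cfg = G.GassomConfig(n_units=9, dim=12, grid_shape=(3, 3),
                             total_steps=10_000)
        d = G.GassomDictionary(cfg, seed=3)
        rng = np.random.default_rng(6)
        for _ in range(10_000):
            d.update(_random_unit_windows(2, 12, seed=rng.integers(2**31)))
        dev = max(
            np.abs(b.T @ b - np.eye(2)).max() for b in d.bases
        )
        assert dev < 1e-6

    def test_nan_input_raises_training_failure(self, small_dict):
        X = np.full((3, 20), np.nan)
        with pytest.raises(FloatingPointError):
            G.GassomDictionary(small_dict.config, seed=9).update(X)


class TestPooling:
    def _full_encodings(self, value=None, seed=0):
        encs = {}
        for k, stream in enumerate(G.STREAMS):
            dim = 100 if stream[1] == "binaural" else 50
            cfg = G.GassomConfig(n_units=400, dim=dim, grid_shape=(20, 20))
            d = G.GassomDictionary(cfg, seed=[seed, k])
            X = _random_unit_windows(5, dim, seed=k)
            encs[stream] = d.encode(X)
        return encs

    def test_feature_dimension_2400(self):
        f = G.pool_features(self._full_encodings())
        assert f.shape == (2400,)

    def test_identical_windows_pool_to_single_response(self):
        cfg = G.GassomConfig(n_units=16, dim=20, grid_shape=(4, 4))
        d = G.GassomDictionary(cfg, seed=0)
        x = _random_unit_windows(1, 20, seed=1)
        X = np.tile(x, (7, 1))
        enc = d.encode(X)
        np.testing.assert_allclose(enc.mean_response, enc.responses[0],
                                   atol=1e-12)

    def test_pooling_linearity(self, small_dict):
        X = _random_unit_windows(10, 20, seed=2)
        enc = small_dict.encode(X)
        np.testing.assert_allclose(
            (3.0 * enc.responses).mean(axis=0), 3.0 * enc.mean_response
        )

    def test_missing_stream_rejected(self):
        with pytest.raises(ValueError):
            G.pool_features({})


class TestLearnedRepresentation:
    @staticmethod
    def _echo_windows(hrtf, direction, rng):
        call = A.synthesize_call(float(np.clip(rng.gamma(8.0, 0.3),
                                               0.51, 9.99)))
        echo = A.render_echo(call, hrtf, horizontal=direction, elevation=0.0)
        return G.extract_windows(echo)[("fine", "binaural")]

    def test_lateralized_training_yields_binaural_tuning(self):
        """Training on lateralized echoes must produce at least one unit
        with fitted |ITD| > 10 us and one with |ILD| > 3 dB."""
        from echoroll import analysis as AN

        hrtf = A.make_synthetic_hrtf(A.SyntheticHrtfConfig(
            horizontal_deg=(-85, 85, 10), elevation_deg=(-85, 85, 10)))
        cfg = G.GassomConfig(n_units=16, dim=100, grid_shape=(4, 4),
                             total_steps=120)
        d = G.GassomDictionary(cfg, seed=0)
        rng = np.random.default_rng(1)
        for _ in range(120):
            direction = rng.choice([-50.0, 50.0])
            d.update(self._echo_windows(hrtf, direction, rng))
        ilds, itds = [], []
        for j in range(cfg.n_units):
            for col in range(2):
                vec = d.bases[j, :, col]
                c = AN.characterize_basis(vec[:50], vec[50:], A.SAMPLE_RATE)
                ilds.append(abs(c.ild_db))
                itds.append(abs(c.itd_us))
        assert max(itds) > 10.0
        assert max(ilds) > 3.0

    def test_heldout_error_decreases_with_training(self):
        """Median held-out reconstruction error over seeds must drop
        between the untrained dictionary and the trained one."""
        hrtf = A.make_synthetic_hrtf(A.SyntheticHrtfConfig(
            horizontal_deg=(-85, 85, 10), elevation_deg=(-85, 85, 10)))
        rng = np.random.default_rng(2)
        held = np.vstack([
            self._echo_windows(hrtf, rng.uniform(-60, 60), rng)
            for _ in range(5)
        ])
        drops = []
        for seed in range(5):
            cfg = G.GassomConfig(n_units=16, dim=100, grid_shape=(4, 4),
                                 total_steps=60)
            d = G.GassomDictionary(cfg, seed=seed)
            before = d.encode(held).window_errors.mean()
            train_rng = np.random.default_rng(100 + seed)
            for _ in range(60):
                d.update(self._echo_windows(
                    hrtf, train_rng.uniform(-60, 60), train_rng))
            after = d.encode(held).window_errors.mean()
            drops.append(before - after)
        assert np.median(drops) > 0


def test_dictionary_hdf5_round_trip(tmp_path, small_dict):
    import h5py

    d = G.GassomDictionary(small_dict.config, seed=5)
    d.update(_random_unit_windows(10, 20, seed=6))
    path = tmp_path / "dict.h5"
    with h5py.File(path, "w") as f:
        d.save(f.create_group("g"))
    with h5py.File(path, "r") as f:
        loaded = G.GassomDictionary.load(f["g"])
    np.testing.assert_array_equal(loaded.bases, d.bases)
    assert loaded.step == d.step
    assert loaded.config.n_units == d.config.n_units
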