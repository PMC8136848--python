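"""Analysis battery: step fits, MSE, basis cues, tuning curves, statistics."""

import numpy as np
import pytest
from scipy import stats

from echoroll import analysis as AN
from echoroll import gassom as G

FS_FINE = 500_000.0


def synth_pair(ild_db, itd_us, fc_khz, m_khz_ms, n=50, fs=FS_FINE,
               t0_frac=0.5, w_frac=0.2, phase=0.3):
    """Gaussian-windowed chirp pair with known binaural cues.

    Positive ITD delays the right component (left leads).
    """
    t = np.arange(n) / fs
    T = t[-1]
    t0, w = t0_frac * T, w_frac * T
    fc, m = fc_khz * 1e3, m_khz_ms * 1e6
    env = np.exp(-0.5 * ((t - t0) / w) ** 2)
    psi = 2 * np.pi * (fc * (t - t0) + 0.5 * m * (t - t0) ** 2)
    amp_l = 10 ** (ild_db / 40.0)
    amp_r = 10 ** (-ild_db / 40.0)
    left = amp_l * env * np.cos(psi + phase)
    right = amp_r * env * np.cos(psi + phase - 2 * np.pi * fc * itd_us * 1e-6)
    return left, right


class TestStepResponseFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(1, 21, dtype=float)
        y = -89.90 * np.exp(-t / 2.46) + 0.74
        fit = AN.fit_step_response(y)
        assert fit.A == pytest.approx(-89.90, abs=1e-6)
        assert fit.B == pytest.approx(0.74, abs=1e-6)
        assert fit.tau == pytest.approx(2.46, abs=1e-6)

    def test_constant_trajectory_rejected(self):
        with pytest.raises(ValueError):
            AN.fit_step_response(np.full(20, 0.74))

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(0)
        t = np.arange(1, 21, dtype=float)
        taus = []
        for _ in range(100):
            y = 60 * np.exp(-t / 3.0) - 1.0 + rng.normal(0, 1.0, 20)
            taus.append(AN.fit_step_response(y).tau)
        assert np.median(taus) == pytest.approx(3.0, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            AN.fit_step_response([1.0, 0.5, 0.2])


class TestSteadyStateMse:
    def test_perfect_localization(self):
        assert AN.steady_state_mse(np.zeros((5, 2))) == 0.0

    def test_single_trace_arithmetic(self):
        assert AN.steady_state_mse([[3.0, 4.0]]) == pytest.approx(25.0)

    def test_self_normalization_is_unity(self):
        d = np.array([[5.0, 2.0], [1.0, -3.0]])
        mse, norm = AN.steady_state_mse(d, reference_mse=AN.steady_state_mse(d))
        assert norm == pytest.approx(1.0)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            AN.steady_state_mse(np.zeros((4, 3)))


class TestCharacterizeBasis:
    def test_identical_components_have_zero_cues(self):
        left, right = synth_pair(0.0, 0.0, 40.0, -20.0)
        c = AN.characterize_basis(left, right, FS_FINE)
        assert c.ild_db == pytest.approx(0.0, abs=0.05)
        assert c.itd_us == pytest.approx(0.0, abs=0.1)

    def test_known_cues_recovered(self):
        left, right = synth_pair(6.0, -5.0, 40.0, -20.0)
        c = AN.characterize_basis(left, right, FS_FINE)
        assert c.ild_db == pytest.approx(6.0, abs=0.2)
        assert c.itd_us == pytest.approx(-5.0, abs=0.5)
        assert c.f_c_khz == pytest.approx(40.0, abs=0.5)
        assert c.sweep_rate_khz_ms == pytest.approx(-20.0, abs=1.0)

    def test_itd_invariant_to_common_scaling(self):
        left, right = synth_pair(3.0, 8.0, 35.0, 10.0)
        c1 = AN.characterize_basis(left, right, FS_FINE)
        c2 = AN.characterize_basis(7.3 * left, 7.3 * right, FS_FINE)
        assert c2.itd_us == pytest.approx(c1.itd_us, abs=0.05)
        assert c2.ild_db == pytest.approx(c1.ild_db, abs=0.01)

    def test_round_trip_across_cue_ranges(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            ild = rng.uniform(-20, 20)
            itd = rng.uniform(-10, 10)  # within half a carrier cycle
            fc = rng.uniform(25, 60)
            m = rng.uniform(-25, 25)
            left, right = synth_pair(ild, itd, fc, m,
                                     phase=rng.uniform(-1, 1))
            c = AN.characterize_basis(left, right, FS_FINE)
            assert c.ild_db == pytest.approx(ild, abs=0.2)
            assert c.itd_us == pytest.approx(itd, abs=0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AN.characterize_basis(np.ones(50), np.ones(40), FS_FINE)


@pytest.fixture(scope="module")
def tone_dict():
    """Dictionary whose unit 0 is a 40 kHz quadrature pair (in phase,
    equal amplitude across ears)."""
    cfg = G.GassomConfig(n_units=4, dim=100, grid_shape=(2, 2))
    d = G.GassomDictionary(cfg, seed=0)
    t = np.arange(50) / FS_FINE
    c = np.cos(2 * np.pi * 40e3 * t)
    s = np.sin(2 * np.pi * 40e3 * t)
    b1 = np.r_[c, c]
    b2 = np.r_[s, s]
    B = np.column_stack([b1 / np.linalg.norm(b1), b2])
    # orthonormalize exactly
    d.bases[0] = np.linalg.qr(B)[0]
    return d


class TestPureToneProbing:
    def test_best_frequency_of_constructed_unit(self, tone_dict):
        probes = AN.probe_pure_tones(tone_dict, FS_FINE)
        assert probes[0]["bf_khz"] == pytest.approx(40.0, abs=1.0)

    def test_probe_grid_sizes(self, tone_dict):
        probes = AN.probe_pure_tones(tone_dict, FS_FINE)
        assert len(probes[0]["frequency"].axis) == 61  # 10..70 in 1 kHz steps
        assert len(probes[0]["ild"].axis) == 81  # -40..40 in 1 dB steps
        assert len(probes[0]["itd"].axis) == 161  # -80..80 in 1 us steps

    def test_curves_max_normalized(self, tone_dict):
        probes = AN.probe_pure_tones(tone_dict, FS_FINE)
        for key in ("frequency", "ild", "itd"):
            assert probes[0][key].values.max() == pytest.approx(1.0)

    def test_itd_curve_periodicity_matches_carrier(self, tone_dict):
        probes = AN.probe_pure_tones(tone_dict, FS_FINE)
        curve = probes[0]["itd"]
        bf_hz = probes[0]["bf_khz"] * 1e3
        period_us = 1e6 / bf_hz  # 25 us at 40 kHz
        v = curve.values - curve.values.mean()
        spec = np.abs(np.fft.rfft(v))
        k = 1 + int(np.argmax(spec[1:]))
        span = curve.axis[-1] - curve.axis[0]
        assert span / k == pytest.approx(period_us, rel=0.1)


class TestClassifyTuningCurve:
    def _curve(self, values, kind="ild", lo=-40, hi=40):
        axis = np.linspace(lo, hi, len(values))
        return AN.TuningCurve(axis, np.asarray(values, float), kind)

    def test_monotonic(self):
        x = np.linspace(0, 1, 50)
        assert AN.classify_tuning_curve(self._curve(1 / (1 + np.exp(-8 * (x - 0.5))))) == "monotonic"

    def test_peaked(self):
        x = np.linspace(-1, 1, 50)
        bump = np.exp(-0.5 * (x / 0.16) ** 2)
        assert AN.classify_tuning_curve(self._curve(bump)) == "peaked"

    def test_cyclic(self):
        x = np.linspace(0, 4 * np.pi, 80)
        assert AN.classify_tuning_curve(self._curve(0.5 + 0.5 * np.sin(x))) == "cyclic"

    def test_flat(self):
        assert AN.classify_tuning_curve(self._curve(np.full(20, 0.5))) == "flat"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            AN.classify_tuning_curve(self._curve(np.arange(5.0)))


class TestCompareDistributions:
    def test_identical_histograms(self):
        p = np.array([0.2, 0.3, 0.5])
        kl, bc = AN.compare_distributions(p, p)
        assert kl == pytest.approx(0.0, abs=1e-12)
        assert bc == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_values(self):
        kl, bc = AN.compare_distributions([1.0, 0.0], [0.5, 0.5])
        assert kl == pytest.approx(np.log(2))
        assert bc == pytest.approx(np.sqrt(0.5))

    def test_bc_symmetric_kl_not(self):
        p = np.array([0.7, 0.2, 0.1])
        q = np.array([0.2, 0.5, 0.3])
        kl_pq, bc_pq = AN.compare_distributions(p, q)
        kl_qp, bc_qp = AN.compare_distributions(q, p)
        assert bc_pq == pytest.approx(bc_qp)
        assert kl_pq != pytest.approx(kl_qp)

    def test_kl_needs_smoothing_for_empty_bins(self):
        with pytest.raises(ValueError):
            AN.compare_distributions([0.5, 0.5], [1.0, 0.0])
        kl, _ = AN.compare_distributions([0.5, 0.5], [1.0, 0.0],
                                         smoothing=1e-6)
        assert np.isfinite(kl) and kl > 0

    def test_kl_nonnegative_bc_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            kl, bc = AN.compare_distributions(p, q, smoothing=1e-9)
            assert kl >= -1e-12
            assert -1e-12 <= bc <= 1 + 1e-12

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            AN.compare_distributions([0.5, 0.5], [0.3, 0.3, 0.4])


class TestEffectStats:
    def test_identical_groups_give_zero_f(self):
        g = np.arange(5.0)
        out = AN.effect_stats([g, g, g])
        assert out["F"] == pytest.approx(0.0, abs=1e-12)

    def test_cohens_d_unit_case(self):
        a = np.array([-1.0, 0.0, 1.0]) + 0.0
        b = a + 1.0
        out = AN.effect_stats([a, b])
        assert out["cohens_d"][(0, 1)] == pytest.approx(-1.0)

    def test_anova_matches_reference_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0,
                                 rng.integers(5, 30)) for _ in range(4)]
            ours = AN.effect_stats(groups)
            ref = stats.f_oneway(*groups)
            assert ours["F"] == pytest.approx(ref.statistic, abs=1e-10)
            assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            AN.effect_stats([[1.0, 1.0], [2.0, 2.0]])

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            AN.effect_stats([[1.0, 2.0]])
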