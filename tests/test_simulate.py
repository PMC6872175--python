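"""Generator statistics: step variance, confinement, drift, switching, noise, blinking."""

import numpy as np
import pytest

import sptkit as sk
from sptkit.simulate import SimConfigError


class TestBrownian:
    def test_zero_diffusion_is_stationary(self):
        ts = sk.simulate_brownian(sk.SimConfig(n_tracks=3, n_steps=10, D=0.0, seed=1))
        for tr in ts:
            assert np.all(tr.x == tr.x[0]) and np.all(tr.y == tr.y[0])

    def test_step_variance_matches_2Ddt(self):
        # D = 0.1 um^2/s, dt = 0.1 s -> per-dimension step variance 0.02 um^2
        cfg = sk.SimConfig(n_tracks=500, n_steps=201, dt=0.1, D=0.1, seed=2)
        steps = np.concatenate([np.diff(tr.x) for tr in sk.simulate_brownian(cfg)])
        assert steps.var() == pytest.approx(0.02, rel=0.02)

    def test_ensemble_msd_slope_4D(self):
        cfg = sk.SimConfig(n_tracks=1000, n_steps=100, dt=0.1, D=0.1, seed=3)
        lags, msd = sk.ensemble_msd(sk.simulate_brownian(cfg), max_lag=10)
        assert np.allclose(msd, 4 * 0.1 * lags, rtol=0.05)

    def test_seed_reproducibility(self):
        cfg = sk.SimConfig(n_tracks=2, n_steps=50, seed=9)
        a = sk.simulate_brownian(cfg)
        b = sk.simulate_brownian(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x) and np.array_equal(ta.y, tb.y)

    def test_invalid_config(self):
        with pytest.raises(SimConfigError):
            sk.SimConfig(n_steps=1)
        with pytest.raises(SimConfigError):
            sk.SimConfig(dt=0.0)
        with pytest.raises(SimConfigError):
            sk.SimConfig(D=-1.0)


class TestConfined:
    def test_square_well_positions_bounded(self):
        cfg = sk.SimConfig(n_tracks=20, n_steps=500, D=0.1, mode="confined_square",
                           L=0.3, seed=4)
        for tr in sk.simulate_confined(cfg):
            assert np.all((tr.x >= 0) & (tr.x <= 0.3))
            assert np.all((tr.y >= 0) & (tr.y <= 0.3))

    def test_large_L_limit_is_brownian(self):
        from scipy import stats

        free = sk.simulate_brownian(sk.SimConfig(n_tracks=50, n_steps=100, D=0.05, seed=5))
        boxed = sk.simulate_confined(sk.SimConfig(n_tracks=50, n_steps=100, D=0.05,
                                                  mode="confined_square", L=100.0, seed=6))
        sa = np.concatenate([np.diff(tr.x) for tr in free])
        sb = np.concatenate([np.diff(tr.x) for tr in boxed])
        assert stats.ks_2samp(sa, sb).pvalue > 0.01

    def test_square_well_msd_plateau_L2_over_6(self):
        from sptkit.msd import _msd_1d_fft

        L = 0.5
        cfg = sk.SimConfig(n_tracks=60, n_steps=20000, dt=0.1, D=0.1,
                           mode="confined_square", L=L, seed=7)
        plat = [_msd_1d_fft(tr.x, 5000)[2000:].mean()
                for tr in sk.simulate_confined(cfg)]
        assert L**2 / np.mean(plat) == pytest.approx(6.0, rel=0.10)

    def test_parabolic_trap_stationary_spread(self):
        cfg = sk.SimConfig(n_tracks=100, n_steps=500, dt=0.1, D=0.01,
                           mode="confined_parabolic", trap_size=0.2, seed=8)
        xs = np.concatenate([tr.x for tr in sk.simulate_confined(cfg)])
        assert xs.std() == pytest.approx(0.05, rel=0.05)

    def test_invalid_L(self):
        with pytest.raises(SimConfigError):
            sk.SimConfig(mode="confined_square", L=0.0)


class TestDirected:
    def test_zero_drift_identity(self):
        cfg = sk.SimConfig(n_tracks=3, n_steps=40, D=0.05, mode="directed",
                           v=(0.0, 0.0), seed=10)
        a = sk.simulate_directed(cfg)
        b = sk.simulate_brownian(cfg.replace(mode="brownian"))
        for ta, tb in zip(a, b):
            assert np.allclose(ta.x, tb.x) and np.allclose(ta.y, tb.y)

    def test_pure_drift_deterministic(self):
        cfg = sk.SimConfig(n_tracks=1, n_steps=10, dt=0.1, D=0.0, mode="directed",
                           v=(0.1, 0.0), seed=11)
        tr = sk.simulate_directed(cfg)[0]
        assert np.allclose(np.diff(tr.x), 0.01)
        assert np.allclose(np.diff(tr.y), 0.0)

    def test_ensemble_msd_parabola(self):
        # MSD(t) = 4 D t + (v t)^2 for drift-diffusion
        D, v = 0.05, 0.2
        cfg = sk.SimConfig(n_tracks=800, n_steps=60, dt=0.1, D=D, mode="directed",
                           v=(v, 0.0), seed=12)
        lags, msd = sk.ensemble_msd(sk.simulate_directed(cfg), max_lag=50)
        expected = 4 * D * lags + (v * lags) ** 2
        assert msd[-1] == pytest.approx(expected[-1], rel=0.10)


class TestSwitching:
    P2 = np.array([[0.98, 0.02], [0.02, 0.98]])

    def test_single_state_equals_brownian_stats(self):
        cfg = sk.SimConfig(n_tracks=50, n_steps=200, dt=0.1, seed=13)
        ts, truth = sk.simulate_switching(cfg, [0.1], [[1.0]])
        steps = np.concatenate([np.diff(tr.x) for tr in ts])
        assert steps.var() == pytest.approx(0.02, rel=0.05)
        assert all(np.all(s == 0) for s in truth.state_sequence.values())

    def test_dwell_length_geometric(self):
        cfg = sk.SimConfig(n_tracks=20, n_steps=2000, dt=0.1, seed=14)
        _, truth = sk.simulate_switching(cfg, [0.01, 0.2], self.P2)
        dwells = []
        for s in truth.state_sequence.values():
            change = np.nonzero(np.diff(s))[0]
            bounds = np.concatenate([[-1], change, [len(s) - 1]])
            dwells.extend(np.diff(bounds))
        assert np.mean(dwells) == pytest.approx(50, rel=0.2)

    def test_transition_frequencies_converge(self):
        cfg = sk.SimConfig(n_tracks=30, n_steps=2000, dt=0.1, seed=15)
        _, truth = sk.simulate_switching(cfg, [0.01, 0.2], self.P2)
        trans = np.zeros((2, 2))
        for s in truth.state_sequence.values():
            for a, b in zip(s[:-1], s[1:]):
                trans[a, b] += 1
        emp = trans / trans.sum(axis=1, keepdims=True)
        n = trans.sum(axis=1)
        for i in range(2):
            se = np.sqrt(0.98 * 0.02 / n[i])
            assert abs(emp[i, i] - 0.98) < 3 * se

    def test_nonstochastic_matrix_rejected(self):
        with pytest.raises(SimConfigError):
            sk.simulate_switching(sk.SimConfig(seed=0), [0.1, 0.2],
                                  [[0.5, 0.4], [0.1, 0.9]])

    def test_three_state_mixture_detected(self):
        # fast/intermediate/slow states leave a multi-component step-size
        # signature: a 3-component Gaussian mixture beats 1 component
        from sklearn.mixture import GaussianMixture

        P = np.full((3, 3), 0.025)
        np.fill_diagonal(P, 0.95)
        cfg = sk.SimConfig(n_tracks=5, n_steps=1000, dt=0.1, seed=16)
        ts, _ = sk.simulate_switching(cfg, [0.005, 0.05, 0.3], P)
        steps = np.concatenate([np.diff(tr.x) for tr in ts]).reshape(-1, 1)
        ll3 = GaussianMixture(3, random_state=0).fit(steps).score(steps)
        ll1 = GaussianMixture(1, random_state=0).fit(steps).score(steps)
        assert ll3 > ll1 + 0.05  # per-sample mean log-likelihood gain


class TestNoiseAndBlinking:
    def test_zero_sigma_identity(self):
        ts = sk.simulate_brownian(sk.SimConfig(n_tracks=2, n_steps=20, seed=17))
        assert sk.add_localization_noise(ts, 0.0) is ts

    def test_original_unmodified_and_displacement_std(self):
        cfg = sk.SimConfig(n_tracks=100, n_steps=100, D=0.0, seed=18)
        ts = sk.simulate_brownian(cfg)
        x_before = ts[0].x.copy()
        noisy = sk.add_localization_noise(ts, 0.025, seed=19)
        assert np.array_equal(ts[0].x, x_before)
        steps = np.concatenate([np.diff(tr.x) for tr in noisy])
        assert steps.std() == pytest.approx(np.sqrt(2) * 0.025, rel=0.03)

    def test_noisy_msd_intercept_4sigma2(self):
        cfg = sk.SimConfig(n_tracks=500, n_steps=100, dt=0.1, D=0.1, seed=20)
        noisy = sk.add_localization_noise(sk.simulate_brownian(cfg), 0.025, seed=21)
        lags, msd = sk.ensemble_msd(noisy, max_lag=4)
        slope, intercept = np.polyfit(lags, msd, 1)
        assert intercept == pytest.approx(4 * 0.025**2, rel=0.25)

    def test_blinking_fraction_and_gap_bound(self):
        cfg = sk.SimConfig(n_tracks=50, n_steps=200, seed=22)
        ts = sk.simulate_brownian(cfg)
        blinked = sk.add_blinking(ts, blink_p=0.1, seed=23)
        removed = sum(200 - len(tr) for tr in blinked)
        assert removed / (50 * 200) == pytest.approx(0.1, abs=0.02)
        for tr in blinked:
            assert tr.frames[0] == 0 and tr.frames[-1] == 199
            assert np.max(np.diff(tr.frames)) - 1 <= 10

    def test_blink_identity_and_warning(self):
        ts = sk.simulate_brownian(sk.SimConfig(n_tracks=1, n_steps=20, seed=24))
        assert sk.add_blinking(ts, 0.0) is ts
        with pytest.warns(UserWarning, match="continuity window"):
            sk.add_blinking(ts, 0.1, blink_max_gap=11, seed=25)

    def test_blur_substeps_reduce_apparent_msd(self):
        # motion blur lowers the 2D lag-1 MSD by 2 * 4*R*D*dt with R ~ 1/6
        base = sk.SimConfig(n_tracks=5000, n_steps=20, dt=0.1, D=0.1, seed=26)
        _, msd0 = sk.ensemble_msd(sk.simulate_brownian(base), max_lag=1)
        _, msd1 = sk.ensemble_msd(
            sk.simulate_brownian(base.replace(blur_substeps=20)), max_lag=1)
        expected_drop = 8 * (1 / 6) * 0.1 * 0.1 * (1 - 1 / 20**2)
        assert msd0[0] - msd1[0] == pytest.approx(expected_drop, rel=0.15)
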