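"""Kalman-filter perceptual model: mapping, updates, filter, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import percgen as pg
from percgen.perception import (
    GroupPerceptParams,
    PerceptParams,
    gaussian_loglik,
    trajectory_arrays,
)


def params(beta0=-3.05, beta1=0.023, sigma_S=0.8, omega=0.002):
    return PerceptParams(beta0, beta1, sigma_S, omega)


class TestSensoryMapping:
    def test_flat_sigmoid_gives_midpoint(self):
        assert pg.sensory_mean(123.0, params(0.0, 0.0)) == pytest.approx(100.0)

    def test_population_median_value(self):
        # direct evaluation of the sigmoid at the CS+ diameter under the
        # reported population medians
        assert pg.sensory_mean(96.54, params()) == pytest.approx(60.75, abs=0.01)

    def test_monotone_and_saturating(self):
        x = np.linspace(0, 280, 50)  # below float saturation of the sigmoid
        mu = pg.sensory_mean(x, params())
        assert np.all(np.diff(mu) > 0)
        assert pg.sensory_mean(2000.0, params()) == pytest.approx(200.0, abs=1e-6)
        assert pg.sensory_mean(-1e6, params()) == pytest.approx(0.0, abs=1e-9)


class TestKalmanUpdates:
    @pytest.mark.parametrize(
        "sp, ss, expected", [(1.0, 1.0, 0.5), (0.0, 1.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_gain_values(self, sp, ss, expected):
        assert pg.kalman_gain(sp, ss) == pytest.approx(expected)

    def test_gain_errors(self):
        with pytest.raises(ValueError):
            pg.kalman_gain(-1.0, 1.0)
        with pytest.raises(ValueError):
            pg.kalman_gain(0.0, 0.0)

    @given(sp=st.floats(0.0, 100.0), ss=st.floats(0.01, 100.0))
    @settings(deadline=None)
    def test_gain_bounded(self, sp, ss):
        g = pg.kalman_gain(sp, ss)
        assert 0.0 <= g < 1.0

    @pytest.mark.parametrize(
        "mu, mu_new, gain, expected", [(50, 70, 0.25, 55), (50, 70, 1, 70), (50, 70, 0, 50)]
    )
    def test_mean_update(self, mu, mu_new, gain, expected):
        assert pg.update_mean(mu, mu_new, gain) == pytest.approx(expected)

    def test_uncertainty_update(self):
        assert pg.update_uncertainty(0.0, 1.0, 11.0, 0.1, 0) == pytest.approx(11.0)
        # reported initial-noise magnitude, 100 trials into the session
        assert pg.update_uncertainty(10.0, 0.5, 11.04, 0.002, 100) == pytest.approx(
            14.04, abs=0.01
        )
        assert pg.update_uncertainty(10.0, 0.5, 11.0, 1e9, 5) == pytest.approx(5.0)


class TestFilter:
    def test_matches_bruteforce_recursion(self, rng):
        """The filter equals a plain step-by-step recomputation of the
        update equations on random instances."""
        group = GroupPerceptParams(eta=11.0)
        for _ in range(20):
            p = params(
                rng.normal(-3, 1), rng.uniform(0.005, 0.05),
                rng.uniform(0.3, 3.0), rng.uniform(0, 0.05),
            )
            x = rng.uniform(50, 120, size=30)
            states = pg.filter_trajectory(x, p, group)
            mu_S = group.Omega / (1 + np.exp(-(p.beta0 + p.beta1 * x)))
            mu, sig = mu_S[0], group.eta
            assert states[0].mu_psi == pytest.approx(mu)
            assert states[0].sigma_psi == pytest.approx(sig)
            for j in range(1, 30):
                gain = sig / (sig + p.sigma_S)
                mu = mu + gain * (mu_S[j] - mu)
                sig = (1 - gain) * sig + group.eta * np.exp(-p.omega * (j - 1))
                assert states[j].mu_psi == pytest.approx(mu, abs=1e-12)
                assert states[j].sigma_psi == pytest.approx(sig, abs=1e-12)
                assert states[j].kalman_gain == pytest.approx(gain, abs=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        group = GroupPerceptParams(eta=8.0)
        x = rng.uniform(50, 120, size=40)
        b0 = rng.normal(-3, 0.5, (2, 3))
        b1 = rng.uniform(0.01, 0.03, (2, 3))
        sS = rng.uniform(0.3, 2.0, (2, 3))
        om = rng.uniform(0, 0.01, (2, 3))
        mu, sig = trajectory_arrays(x, b0, b1, sS, om, 8.0)
        for c in range(2):
            for i in range(3):
                states = pg.filter_trajectory(
                    x, PerceptParams(b0[c, i], b1[c, i], sS[c, i], om[c, i]), group
                )
                assert np.allclose(mu[:, c, i], [s.mu_psi for s in states])
                assert np.allclose(sig[:, c, i], [s.sigma_psi for s in states])

    def test_mean_contraction_under_constant_input(self):
        """For constant input the perceptual mean homes in on the sensory
        mean monotonically."""
        group = GroupPerceptParams(eta=11.0)
        p = params(0.0, 0.01, 1.0, 0.0)
        states = pg.filter_trajectory(np.full(50, 80.0), p, group)
        mu_S = states[0].mu_S
        err = np.abs([s.mu_psi - mu_S for s in states])
        assert np.all(np.diff(err) <= 1e-12)

    def test_uncertainty_nonincreasing_without_process_noise(self):
        # eta = 0 degenerates the noise term: sigma can only shrink
        sig = [7.0]
        for j in range(1, 40):
            gain = pg.kalman_gain(sig[-1], 1.0)
            sig.append(pg.update_uncertainty(sig[-1], gain, 0.0, 0.0, j - 1))
        assert np.all(np.diff(sig) <= 0)
        assert sig[-1] >= 0

    def test_gain_one_tracks_input_eta_zero_freezes(self):
        group = GroupPerceptParams(eta=11.0)
        p = params(0.0, 0.02, 1e-9, 10.0)  # tiny sensory noise, fast decay
        x = np.full(60, 90.0)
        states = pg.filter_trajectory(x, p, group)
        assert states[-1].mu_psi == pytest.approx(states[-1].mu_S, abs=1e-6)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pg.filter_trajectory(np.array([]), params(), GroupPerceptParams())


class TestSampling:
    def test_seeded_reproducibility(self):
        a = pg.sample_sensory(60.0, 2.0, np.random.default_rng(3))
        b = pg.sample_sensory(60.0, 2.0, np.random.default_rng(3))
        assert a == b

    def test_degenerate_noise_returns_mean(self):
        assert pg.sample_sensory(60.0, 0.0, np.random.default_rng(0)) == 60.0

    def test_monte_carlo_mean(self, rng):
        draws = [pg.sample_sensory(60.0, 2.0, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(60.0, abs=3 * 2.0 / np.sqrt(10_000))


class TestLoglik:
    def test_exact_value_at_mode(self):
        states = [pg.PerceptState(0, 60.0, 60.0, 1.0, 1.0)]
        assert pg.perceptual_loglik([60.0], states) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_doubling_sigma_closed_form(self, rng):
        mu = rng.normal(60, 5, 10)
        sd = rng.uniform(1, 3, 10)
        y = mu + rng.normal(0, 1, 10)
        s1 = [pg.PerceptState(j, m, m, s, 0.5) for j, (m, s) in enumerate(zip(mu, sd))]
        s2 = [pg.PerceptState(j, m, m, 2 * s, 0.5) for j, (m, s) in enumerate(zip(mu, sd))]
        l1 = pg.perceptual_loglik(y, s1)
        l2 = pg.perceptual_loglik(y, s2)
        # halving precision: residual terms shrink by 3/4, plus n*log 2
        expected = l2 - l1
        z2 = ((y - mu) / sd) ** 2
        assert expected == pytest.approx(0.375 * z2.sum() - 10 * np.log(2))

    def test_empty_and_errors(self):
        assert pg.perceptual_loglik([], []) == 0.0
        with pytest.raises(ValueError):
            pg.perceptual_loglik([1.0], [])
        bad = [pg.PerceptState(0, 60.0, 60.0, 0.0, 1.0)]
        with pytest.raises(ValueError):
            pg.perceptual_loglik([60.0], bad)

    def test_gaussian_loglik_matches_scipy(self, rng):
        from scipy.stats import norm

        y = rng.normal(size=(7, 3))
        mu = rng.normal(size=(7, 3))
        assert gaussian_loglik(y, mu, 1.7) == pytest.approx(
            norm.logpdf(y, mu, 1.7).sum(0), abs=1e-10
        )
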