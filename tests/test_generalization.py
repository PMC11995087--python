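"""Error-driven learning, similarity decay, response mapping, forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import percgen as pg
from percgen.distances import DistanceSeries, Metric
from percgen.generalization import forward_theta, forward_values


class TestRescorlaWagner:
    @pytest.mark.parametrize(
        "v, alpha, r, k, expected",
        [(0.0, 0.5, 1, 1, 0.5), (0.7, 0.3, 1, 0, 0.7), (0.5, 0.2, 0, 1, 0.4),
         (0.0, 0.4, -1, 1, -0.4)],
    )
    def test_update(self, v, alpha, r, k, expected):
        assert pg.rw_update(v, alpha, r, k) == pytest.approx(expected)

    def test_expected_value_converges_to_reinforcement_rate(self, rng):
        """Under 50% reinforcement v fluctuates around 0.5 for any alpha."""
        for alpha in (0.1, 0.5, 0.9):
            means = []
            for _ in range(40):
                r = rng.permutation([1] * 250 + [0] * 250)
                v = 0.0
                tail = []
                for rj in r:
                    v = pg.rw_update(v, alpha, rj, 1)
                    tail.append(v)
                means.append(np.mean(tail[100:]))
            assert np.mean(means) == pytest.approx(0.5, abs=0.05)


class TestGeneralize:
    def test_zero_distance_returns_strength(self):
        assert pg.generalize(0.8, 2.0, 0.0) == pytest.approx(0.8)

    def test_differential_cancellation_at_lambda_zero(self):
        g = pg.generalize(1.0, 0.0, 3.0, v_minus=-1.0, d_minus=5.0, design="differential")
        assert g == pytest.approx(0.0)

    def test_half_decay(self):
        assert pg.generalize(1.0, np.log(2), 1.0) == pytest.approx(0.5)

    def test_negative_lambda_errors(self):
        with pytest.raises(ValueError):
            pg.generalize(1.0, -0.1, 1.0)

    @given(
        vp=st.floats(0.0, 1.0), vm=st.floats(-1.0, 0.0),
        lam=st.floats(0.0, 10.0), dp=st.floats(0.0, 5.0), dm=st.floats(0.0, 5.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounds(self, vp, vm, lam, dp, dm):
        assert 0.0 <= pg.generalize(vp, lam, dp) <= 1.0
        g = pg.generalize(vp, lam, dp, v_minus=vm, d_minus=dm, design="differential")
        assert -1.0 <= g <= 1.0


class TestResponseMapping:
    def test_midpoint(self):
        assert pg.response_mean(0.0, 0.0, 3.0) == pytest.approx(5.5)

    def test_saturation(self):
        assert pg.response_mean(0.0, 50.0, 1.0) == pytest.approx(10.0)
        assert pg.response_mean(0.0, -50.0, 1.0) == pytest.approx(1.0)

    def test_monotone_in_strength(self):
        g = np.linspace(-1, 1, 20)
        th = pg.response_mean(g, 0.5, 2.0)
        assert np.all(np.diff(th) > 0)

    def test_loglik_exact_and_scaling(self, rng):
        th = rng.uniform(2, 9, 15)
        assert pg.response_loglik(th, th, 1.0) == pytest.approx(
            -15 * 0.5 * np.log(2 * np.pi)
        )
        resid = rng.normal(0, 0.5, 15)
        l1 = pg.response_loglik(th + resid, th, 1.0)
        l2 = pg.response_loglik(th + 2 * resid, th, 1.0)
        assert l1 - l2 == pytest.approx(1.5 * (resid**2).sum())
        assert pg.response_loglik([], [], 1.0) == 0.0
        with pytest.raises(ValueError):
            pg.response_loglik(th, th, 0.0)


class TestOvergeneralizerBound:
    def test_values(self):
        assert pg.overgeneralizer_lambda_bound(1.0) == pytest.approx(0.35667, abs=1e-5)
        lam = pg.overgeneralizer_lambda_bound(3.7)
        assert np.exp(-lam * 3.7) == pytest.approx(0.7)
        assert pg.overgeneralizer_lambda_bound(2.0) == pytest.approx(
            pg.overgeneralizer_lambda_bound(1.0) / 2
        )
        with pytest.raises(ValueError):
            pg.overgeneralizer_lambda_bound(0.0)


class TestForwardModel:
    def test_matches_bruteforce_chain(self, exp1_schedule, rng):
        """The vectorized forward pass equals a literal trial loop through
        the learning, generalization and response equations."""
        T = len(exp1_schedule)
        for _ in range(10):
            gp = pg.GenParams(
                alpha=rng.uniform(0.1, 0.9), lam=rng.uniform(0.1, 3.0),
                w0=rng.normal(), w1=rng.normal(3, 1),
            )
            d = DistanceSeries(Metric.POINT, rng.uniform(0, 1, T))
            theta = forward_theta(exp1_schedule, gp, d)
            v = 0.0
            for j, e in enumerate(exp1_schedule.entries):
                g = pg.generalize(v, gp.lam, d.d_plus[j])
                assert theta[j] == pytest.approx(
                    pg.response_mean(g, gp.w0, gp.w1), abs=1e-12
                )
                if e.k == 1:
                    v = pg.rw_update(v, gp.alpha, e.r, 1)

    def test_differential_bruteforce(self, exp2_schedule, rng):
        from percgen.design import Role

        T = len(exp2_schedule)
        gp = pg.GenParams(alpha=0.4, lam=1.2, w0=-0.5, w1=4.0)
        d = DistanceSeries(Metric.POINT, rng.uniform(0, 1, T), rng.uniform(0, 1, T))
        theta = forward_theta(exp2_schedule, gp, d)
        vp = vm = 0.0
        for j, e in enumerate(exp2_schedule.entries):
            g = vp * np.exp(-gp.lam * d.d_plus[j]) + vm * np.exp(-gp.lam * d.d_minus[j])
            assert theta[j] == pytest.approx(pg.response_mean(g, gp.w0, gp.w1), abs=1e-12)
            role = exp2_schedule.stimuli.roles[e.stimulus]
            if e.k == 1 and role is Role.CS_PLUS:
                vp = pg.rw_update(vp, gp.alpha, e.r, 1)
            elif e.k == 1 and role is Role.CS_MINUS:
                vm = pg.rw_update(vm, gp.alpha, e.r, 1)

    def test_values_respect_bounds(self, exp2_schedule):
        vp, vm = forward_values(exp2_schedule, alpha=0.7)
        assert np.all((vp >= 0) & (vp <= 1))
        assert np.all((vm >= -1) & (vm <= 0))
        assert vm.min() < -0.5  # inhibitory learning actually happened

    def test_nonlearner_flat_theta(self, exp1_schedule):
        gp = pg.GenParams(alpha=0.0, lam=0.0, w0=0.3, w1=2.0, group=pg.Group.NON_LEARNER)
        d = DistanceSeries(Metric.POINT, np.zeros(len(exp1_schedule)))
        theta = forward_theta(exp1_schedule, gp, d)
        assert np.ptp(theta) == 0.0

    def test_theta_decreasing_in_distance_for_sharp_generalizer(self, exp1_schedule):
        gp = pg.GenParams(alpha=0.9, lam=4.0, w0=0.0, w1=5.0)
        T = len(exp1_schedule)
        near = DistanceSeries(Metric.POINT, np.full(T, 0.1))
        far = DistanceSeries(Metric.POINT, np.full(T, 0.9))
        assert np.all(
            forward_theta(exp1_schedule, gp, near)[20:]
            > forward_theta(exp1_schedule, gp, far)[20:]
        )

    def test_simulate_responses_seeded_and_clipped(self, exp1_schedule, rng):
        gp = pg.GenParams(alpha=0.5, lam=1.0, w0=0.0, w1=4.0)
        d = DistanceSeries(Metric.POINT, rng.uniform(0, 1, len(exp1_schedule)))
        y1 = pg.simulate_responses(exp1_schedule, gp, d, 2.0, np.random.default_rng(5))
        y2 = pg.simulate_responses(exp1_schedule, gp, d, 2.0, np.random.default_rng(5))
        assert np.array_equal(y1, y2)
        assert y1.min() >= 1.0 and y1.max() <= 10.0
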