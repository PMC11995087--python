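"""Overlap, point and physical distances; CS memory; distance series."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm


def min_density_integral(m1, s1, m2, s2):
    """Brute-force oracle: integrate min(f1, f2) numerically, splitting at
    density crossings located by sign-scanning (independent of the package's
    analytic crossing formula)."""
    lo = min(m1 - 10 * s1, m2 - 10 * s2)
    hi = max(m1 + 10 * s1, m2 + 10 * s2)
    diff = lambda x: norm.logpdf(x, m1, s1) - norm.logpdf(x, m2, s2)
    grid = np.linspace(lo, hi, 4001)
    vals = diff(grid)
    cuts = [lo]
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if np.sign(va) != np.sign(vb) and np.isfinite(va) and np.isfinite(vb):
            cuts.append(brentq(diff, a, b))
    cuts.append(hi)
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        piece, _ = quad(
            lambda x: min(norm.pdf(x, m1, s1), norm.pdf(x, m2, s2)), a, b,
            limit=200,
        )
        total += piece
    return total

import percgen as pg
from percgen.design import Role
from percgen.distances import (
    Metric,
    PerceptualDistribution,
    overlap_coefficient_arrays,
    overlap_distance_arrays,
)

N = PerceptualDistribution


class TestOverlap:
    def test_identical_distributions(self):
        assert pg.overlap_coefficient(N(3.0, 2.0), N(3.0, 2.0)) == pytest.approx(1.0)
        assert pg.overlap_distance(N(3.0, 2.0), N(3.0, 2.0)) == pytest.approx(0.0)

    def test_disjoint_support(self):
        assert pg.overlap_coefficient(N(0, 1), N(1e6, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        # equal variances: overlap = 2*Phi(-|dmu| / (2*sigma))
        assert pg.overlap_coefficient(N(0, 1), N(1, 1)) == pytest.approx(
            2 * norm.cdf(-0.5), abs=1e-10
        )
        assert pg.overlap_distance(N(0, 1), N(1, 1)) == pytest.approx(0.3829, abs=1e-4)

    def test_equal_sd_closed_form_random_pairs(self, rng):
        for _ in range(200):
            m1, m2 = rng.normal(0, 20, 2)
            s = rng.uniform(0.1, 15)
            got = pg.overlap_coefficient(N(m1, s), N(m2, s))
            assert got == pytest.approx(2 * norm.cdf(-abs(m1 - m2) / (2 * s)), abs=1e-8)

    def test_unequal_sd_vs_numeric_quadrature(self, rng):
        """Analytic piecewise evaluation against brute-force numeric
        integration of min(f1, f2)."""
        for _ in range(25):
            p = N(rng.normal(0, 5), rng.uniform(0.2, 5))
            q = N(rng.normal(0, 5), rng.uniform(0.2, 5))
            ref = min_density_integral(p.mean, p.sd, q.mean, q.sd)
            assert pg.overlap_coefficient(p, q) == pytest.approx(ref, abs=1e-8)

    def test_vectorized_matches_scalar(self, rng):
        m1, m2 = rng.normal(0, 5, (2, 50))
        s1, s2 = rng.uniform(0.2, 5, (2, 50))
        vec = overlap_coefficient_arrays(m1, s1, m2, s2)
        for i in range(50):
            assert vec[i] == pytest.approx(
                pg.overlap_coefficient(N(m1[i], s1[i]), N(m2[i], s2[i])), abs=1e-10
            )

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            p = N(rng.normal(0, 5), rng.uniform(0.2, 5))
            q = N(rng.normal(0, 5), rng.uniform(0.2, 5))
            ab = pg.overlap_distance(p, q)
            ba = pg.overlap_distance(q, p)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0

    def test_monotone_in_mean_separation(self):
        d = [pg.overlap_distance(N(0, 2), N(dm, 2)) for dm in np.linspace(0, 20, 15)]
        assert np.all(np.diff(d) > 0)

    def test_wide_equal_sds_vanishing_distance(self):
        assert pg.overlap_distance(N(0, 1e4), N(5, 1e4)) == pytest.approx(0.0, abs=1e-3)

    def test_monte_carlo_convergence(self, rng):
        for _ in range(10):
            p = N(rng.normal(0, 3), rng.uniform(0.5, 3))
            q = N(rng.normal(0, 3), rng.uniform(0.5, 3))
            exact = pg.overlap_coefficient(p, q)
            mc = pg.overlap_coefficient(p, q, method="monte_carlo", n_mc=40_000, seed=8)
            assert abs(mc - exact) <= 3 / np.sqrt(40_000)

    def test_monte_carlo_seeded(self):
        a = pg.overlap_coefficient(N(0, 1), N(1, 2), method="monte_carlo", n_mc=500, seed=4)
        b = pg.overlap_coefficient(N(0, 1), N(1, 2), method="monte_carlo", n_mc=500, seed=4)
        assert a == b

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            N(0.0, 0.0)
        with pytest.raises(ValueError):
            pg.overlap_coefficient(N(0, 1), N(0, 1), method="simpson")
        with pytest.raises(ValueError):
            pg.overlap_coefficient(N(0, 1), N(0, 1), method="monte_carlo", n_mc=0)


class TestPointAndPhysical:
    def test_physical(self):
        assert pg.physical_distance(96.54, 96.54) == 0.0
        assert pg.physical_distance(96.544, 119.42) == pytest.approx(22.876)
        assert pg.physical_distance(3.0, 7.0) == pg.physical_distance(7.0, 3.0)

    @pytest.mark.parametrize(
        "hist, rating, expected",
        [([60, 62], 61, 0.0), ([50], 70, 20.0), ([40, 60, 80], 50, 10.0)],
    )
    def test_point(self, hist, rating, expected):
        assert pg.point_distance(hist, rating) == pytest.approx(expected)

    def test_point_empty_history_errors(self):
        with pytest.raises(ValueError):
            pg.point_distance([], 50.0)


class TestCsMemory:
    def test_memory_is_most_recent_preceding_cs(self, exp1_schedule):
        p = pg.PerceptParams(-3.0, 0.02, 1.0, 0.002)
        states = pg.filter_trajectory(
            np.array([exp1_schedule.stimuli.diameter(e.stimulus)
                      for e in exp1_schedule.entries]),
            p, pg.GroupPerceptParams(eta=11.0),
        )
        mem = pg.cs_memory(states, exp1_schedule, trial=2)
        assert mem.mean == states[1].mu_psi  # trial 1 is the later CS+ trial
        assert mem.sd == states[1].sigma_psi
        with pytest.raises(ValueError):
            pg.cs_memory(states, exp1_schedule, trial=0)
        with pytest.raises(ValueError):
            pg.cs_memory(states, exp1_schedule, trial=50, which=Role.CS_MINUS)


class TestDistanceSeries:
    def test_physical_constant_per_label(self, exp1_schedule):
        series = pg.build_distance_series(exp1_schedule, Metric.PHYSICAL)
        labels = [e.stimulus for e in exp1_schedule.entries]
        per_label = {}
        for lab, d in zip(labels, series.d_plus):
            per_label.setdefault(lab, set()).add(round(d, 9))
        assert all(len(v) == 1 for v in per_label.values())
        assert per_label["S7"] == {0.0}

    def test_overlap_series_matches_quadrature_oracle(self, exp1_schedule, rng):
        T = len(exp1_schedule)
        mu = rng.normal(60, 8, T)
        sd = rng.uniform(5, 12, T)
        series = pg.build_distance_series(
            exp1_schedule, Metric.OVERLAP, mu_psi=mu, sigma_psi=sd
        )
        roles = [exp1_schedule.stimuli.roles[e.stimulus] for e in exp1_schedule.entries]
        last = None
        for j in rng.choice(T, size=100, replace=False):
            if last is None:
                pass
            d_ref = 0.0
            prev = [k for k in range(j) if roles[k] is Role.CS_PLUS]
            if prev:
                k = prev[-1]
                d_ref = 1 - min_density_integral(mu[j], sd[j], mu[k], sd[k])
            assert series.d_plus[j] == pytest.approx(d_ref, abs=1e-6)

    def test_normalization(self, exp1_schedule, rng):
        T = len(exp1_schedule)
        series = pg.build_distance_series(
            exp1_schedule, Metric.POINT, ratings=rng.uniform(30, 90, T), normalize=True
        )
        assert series.normalized
        assert series.d_plus.max() == pytest.approx(1.0)
        assert series.d_plus.min() >= 0.0

    def test_missing_inputs_error(self, exp1_schedule):
        with pytest.raises(ValueError):
            pg.build_distance_series(exp1_schedule, Metric.POINT)
        with pytest.raises(ValueError):
            pg.build_distance_series(exp1_schedule, Metric.OVERLAP)

    def test_differential_design_has_minus_series(self, exp2_schedule):
        series = pg.build_distance_series(exp2_schedule, Metric.PHYSICAL)
        assert series.d_minus is not None
        assert len(series.d_minus) == len(series.d_plus) == 186
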