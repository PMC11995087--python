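"""Trial-wise stimulus distances: physical, point-based, distribution overlap.

Three metrics quantify how far the currently encountered stimulus sits from
the conditioned-stimulus (CS) memory:

* PHYSICAL — absolute diameter difference in mm.
* POINT — absolute difference between the running mean of past CS size
  ratings and the current trial's size rating (descriptive perception).
* OVERLAP — one minus the overlap coefficient ``int min(f1, f2) dx`` of the
  current perceptual distribution and the CS memory distribution, both
  Gaussian; the memory is the perceptual state on the most recent preceding
  CS trial.  Overlap distances live in [0, 1].

The overlap integral has an exact piecewise-Gaussian evaluation via the
analytic crossing points of the two densities (the default); a hit-or-miss
Monte Carlo estimator under the pointwise minimum is provided as well.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import Role, TrialSchedule
from .perception import PerceptState


class Metric(str, enum.Enum):
    PHYSICAL = "PHYSICAL"
    POINT = "POINT"
    OVERLAP = "OVERLAP"


@dataclass(frozen=True)
class PerceptualDistribution:
    """A Gaussian stimulus representation (percept or CS memory)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def _gaussian_crossings(p: PerceptualDistribution, q: PerceptualDistribution) -> np.ndarray:
    """Solutions of f_p(x) = f_q(x), ascending (0, 1 or 2 points)."""
    m1, s1, m2, s2 = p.mean, p.sd, q.mean, q.sd
    if np.isclose(s1, s2):
        if np.isclose(m1, m2):
            return np.array([])
        return np.array([(m1 + m2) / 2.0])
    # log f_p - log f_q is a quadratic a x^2 + b x + c
    a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = 0.5 * (m2**2 / s2**2 - m1**2 / s1**2) + np.log(s2 / s1)
    disc = b**2 - 4.0 * a * c
    if disc <= 0:
        return np.array([])
    r = np.sqrt(disc)
    return np.sort(np.array([(-b - r) / (2 * a), (-b + r) / (2 * a)]))


def overlap_coefficient(
    p: PerceptualDistribution,
    q: PerceptualDistribution,
    method: str = "quadrature",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """Overlap coefficient ``int min(f_p, f_q) dx`` of two Gaussians, in [0,1].

    ``quadrature`` evaluates the integral exactly piecewise between the
    analytic crossing points of the two densities.  ``monte_carlo`` is the
    hit-or-miss estimator: points uniform in a bounding box, accepted when
    below the pointwise minimum of the densities.
    """
    if method == "quadrature":
        xs = _gaussian_crossings(p, q)
        cuts = np.concatenate(([-np.inf], xs, [np.inf]))
        total = 0.0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mid = _segment_midpoint(lo, hi)
            # log densities: far tails underflow plain pdfs to a 0 == 0 tie
            fp = norm.logpdf(mid, p.mean, p.sd)
            fq = norm.logpdf(mid, q.mean, q.sd)
            d = p if fp <= fq else q
            total += norm.cdf(hi, d.mean, d.sd) - norm.cdf(lo, d.mean, d.sd)
        return float(min(total, 1.0))
    if method == "monte_carlo":
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        rng = np.random.default_rng(seed)
        # min(f_p, f_q) is negligible wherever either density is, so the
        # bounding box is the intersection of the two 6-sigma ranges, capped
        # by the lower of the two peaks; x is stratified to cut the variance
        # of the acceptance rate across the range
        lo = max(p.mean - 6 * p.sd, q.mean - 6 * q.sd)
        hi = min(p.mean + 6 * p.sd, q.mean + 6 * q.sd)
        if hi <= lo:
            return 0.0
        ymax = min(norm.pdf(p.mean, p.mean, p.sd), norm.pdf(q.mean, q.mean, q.sd))
        u = (np.arange(n_mc) + rng.uniform(size=n_mc)) / n_mc
        x = lo + u * (hi - lo)
        y = rng.uniform(0.0, ymax, size=n_mc)
        fmin = np.minimum(norm.pdf(x, p.mean, p.sd), norm.pdf(x, q.mean, q.sd))
        hits = np.mean(y < fmin)
        return float(min(hits * (hi - lo) * ymax, 1.0))
    raise ValueError(f"unknown method {method!r}")


def _segment_midpoint(lo: float, hi: float) -> float:
    if np.isinf(lo) and np.isinf(hi):
        return 0.0
    if np.isinf(lo):
        return hi - 1.0
    if np.isinf(hi):
        return lo + 1.0
    return 0.5 * (lo + hi)


def overlap_distance(
    p: PerceptualDistribution,
    q: PerceptualDistribution,
    method: str = "quadrature",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """Distance 1 - overlap_coefficient, in [0, 1]; 0 iff p == q."""
    return 1.0 - overlap_coefficient(p, q, method=method, n_mc=n_mc, seed=seed)


def overlap_coefficient_arrays(
    mu1: np.ndarray, sd1: np.ndarray, mu2: np.ndarray, sd2: np.ndarray
) -> np.ndarray:
    """Vectorized exact Gaussian overlap coefficient.

    Equal-sd pairs reduce to 2*Phi(-|dmu|/(2*sd)).  For unequal sds the two
    densities cross at the roots of a quadratic; the pointwise minimum is the
    narrower density on the outer segments (its tails are lighter) and the
    wider one in between, so the integral is a sum of normal CDF pieces.
    """
    from scipy.special import ndtr

    mu1, sd1, mu2, sd2 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(mu1, float)), np.asarray(sd1, float),
        np.asarray(mu2, float), np.asarray(sd2, float),
    )
    out = np.empty(mu1.shape)
    eq = np.isclose(sd1, sd2)
    if np.any(eq):
        s = sd1[eq]
        out[eq] = 2.0 * ndtr(-np.abs(mu1[eq] - mu2[eq]) / (2.0 * s))
    ne = ~eq
    if np.any(ne):
        m1, s1, m2, s2 = mu1[ne], sd1[ne], mu2[ne], sd2[ne]
        # orient so that s1 is the narrower density
        swap = s1 > s2
        m1, m2 = np.where(swap, m2, m1), np.where(swap, m1, m2)
        s1, s2 = np.where(swap, s2, s1), np.where(swap, s1, s2)
        a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
        b = m1 / s1**2 - m2 / s2**2
        c = 0.5 * (m2**2 / s2**2 - m1**2 / s1**2) + np.log(s2 / s1)
        disc = np.maximum(b**2 - 4.0 * a * c, 0.0)
        r = np.sqrt(disc)
        x_lo = (-b + r) / (2.0 * a)  # a < 0 when s1 < s2
        x_hi = (-b - r) / (2.0 * a)
        narrow_outer = ndtr((x_lo - m1) / s1) + ndtr(-(x_hi - m1) / s1)
        wide_middle = ndtr((x_hi - m2) / s2) - ndtr((x_lo - m2) / s2)
        out[ne] = narrow_outer + wide_middle
    return np.minimum(out, 1.0)


def overlap_distance_arrays(
    mu1: np.ndarray, sd1: np.ndarray, mu2: np.ndarray, sd2: np.ndarray
) -> np.ndarray:
    """Vectorized exact overlap distance 1 - int min(f1, f2)."""
    return 1.0 - overlap_coefficient_arrays(mu1, sd1, mu2, sd2)


def physical_distance(x_cs: float, x_ts: float) -> float:
    """Absolute diameter difference in mm."""
    return abs(x_cs - x_ts)


def point_distance(cs_ratings_so_far: list[float] | np.ndarray, ts_rating: float) -> float:
    """|cumulative mean of CS size ratings - current rating|."""
    arr = np.asarray(cs_ratings_so_far, dtype=float)
    if arr.size == 0:
        raise ValueError("cs_ratings_so_far must be nonempty")
    return float(abs(arr.mean() - ts_rating))


def cs_memory(
    states: list[PerceptState],
    schedule: TrialSchedule,
    trial: int,
    which: Role = Role.CS_PLUS,
) -> PerceptualDistribution:
    """Perceptual state of the most recent CS trial of ``which`` role before
    ``trial``: the CS memory distribution."""
    if which not in (Role.CS_PLUS, Role.CS_MINUS):
        raise ValueError("which must be CS_PLUS or CS_MINUS")
    for j in range(trial - 1, -1, -1):
        if schedule.stimuli.roles[schedule.entries[j].stimulus] is which:
            return PerceptualDistribution(states[j].mu_psi, states[j].sigma_psi)
    raise ValueError(f"no {which.value} trial precedes trial {trial}")


@dataclass
class DistanceSeries:
    """Per-trial distances to CS+ (and CS- in differential designs)."""

    metric: Metric
    d_plus: np.ndarray
    d_minus: np.ndarray | None = None
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.d_plus)

    def normalize(self) -> "DistanceSeries":
        """Rescale by the series maximum so distances are comparable across
        metrics (and the generalization rate lambda across pathways)."""
        scale = float(np.max(self.d_plus))
        if self.d_minus is not None:
            scale = max(scale, float(np.max(self.d_minus)))
        if scale <= 0:
            scale = 1.0
        return DistanceSeries(
            self.metric,
            self.d_plus / scale,
            None if self.d_minus is None else self.d_minus / scale,
            normalized=True,
        )

    def to_frame(self, participant: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant": participant,
                "trial": np.arange(len(self.d_plus)),
                "metric": self.metric.value,
                "d_plus": self.d_plus,
            }
        )
        df["d_minus"] = self.d_minus if self.d_minus is not None else np.nan
        return df


def _series_against(
    schedule: TrialSchedule,
    which: Role,
    metric: Metric,
    ratings: np.ndarray | None,
    mu_psi: np.ndarray | None,
    sigma_psi: np.ndarray | None,
) -> np.ndarray:
    roles = [schedule.stimuli.roles[e.stimulus] for e in schedule.entries]
    T = len(schedule)
    d = np.zeros(T)
    if metric is Metric.PHYSICAL:
        cs_label = schedule.stimuli.cs_plus if which is Role.CS_PLUS else schedule.stimuli.cs_minus
        x_cs = schedule.stimuli.diameter(cs_label)
        for j, e in enumerate(schedule.entries):
            d[j] = physical_distance(x_cs, schedule.stimuli.diameter(e.stimulus))
        return d
    if metric is Metric.POINT:
        hist: list[float] = []
        for j in range(T):
            if hist:
                d[j] = point_distance(hist, float(ratings[j]))
            else:
                d[j] = 0.0  # no CS memory yet; v=0 there so g is 0 regardless
            if roles[j] is which:
                hist.append(float(ratings[j]))
        return d
    # OVERLAP
    last: tuple[float, float] | None = None
    for j in range(T):
        if last is not None:
            d[j] = overlap_distance(
                PerceptualDistribution(float(mu_psi[j]), float(sigma_psi[j])),
                PerceptualDistribution(last[0], last[1]),
            )
        else:
            d[j] = 0.0
        if roles[j] is which:
            last = (float(mu_psi[j]), float(sigma_psi[j]))
    return d


def build_distance_series(
    schedule: TrialSchedule,
    metric: Metric,
    ratings: np.ndarray | None = None,
    mu_psi: np.ndarray | None = None,
    sigma_psi: np.ndarray | None = None,
    normalize: bool = False,
) -> DistanceSeries:
    """Per-trial distance series to CS+ (and CS- for differential designs).

    POINT requires per-trial size ratings; OVERLAP requires per-trial
    posterior-median perceptual states (mu_psi, sigma_psi).  Trials before
    the first CS trial of a role get distance 0 to that role's memory (the
    associative strength is still at zero there, so the value is inert).
    """
    if metric is Metric.POINT and ratings is None:
        raise ValueError("POINT metric requires size ratings")
    if metric is Metric.OVERLAP and (mu_psi is None or sigma_psi is None):
        raise ValueError("OVERLAP metric requires fitted perceptual states")
    d_plus = _series_against(schedule, Role.CS_PLUS, metric, ratings, mu_psi, sigma_psi)
    d_minus = None
    if schedule.stimuli.cs_minus is not None:
        d_minus = _series_against(
            schedule, Role.CS_MINUS, metric, ratings, mu_psi, sigma_psi
        )
    series = DistanceSeries(metric, d_plus, d_minus)
    return series.normalize() if normalize else series
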