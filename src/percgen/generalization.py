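"""Error-driven learning, similarity-decay generalization, response mapping.

The associative strength v of a conditioned stimulus is updated on CS trials
by the Rescorla-Wagner delta rule

    v' = v + alpha * (r - v) * k,

with learning rate alpha in [0, 1], outcome r (CS+: 1 = shock, 0 = omitted;
CS-: -1 on every trial, encoding the no-shock outcome that drives inhibitory
learning) and update indicator k (1 on CS trials, 0 on test-stimulus trials).
Learned strength transfers to other stimuli along a Shepard exponential
gradient of the trial-wise stimulus distance d:

    g = v+ * exp(-lambda * d+)                      (simple conditioning)
    g = v+ * exp(-lambda * d+) + v- * exp(-lambda * d-)   (differential)

and is mapped to the 1-10 shock-expectancy scale by a sigmoid

    theta = A + (K - A) / (1 + exp(-(w0 + w1 * g))),   A = 1, K = 10,

with Gaussian response noise: y ~ N(theta, sigma^2).

Four latent groups structure the population: Non-Learners (alpha = 0, flat
baseline responding with their own noise class), Overgeneralizers (lambda
small enough that similarity exceeds 70% even at the largest distance),
Physical Generalizers (distances on the physical dimension) and Perceptual
Generalizers (distances on the perceived dimension).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .design import TrialSchedule
from .distances import DistanceSeries
from .perception import gaussian_loglik

RESPONSE_FLOOR = 1.0  # A: lower asymptote of the response scale
RESPONSE_CEIL = 10.0  # K: upper asymptote

#: similarity retained by Overgeneralizers at the largest distance
OVERGEN_SIMILARITY = 0.7


class Group(enum.IntEnum):
    NON_LEARNER = 0
    OVERGENERALIZER = 1
    PHYSICAL = 2
    PERCEPTUAL = 3


@dataclass
class GenParams:
    """Participant-level generalization parameters."""

    alpha: float  # learning rate in [0, 1]
    lam: float  # generalization (similarity-decay) rate >= 0
    w0: float  # baseline response (sigmoid offset)
    w1: float  # response scaling (sigmoid slope)
    group: Group = Group.PERCEPTUAL

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def rw_update(v: float, alpha: float, r: float, k: int) -> float:
    """One Rescorla-Wagner step; k = 0 leaves v unchanged."""
    return v + alpha * (r - v) * k


def generalize(
    v_plus: float,
    lam: float,
    d_plus: float,
    v_minus: float = 0.0,
    d_minus: float = 0.0,
    design: str = "simple",
) -> float:
    """Generalized associative strength under exponential similarity decay."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    g = v_plus * np.exp(-lam * d_plus)
    if design == "differential":
        g = g + v_minus * np.exp(-lam * d_minus)
    return float(g)


def response_mean(g: float | np.ndarray, w0: float, w1: float) -> float | np.ndarray:
    """Sigmoid mapping of latent strength to the 1-10 expectancy scale."""
    return RESPONSE_FLOOR + (RESPONSE_CEIL - RESPONSE_FLOOR) / (
        1.0 + np.exp(-(w0 + w1 * np.asarray(g)))
    )


def response_loglik(
    y: np.ndarray, theta: np.ndarray, sigma: float
) -> float:
    """Sum of log N(y | theta, sigma^2) over trials."""
    y = np.asarray(y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if y.size == 0:
        return 0.0
    return float(gaussian_loglik(y, np.asarray(theta, dtype=float), sigma))


def overgeneralizer_lambda_bound(d_max: float) -> float:
    """Critical decay rate: lambda below this keeps exp(-lambda*d) above 70%
    at the largest observed distance d_max."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    return -np.log(OVERGEN_SIMILARITY) / d_max


def forward_values(
    schedule: TrialSchedule, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-wise associative strengths (v_plus, v_minus) before each trial's
    response, updated after CS trials (including generalization-phase CS
    trials: re-acquisition keeps learning live)."""
    T = len(schedule)
    v_plus = np.zeros(T)
    v_minus = np.zeros(T)
    vp = vm = 0.0
    roles = [schedule.stimuli.roles[e.stimulus] for e in schedule.entries]
    for j, e in enumerate(schedule.entries):
        v_plus[j], v_minus[j] = vp, vm
        if e.k == 1:
            if roles[j].value == "CS_PLUS":
                vp = rw_update(vp, alpha, e.r, 1)
            else:
                vm = rw_update(vm, alpha, e.r, 1)
    return v_plus, v_minus


def forward_theta(
    schedule: TrialSchedule,
    params: GenParams,
    distances: DistanceSeries,
) -> np.ndarray:
    """Noiseless response means theta for every trial.

    Non-Learners respond at the w0-only baseline; the learner groups run the
    full learning -> generalization -> response chain on the supplied
    distance series.
    """
    T = len(schedule)
    if len(distances) != T:
        raise ValueError("distances do not match schedule length")
    if params.group is Group.NON_LEARNER:
        return np.full(T, response_mean(0.0, params.w0, 0.0))
    v_plus, v_minus = forward_values(schedule, params.alpha)
    design = "differential" if distances.d_minus is not None else "simple"
    g = v_plus * np.exp(-params.lam * distances.d_plus)
    if design == "differential":
        g = g + v_minus * np.exp(-params.lam * distances.d_minus)
    return np.asarray(response_mean(g, params.w0, params.w1))


def simulate_responses(
    schedule: TrialSchedule,
    params: GenParams,
    distances: DistanceSeries,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a shock-expectancy series: Gaussian noise around theta, clipped
    to the 1-10 scale at emission."""
    theta = forward_theta(schedule, params, distances)
    y = rng.normal(theta, sigma)
    return np.clip(y, RESPONSE_FLOOR, RESPONSE_CEIL)
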