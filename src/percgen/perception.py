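"""Dynamic Bayesian perceptual model (Kalman-filter state space).

Physical circle diameters are mapped to the 0-200 mm size-rating scale by a
participant-specific sigmoid

    mu_S = Omega / (1 + exp(-(beta0 + beta1 * x))),        Omega = 200,

with sensory noise sigma_S.  A single latent perceptual state per participant
(mean mu_psi, uncertainty sigma_psi) evolves across trials by Kalman-gain
integration of the sensory mean:

    gain    = sigma_psi / (sigma_psi + sigma_S)
    mu'     = mu_psi + gain * (mu_S' - mu_psi)
    sigma'  = (1 - gain) * sigma_psi + eta * exp(-omega * j)

where the process-noise term eta * exp(-omega * j) decays with the 0-based
trial index j, eta being the initial uncertainty magnitude and omega the
participant-specific decay rate.  The gain is the standard-deviation ratio,
not the textbook variance ratio — deliberately so.

The observed size rating on trial j is modeled as N(mu_psi_j, sigma_psi_j^2);
ratings are truncated to [0, 200] only when simulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OMEGA_SCALE = 200.0  # rating-scale ceiling


@dataclass
class PerceptParams:
    """Participant-level perceptual parameters."""

    beta0: float  # sigmoid offset
    beta1: float  # sigmoid slope, per mm
    sigma_S: float  # sensory-mapping noise, rating units (> 0)
    omega: float  # process-noise decay rate, per trial (>= 0)

    def __post_init__(self) -> None:
        if self.sigma_S <= 0:
            raise ValueError("sigma_S must be positive")
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")


@dataclass
class GroupPerceptParams:
    """Population-level perceptual parameters."""

    mu_beta0: float = 0.0
    mu_beta1: float = 0.0
    mu_omega: float = 0.0
    sd_beta0: float = 2.5
    sd_beta1: float = 0.05
    sd_omega: float = 0.05
    eta: float = 11.0  # initial process-noise magnitude, rating units
    Omega: float = OMEGA_SCALE

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass
class PerceptState:
    """Perceptual state after trial j."""

    trial: int
    mu_S: float
    mu_psi: float
    sigma_psi: float
    kalman_gain: float


def sensory_mean(
    x: float | np.ndarray, params: PerceptParams, Omega: float = OMEGA_SCALE
) -> float | np.ndarray:
    """Sigmoid sensory mapping from diameter (mm) to the rating scale."""
    if Omega <= 0:
        raise ValueError("Omega must be positive")
    return Omega / (1.0 + np.exp(-(params.beta0 + params.beta1 * np.asarray(x))))


def sample_sensory(
    mu_S: float, sigma_S: float, rng: np.random.Generator
) -> float:
    """One draw of the noisy sensory percept psi_S ~ N(mu_S, sigma_S^2)."""
    if sigma_S < 0:
        raise ValueError("sigma_S must be nonnegative")
    return float(rng.normal(mu_S, sigma_S))


def kalman_gain(sigma_psi: float, sigma_S: float) -> float:
    """Weight on new sensory evidence: sigma_psi / (sigma_psi + sigma_S)."""
    if sigma_psi < 0:
        raise ValueError("sigma_psi must be nonnegative")
    if sigma_psi == 0 and sigma_S == 0:
        raise ValueError("sigma_psi and sigma_S cannot both be zero")
    return sigma_psi / (sigma_psi + sigma_S)


def update_mean(mu_psi: float, mu_S_new: float, gain: float) -> float:
    """Kalman mean update: convex combination of prior and sensory means."""
    return mu_psi + gain * (mu_S_new - mu_psi)


def update_uncertainty(
    sigma_psi: float, gain: float, eta: float, omega: float, j: int
) -> float:
    """Uncertainty update: shrink by (1-gain), add decaying process noise."""
    return (1.0 - gain) * sigma_psi + eta * np.exp(-omega * j)


def filter_trajectory(
    diameters_mm: np.ndarray,
    params: PerceptParams,
    group: GroupPerceptParams,
) -> list[PerceptState]:
    """Run the perceptual filter over a stimulus sequence.

    The first trial initializes mu_psi to that trial's sensory mean and
    sigma_psi to eta (gain 1: no prior experience exists).  Thereafter the
    state at trial j serves as the prior for trial j+1 regardless of which
    stimulus was shown.
    """
    x = np.asarray(diameters_mm, dtype=float)
    if x.size == 0:
        raise ValueError("empty stimulus sequence")
    mu_S = np.asarray(sensory_mean(x, params, group.Omega), dtype=float)
    states: list[PerceptState] = []
    mu_psi = float(mu_S[0])
    sigma_psi = group.eta
    states.append(PerceptState(0, float(mu_S[0]), mu_psi, sigma_psi, 1.0))
    for j in range(1, x.size):
        gain = kalman_gain(sigma_psi, params.sigma_S)
        mu_psi = update_mean(mu_psi, float(mu_S[j]), gain)
        # decay term indexed by the source trial (0-based), per the recursion
        sigma_psi = update_uncertainty(sigma_psi, gain, group.eta, params.omega, j - 1)
        states.append(PerceptState(j, float(mu_S[j]), mu_psi, sigma_psi, gain))
    return states


def trajectory_arrays(
    diameters_mm: np.ndarray,
    beta0: np.ndarray,
    beta1: np.ndarray,
    sigma_S: np.ndarray,
    omega: np.ndarray,
    eta: np.ndarray | float,
    Omega: float = OMEGA_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized filter over trailing batch dimensions.

    ``diameters_mm`` has shape (T,) or (T, *batch); the parameter arrays share
    a common batch shape.  Returns (mu_psi, sigma_psi), each (T, *batch).
    Used by the fitting machinery, where thousands of trajectory evaluations
    are needed; `filter_trajectory` is the scalar reference path.
    """
    x = np.asarray(diameters_mm, dtype=float)
    beta0 = np.asarray(beta0, dtype=float)
    batch = beta0.shape
    if x.ndim == 1 and batch:
        x = x.reshape((x.shape[0],) + (1,) * len(batch))
    T = x.shape[0]
    with np.errstate(over="ignore"):
        mu_S = Omega / (1.0 + np.exp(-(beta0 + beta1 * x)))
    mu = np.empty((T,) + batch)
    sig = np.empty((T,) + batch)
    mu[0] = mu_S[0]
    sig[0] = eta
    decay = np.exp(-np.asarray(omega, dtype=float))
    noise = eta * np.ones(batch) if np.ndim(eta) == 0 else np.broadcast_to(eta, batch).copy()
    for j in range(1, T):
        gain = sig[j - 1] / (sig[j - 1] + sigma_S)
        mu[j] = mu[j - 1] + gain * (mu_S[j] - mu[j - 1])
        sig[j] = (1.0 - gain) * sig[j - 1] + noise
        noise = noise * decay  # eta * exp(-omega * (j-1)) rolled forward
    return mu, sig


def perceptual_loglik(
    ratings: np.ndarray, states: list[PerceptState]
) -> float:
    """Sum of log N(rating_j | mu_psi_j, sigma_psi_j^2) over trials."""
    y = np.asarray(ratings, dtype=float)
    if y.size != len(states):
        raise ValueError("ratings and states must have equal length")
    if y.size == 0:
        return 0.0
    mu = np.array([s.mu_psi for s in states])
    sd = np.array([s.sigma_psi for s in states])
    if np.any(sd <= 0):
        raise ValueError("nonpositive sigma_psi in states")
    z = (y - mu) / sd
    return float(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)))


def gaussian_loglik(
    y: np.ndarray, mu: np.ndarray, sd: np.ndarray | float, axis: int | None = 0
) -> np.ndarray:
    """Vectorized Gaussian log likelihood summed along ``axis``."""
    sd = np.asarray(sd, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        z = (y - mu) / sd
        ll = -0.5 * z**2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)
    return np.sum(ll, axis=axis) if axis is not None else ll


@dataclass
class PerceptPriors:
    """Hyperpriors for the hierarchical perceptual model (all overridable)."""

    mu_beta0_sd: float = 5.0
    mu_beta1_sd: float = 0.1
    sd_beta0_scale: float = 2.5
    sd_beta1_scale: float = 0.05
    sigma_S_scale: float = 5.0
    mu_omega_scale: float = 0.05
    sd_omega_scale: float = 0.05
    eta_scale: float = 20.0
    extra: dict = field(default_factory=dict)
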