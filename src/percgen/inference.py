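"""Two-step hierarchical Bayesian fitting by Metropolis-within-Gibbs MCMC.

Step one fits the perceptual state-space model to size ratings alone; step
two fits the latent-mixture generalization model to shock-expectancy ratings
using precomputed distance series (the generalization fit never re-estimates
perception, so perceptual assumptions cannot leak into the model comparison).

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme run
simultaneously for all chains and participants as one vectorized batch:
participant-level parameters are conditionally independent given the
population-level parameters, so a whole cross-participant block is proposed
and accepted elementwise in a single numpy operation.  Proposal scales adapt
toward a 0.44 acceptance rate during burn-in and are frozen afterwards.
The discrete group indicator of the mixture is marginalized out of every
continuous-parameter conditional (log-sum-exp over the four pathways); the
group-probability vector pi is refreshed through a momentary data
augmentation (sample indicators, then a conjugate Dirichlet draw, then
discard the indicators).

Presets: ``paper`` mirrors the published chain settings (4 chains x 100,000
iterations, 75,000 burn-in, thin 10 -> 10,000 retained draws; the super model
uses 4 x 250,000, 100,000 burn-in, thin 5 -> 120,000); ``desk`` (4 x 2,000,
1,000 burn-in) runs in minutes and is the default for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp, ndtri

from .design import Role, TrialSchedule
from .distances import DistanceSeries, Metric
from .generalization import RESPONSE_CEIL, RESPONSE_FLOOR, Group, overgeneralizer_lambda_bound
from .perception import PerceptPriors, gaussian_loglik, trajectory_arrays

_TARGET_ACCEPT = 0.44
_ADAPT_GAMMA = 0.05


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    iterations: int = 2_000
    burn_in: int = 1_000
    thin: int = 1
    seed: int = 0
    backend: str = "mwg"  # Metropolis-within-Gibbs, the in-package sampler

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.burn_in) // self.thin


PRESETS: dict[str, MCMCConfig] = {
    "paper": MCMCConfig(chains=4, iterations=100_000, burn_in=75_000, thin=10),
    "paper_super": MCMCConfig(chains=4, iterations=250_000, burn_in=100_000, thin=5),
    "desk": MCMCConfig(chains=4, iterations=2_000, burn_in=1_000, thin=1),
}


def preset(name: str, seed: int = 0) -> MCMCConfig:
    return replace(PRESETS[name], seed=seed)


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n): m >= 2 chains of n draws each.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


@dataclass
class PosteriorSummary:
    """Retained MCMC draws with quantile and convergence accessors.

    Draw arrays are keyed by parameter name with shape (chains, kept) for
    population-level scalars and (chains, kept, n_participants) for
    participant-level vectors.
    """

    draws: dict[str, np.ndarray]
    participants: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        first = next(iter(self.draws.values()))
        return first.shape[0] * first.shape[1]

    def quantiles(self, name: str, qs=(2.5, 25, 50, 75, 97.5)) -> np.ndarray:
        d = self.draws[name]
        flat = d.reshape(-1, *d.shape[2:])
        return np.percentile(flat, qs, axis=0)

    def median(self, name: str) -> np.ndarray | float:
        q = self.quantiles(name, qs=(50,))[0]
        return float(q) if np.ndim(q) == 0 else q

    def rhat(self, name: str) -> np.ndarray | float:
        d = self.draws[name]
        if d.ndim == 2:
            return rhat(d)
        return np.array([rhat(d[:, :, i]) for i in range(d.shape[2])])

    def max_rhat(self, names: list[str] | None = None) -> float:
        names = names if names is not None else list(self.draws)
        return float(max(np.max(self.rhat(n)) for n in names))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, d in self.draws.items():
            qs = self.quantiles(name)
            rh = self.rhat(name)
            if d.ndim == 2:
                rows.append(
                    {"parameter": name, "index": -1, "rhat": float(rh),
                     **{f"q{p}": float(q) for p, q in zip((2.5, 25, 50, 75, 97.5), qs)}}
                )
            else:
                for i in range(d.shape[2]):
                    rows.append(
                        {"parameter": name, "index": i, "rhat": float(rh[i]),
                         **{f"q{p}": float(qs[k, i]) for k, p in enumerate((2.5, 25, 50, 75, 97.5))}}
                    )
        return pd.DataFrame(rows)


class _Adaptive:
    """Elementwise random-walk proposal with Robbins-Monro scale adaptation."""

    def __init__(self, shape, scale=0.1):
        self.scale = np.full(shape, float(scale))

    def propose(self, value: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # occasional 5x jumps help hop between pathway-induced posterior modes
        boost = np.where(rng.uniform(size=value.shape) < 0.1, 5.0, 1.0)
        return value + boost * self.scale * rng.standard_normal(value.shape)

    def adapt(self, accepted: np.ndarray) -> None:
        self.scale *= np.exp(_ADAPT_GAMMA * (accepted - _TARGET_ACCEPT))


def _accept(lp_new: np.ndarray, lp_old: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Elementwise Metropolis acceptance mask."""
    with np.errstate(invalid="ignore"):
        logr = np.where(np.isfinite(lp_new), lp_new - lp_old, -np.inf)
    return np.log(rng.uniform(size=lp_new.shape)) < logr


def _halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, -0.5 * (x / scale) ** 2, -np.inf)
    return out  # unnormalized is fine inside MH ratios of fixed scale


def _normal_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd)


# --------------------------------------------------------------------------
# Step 1: perceptual model
# --------------------------------------------------------------------------

@dataclass
class PerceptualFit:
    summary: PosteriorSummary
    state_mu: np.ndarray  # (T, n) posterior-median perceptual means
    state_sigma: np.ndarray  # (T, n) posterior-median perceptual uncertainties
    participants: list
    config: MCMCConfig

    def replicate_ratings(
        self, n_rep: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Posterior-predictive size ratings: (n_rep, T, n) draws from the
        fitted per-trial perceptual distributions, truncated to [0, 200]."""
        draws = rng.normal(
            self.state_mu[None], self.state_sigma[None],
            size=(n_rep,) + self.state_mu.shape,
        )
        return np.clip(draws, 0.0, 200.0)

    def states_frame(self) -> pd.DataFrame:
        T, n = self.state_mu.shape
        return pd.DataFrame(
            {
                "participant": np.repeat(self.participants, T),
                "trial": np.tile(np.arange(T), n),
                "mu_psi": self.state_mu.T.ravel(),
                "sigma_psi": self.state_sigma.T.ravel(),
            }
        )


def _pivot(data: pd.DataFrame, col: str) -> tuple[np.ndarray, list]:
    wide = data.pivot(index="trial", columns="participant", values=col).sort_index()
    return wide.to_numpy(dtype=float), list(wide.columns)


def fit_perceptual(
    data: pd.DataFrame,
    config: MCMCConfig,
    priors: PerceptPriors | None = None,
) -> PerceptualFit:
    """Fit the hierarchical perceptual model to size ratings.

    ``data`` is the long-format trial table with columns participant, trial,
    diameter_mm and size_rating; expectancy ratings are never consulted.
    Returns posterior draws for the participant-level parameters (beta0,
    beta1, sigma_S, omega), the population-level parameters (mu/sd of each,
    eta) and per-trial posterior-median perceptual states.
    """
    priors = priors or PerceptPriors()
    x, participants = _pivot(data, "diameter_mm")
    y, _ = _pivot(data, "size_rating")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("unbalanced trial table: every participant needs every trial")
    T, n = x.shape
    C = config.chains
    rng = np.random.default_rng(config.seed)
    xb = x[:, None, :]  # broadcast over chains
    yb = y[:, None, :]

    # data-informed initialization, jittered per chain
    p = np.clip(y / 200.0, 0.02, 0.98)
    lo = np.log(p / (1 - p))
    xc = x - x.mean(0)
    b1_init = (xc * (lo - lo.mean(0))).sum(0) / (xc**2).sum(0)
    b0_init = lo.mean(0) - b1_init * x.mean(0)
    b0 = b0_init + 0.3 * rng.standard_normal((C, n))
    b1 = b1_init + 0.01 * rng.standard_normal((C, n))
    lsS = np.log(1.0) + 0.3 * rng.standard_normal((C, n))
    lom = np.log(0.005) + 0.3 * rng.standard_normal((C, n))
    leta = np.log(np.maximum(y.std(0).mean(), 1.0)) + 0.1 * rng.standard_normal(C)
    mu_b0 = b0.mean(1)
    sd_b0 = np.full(C, 1.0)
    mu_b1 = b1.mean(1)
    sd_b1 = np.full(C, 0.02)
    mu_om = np.full(C, 0.005)
    sd_om = np.full(C, 0.01)

    def loglik(b0, b1, lsS, lom, leta):
        mu, sig = trajectory_arrays(
            xb, b0, b1, np.exp(lsS), np.exp(lom), np.exp(leta)[:, None]
        )
        return gaussian_loglik(yb, mu, sig, axis=0)  # (C, n)

    ll = loglik(b0, b1, lsS, lom, leta)

    def prior_b0(v):
        return _normal_logpdf(v, mu_b0[:, None], sd_b0[:, None])

    def prior_b1(v):
        return _normal_logpdf(v, mu_b1[:, None], sd_b1[:, None])

    def prior_lsS(v):  # sigma_S ~ HalfNormal(scale); jacobian of log transform
        return _halfnormal_logpdf(np.exp(v), priors.sigma_S_scale) + v

    def prior_lom(v):  # omega ~ Normal(mu_om, sd_om) truncated to [0, inf)
        om = np.exp(v)
        return _normal_logpdf(om, mu_om[:, None], sd_om[:, None]) + v

    steps = {
        "b0": _Adaptive((C, n), 0.2),
        "b1": _Adaptive((C, n), 0.005),
        "lsS": _Adaptive((C, n), 0.3),
        "lom": _Adaptive((C, n), 0.5),
        "leta": _Adaptive((C,), 0.05),
        "sd_b0": _Adaptive((C,), 0.3),
        "sd_b1": _Adaptive((C,), 0.3),
        "mu_om": _Adaptive((C,), 0.3),
        "sd_om": _Adaptive((C,), 0.3),
    }

    kept = (config.iterations - config.burn_in) // config.thin
    out = {
        "beta0": np.empty((C, kept, n)), "beta1": np.empty((C, kept, n)),
        "sigma_S": np.empty((C, kept, n)), "omega": np.empty((C, kept, n)),
        "eta": np.empty((C, kept)), "mu_beta0": np.empty((C, kept)),
        "mu_beta1": np.empty((C, kept)), "mu_omega": np.empty((C, kept)),
        "sd_beta0": np.empty((C, kept)), "sd_beta1": np.empty((C, kept)),
        "sd_omega": np.empty((C, kept)),
    }
    state_thin = max(1, kept // 250)
    mu_acc: list[np.ndarray] = []
    sig_acc: list[np.ndarray] = []
    k = 0
    xbar = x.mean(0)  # slope updates pivot the sigmoid around the mean diameter
    for it in range(config.iterations):
        warm = it < config.burn_in
        # participant-level blocks (elementwise accept across chains x participants)
        for name, cur, prior in (
            ("b0", b0, prior_b0),
            ("lsS", lsS, prior_lsS), ("lom", lom, prior_lom),
        ):
            prop = steps[name].propose(cur, rng)
            args = {"b0": b0, "b1": b1, "lsS": lsS, "lom": lom}
            args[name] = prop
            ll_new = loglik(args["b0"], args["b1"], args["lsS"], args["lom"], leta)
            acc = _accept(ll_new + prior(prop), ll + prior(cur), rng)
            cur[acc] = prop[acc]
            ll[acc] = ll_new[acc]
            if warm:
                steps[name].adapt(acc)
        # slope block: b0 and b1 are strongly anticorrelated, so move them
        # jointly along the direction that fixes the value at the mean diameter
        delta = steps["b1"].scale * rng.standard_normal((C, n))
        b1_prop = b1 + delta
        b0_prop = b0 - delta * xbar
        ll_new = loglik(b0_prop, b1_prop, lsS, lom, leta)
        acc = _accept(
            ll_new + prior_b0(b0_prop) + prior_b1(b1_prop),
            ll + prior_b0(b0) + prior_b1(b1), rng,
        )
        b0[acc] = b0_prop[acc]
        b1[acc] = b1_prop[acc]
        ll[acc] = ll_new[acc]
        if warm:
            steps["b1"].adapt(acc)
        # shared eta (one per chain)
        prop = steps["leta"].propose(leta, rng)
        ll_new = loglik(b0, b1, lsS, lom, prop)
        lp_new = ll_new.sum(1) + _halfnormal_logpdf(np.exp(prop), priors.eta_scale) + prop
        lp_old = ll.sum(1) + _halfnormal_logpdf(np.exp(leta), priors.eta_scale) + leta
        acc = _accept(lp_new, lp_old, rng)
        leta[acc] = prop[acc]
        ll[acc] = ll_new[acc]
        if warm:
            steps["leta"].adapt(acc)
        # population means: conjugate normal draws
        for vals, mu_arr, sd_arr, prior_sd in (
            (b0, mu_b0, sd_b0, priors.mu_beta0_sd),
            (b1, mu_b1, sd_b1, priors.mu_beta1_sd),
        ):
            prec = n / sd_arr**2 + 1.0 / prior_sd**2
            mean = (vals.sum(1) / sd_arr**2) / prec
            mu_arr[:] = mean + rng.standard_normal(C) / np.sqrt(prec)
        # population spreads and omega hyperparameters: cheap MH
        for name, mu_arr, sd_arr, vals, scale in (
            ("sd_b0", mu_b0, sd_b0, b0, priors.sd_beta0_scale),
            ("sd_b1", mu_b1, sd_b1, b1, priors.sd_beta1_scale),
        ):
            prop = sd_arr * np.exp(steps[name].propose(np.zeros(C), rng))
            lp_new = (_normal_logpdf(vals, mu_arr[:, None], prop[:, None]).sum(1)
                      + _halfnormal_logpdf(prop, scale) + np.log(prop))
            lp_old = (_normal_logpdf(vals, mu_arr[:, None], sd_arr[:, None]).sum(1)
                      + _halfnormal_logpdf(sd_arr, scale) + np.log(sd_arr))
            acc = _accept(lp_new, lp_old, rng)
            sd_arr[acc] = prop[acc]
            if warm:
                steps[name].adapt(acc)
        # omega_i ~ Normal(mu_om, sd_om) truncated to [0, inf): the truncation
        # normalizer Phi(mu/sd) depends on the hyperparameters, so it appears
        # in their conditionals (it cancels in the omega_i updates).
        om = np.exp(lom)
        prop = mu_om + steps["mu_om"].scale * rng.standard_normal(C)
        lp_new = (_normal_logpdf(om, prop[:, None], sd_om[:, None]).sum(1)
                  - n * _safe_log_ndtr(prop / sd_om)
                  + _halfnormal_logpdf(prop, priors.mu_omega_scale))
        lp_old = (_normal_logpdf(om, mu_om[:, None], sd_om[:, None]).sum(1)
                  - n * _safe_log_ndtr(mu_om / sd_om)
                  + _halfnormal_logpdf(mu_om, priors.mu_omega_scale))
        acc = _accept(lp_new, lp_old, rng)
        mu_om[acc] = prop[acc]
        if warm:
            steps["mu_om"].adapt(acc)
        prop = sd_om * np.exp(steps["sd_om"].propose(np.zeros(C), rng))
        lp_new = (_normal_logpdf(om, mu_om[:, None], prop[:, None]).sum(1)
                  - n * _safe_log_ndtr(mu_om / prop)
                  + _halfnormal_logpdf(prop, priors.sd_omega_scale) + np.log(prop))
        lp_old = (_normal_logpdf(om, mu_om[:, None], sd_om[:, None]).sum(1)
                  - n * _safe_log_ndtr(mu_om / sd_om)
                  + _halfnormal_logpdf(sd_om, priors.sd_omega_scale) + np.log(sd_om))
        acc = _accept(lp_new, lp_old, rng)
        sd_om[acc] = prop[acc]
        if warm:
            steps["sd_om"].adapt(acc)

        if not warm and (it - config.burn_in) % config.thin == 0:
            out["beta0"][:, k] = b0
            out["beta1"][:, k] = b1
            out["sigma_S"][:, k] = np.exp(lsS)
            out["omega"][:, k] = np.exp(lom)
            out["eta"][:, k] = np.exp(leta)
            out["mu_beta0"][:, k] = mu_b0
            out["mu_beta1"][:, k] = mu_b1
            out["mu_omega"][:, k] = mu_om
            out["sd_beta0"][:, k] = sd_b0
            out["sd_beta1"][:, k] = sd_b1
            out["sd_omega"][:, k] = sd_om
            if k % state_thin == 0:
                mu_t, sig_t = trajectory_arrays(
                    xb, b0, b1, np.exp(lsS), np.exp(lom), np.exp(leta)[:, None]
                )
                mu_acc.append(mu_t.reshape(T, C * n).copy())
                sig_acc.append(sig_t.reshape(T, C * n).copy())
            k += 1

    mu_stack = np.stack(mu_acc)  # (draws, T, C*n)
    sig_stack = np.stack(sig_acc)
    state_mu = np.median(
        mu_stack.reshape(len(mu_acc), T, C, n), axis=(0, 2)
    )
    state_sigma = np.median(
        sig_stack.reshape(len(sig_acc), T, C, n), axis=(0, 2)
    )
    summary = PosteriorSummary(out, participants)
    return PerceptualFit(summary, state_mu, state_sigma, participants, config)


# --------------------------------------------------------------------------
# Step 2: latent-mixture generalization model
# --------------------------------------------------------------------------

@dataclass
class GenPriors:
    """Priors for the generalization model (all overridable)."""

    lam_scale: float = 2.0  # Half-Normal scale for lambda, truncated by group
    w0_sd: float = 2.0
    w1_sd: float = 5.0
    sigma_learner_scale: float = 2.0
    sigma_nonlearner_scale: float = 5.0
    dirichlet: tuple = (1.0, 1.0, 1.0, 1.0)


@dataclass
class GenData:
    """Per-participant trial arrays consumed by the generalization fit.

    All participants share the trial count T.  ``d_phys`` and ``d_perc`` are
    normalized distance series ((T, n) arrays; the *_minus entries are None
    for simple conditioning).
    """

    y: np.ndarray  # (T, n) expectancy ratings
    is_cs_plus: np.ndarray  # (T, n) bool
    is_cs_minus: np.ndarray  # (T, n) bool
    r: np.ndarray  # (T, n) outcomes
    d_phys_plus: np.ndarray
    d_perc_plus: np.ndarray
    d_phys_minus: np.ndarray | None = None
    d_perc_minus: np.ndarray | None = None
    participants: list = field(default_factory=list)
    metric: Metric = Metric.OVERLAP

    @property
    def differential(self) -> bool:
        return self.d_phys_minus is not None


def build_gen_data(
    schedules: list[TrialSchedule],
    expectancy: np.ndarray,
    phys: list[DistanceSeries],
    perc: list[DistanceSeries],
    participants: list | None = None,
) -> GenData:
    """Assemble GenData from per-participant schedules and distance series."""
    n = len(schedules)
    T = len(schedules[0])
    y = np.asarray(expectancy, dtype=float)
    if y.shape != (T, n):
        raise ValueError("expectancy must have shape (T, n_participants)")
    isp = np.zeros((T, n), dtype=bool)
    ism = np.zeros((T, n), dtype=bool)
    r = np.zeros((T, n))
    for i, sch in enumerate(schedules):
        roles = [sch.stimuli.roles[e.stimulus] for e in sch.entries]
        isp[:, i] = [ro is Role.CS_PLUS for ro in roles]
        ism[:, i] = [ro is Role.CS_MINUS for ro in roles]
        r[:, i] = [e.r for e in sch.entries]
    differential = phys[0].d_minus is not None
    stack = lambda ss, attr: np.stack([getattr(s, attr) for s in ss], axis=1)
    return GenData(
        y=y, is_cs_plus=isp, is_cs_minus=ism, r=r,
        d_phys_plus=stack(phys, "d_plus"),
        d_perc_plus=stack(perc, "d_plus"),
        d_phys_minus=stack(phys, "d_minus") if differential else None,
        d_perc_minus=stack(perc, "d_minus") if differential else None,
        participants=participants if participants is not None else list(range(n)),
        metric=perc[0].metric,
    )


@dataclass
class GeneralizationFit:
    summary: PosteriorSummary
    membership: np.ndarray  # (n, 4) posterior group-membership probabilities
    participants: list
    config: MCMCConfig

    def modal_group(self) -> np.ndarray:
        return self.membership.argmax(axis=1)

    def membership_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.membership, columns=[g.name for g in Group])
        df.insert(0, "participant", self.participants)
        return df


def _values_batch(alpha: np.ndarray, data: GenData) -> tuple[np.ndarray, np.ndarray]:
    """Associative-strength trajectories (T, C, n) for alpha of shape (C, n)."""
    T, n = data.y.shape
    C = alpha.shape[0]
    vp = np.zeros((C, n))
    vm = np.zeros((C, n))
    v_plus = np.empty((T, C, n))
    v_minus = np.empty((T, C, n))
    for j in range(T):
        v_plus[j] = vp
        v_minus[j] = vm
        p = data.is_cs_plus[j]
        m = data.is_cs_minus[j]
        if p.any():
            vp = np.where(p, vp + alpha * (data.r[j] - vp), vp)
        if m.any():
            vm = np.where(m, vm + alpha * (data.r[j] - vm), vm)
    return v_plus, v_minus


def _htrunc_ppf(u: np.ndarray, scale: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Quantile function of Half-Normal(scale) truncated to [lo, hi)."""
    Flo = 2.0 * _ndtr(lo / scale) - 1.0
    Fhi = 2.0 * _ndtr(hi / scale) - 1.0
    p = Flo + u * (Fhi - Flo)
    return scale * ndtri((np.clip(p, 1e-12, 1 - 1e-12) + 1.0) / 2.0)


def _ndtr(x):
    from scipy.special import ndtr
    return ndtr(x)


def _safe_log_ndtr(x):
    from scipy.special import log_ndtr
    return log_ndtr(x)


def fit_generalization(
    data: GenData,
    config: MCMCConfig,
    priors: GenPriors | None = None,
) -> GeneralizationFit:
    """Fit the four-group latent-mixture generalization model.

    Pathways: Non-Learner (alpha = 0, baseline responding, its own noise
    class), Overgeneralizer (lambda below the critical bound of the active
    perceptual metric), Physical Generalizer (physical distances, lambda at
    or above the bound) and Perceptual Generalizer (active perceptual-metric
    distances, lambda at or above the bound).  The group indicator is
    marginalized; per-participant membership probabilities are averaged over
    retained draws.
    """
    priors = priors or GenPriors()
    T, n = data.y.shape
    C = config.chains
    rng = np.random.default_rng(config.seed)
    yb = data.y[:, None, :]

    dmax_phys = data.d_phys_plus.max(0)
    dmax_perc = data.d_perc_plus.max(0)
    if data.differential:
        dmax_phys = np.maximum(dmax_phys, data.d_phys_minus.max(0))
        dmax_perc = np.maximum(dmax_perc, data.d_perc_minus.max(0))
    lcrit_phys = np.array([overgeneralizer_lambda_bound(d) for d in dmax_phys])
    lcrit_perc = np.array([overgeneralizer_lambda_bound(d) for d in dmax_perc])
    inf = np.full(n, np.inf)
    zero = np.zeros(n)

    # latents: a = logit(alpha); u = logit-uniform latent behind lambda
    a = rng.normal(0.0, 0.5, (C, n))
    u = rng.normal(0.0, 0.5, (C, n))
    p0 = np.clip((data.y.mean(0) - RESPONSE_FLOOR) / (RESPONSE_CEIL - RESPONSE_FLOOR), 0.05, 0.95)
    w0 = np.log(p0 / (1 - p0)) + 0.3 * rng.standard_normal((C, n))
    w1 = 1.0 + 0.3 * rng.standard_normal((C, n))
    lsig_l = np.log(np.maximum(data.y.std(0).mean(), 0.5)) + 0.1 * rng.standard_normal(C)
    lsig_nl = lsig_l + 0.5 + 0.1 * rng.standard_normal(C)
    pi = rng.dirichlet(priors.dirichlet, size=C)

    def theta_of(g, w0, w1):
        with np.errstate(over="ignore"):
            return RESPONSE_FLOOR + (RESPONSE_CEIL - RESPONSE_FLOOR) / (
                1.0 + np.exp(-(w0 + w1 * g))
            )

    def pathway_logliks(a, u, w0, w1, lsig_l, lsig_nl):
        """Stacked (4, C, n) per-pathway log likelihoods, plus the trial-mean
        generalized strength of the perceptual pathway (the w1-update pivot)."""
        alpha = expit(a)
        uu = expit(u)
        sig_l = np.exp(lsig_l)[:, None]
        sig_nl = np.exp(lsig_nl)[:, None]
        vp, vm = _values_batch(alpha, data)
        lam_ovg = _htrunc_ppf(uu, priors.lam_scale, zero, lcrit_perc)
        lam_phy = _htrunc_ppf(uu, priors.lam_scale, lcrit_phys, inf)
        lam_per = _htrunc_ppf(uu, priors.lam_scale, lcrit_perc, inf)
        ll = np.empty((4, C, n))
        th_nl = theta_of(0.0, w0, 0.0)
        ll[Group.NON_LEARNER] = gaussian_loglik(yb, th_nl[None], sig_nl[None], axis=None).sum(0)
        g_mean = None
        for gidx, lam, dp, dm in (
            (Group.OVERGENERALIZER, lam_ovg, data.d_perc_plus, data.d_perc_minus),
            (Group.PHYSICAL, lam_phy, data.d_phys_plus, data.d_phys_minus),
            (Group.PERCEPTUAL, lam_per, data.d_perc_plus, data.d_perc_minus),
        ):
            g = vp * np.exp(-lam * dp[:, None, :])
            if data.differential:
                g = g + vm * np.exp(-lam * dm[:, None, :])
            th = theta_of(g, w0, w1)
            ll[gidx] = gaussian_loglik(yb, th, sig_l[None], axis=None).sum(0)
            if gidx is Group.PERCEPTUAL:
                g_mean = g.mean(0)
        return ll, g_mean

    def mix(ll, pi):
        return logsumexp(np.log(pi.T)[:, :, None] + ll, axis=0)  # (C, n)

    def indiv_prior(a, u, w0, w1):
        # alpha, u ~ Uniform(0,1) on the unit scale -> logistic density on logits;
        # lambda's truncated prior is absorbed by the quantile mapping of u
        return (
            np.log(expit(a)) + np.log(expit(-a))
            + np.log(expit(u)) + np.log(expit(-u))
            + _normal_logpdf(w0, 0.0, priors.w0_sd)
            + _normal_logpdf(w1, 0.0, priors.w1_sd)
        )

    ll_path, g_pivot = pathway_logliks(a, u, w0, w1, lsig_l, lsig_nl)
    ll = mix(ll_path, pi)

    steps = {k: _Adaptive((C, n), s) for k, s in
             (("a", 0.4), ("u", 0.4), ("w0", 0.3), ("w1", 0.3))}
    steps["lsig_l"] = _Adaptive((C,), 0.1)
    steps["lsig_nl"] = _Adaptive((C,), 0.1)

    kept = (config.iterations - config.burn_in) // config.thin
    out = {
        "alpha": np.empty((C, kept, n)),
        "lambda_overgen": np.empty((C, kept, n)),
        "lambda_physical": np.empty((C, kept, n)),
        "lambda_perceptual": np.empty((C, kept, n)),
        "w0": np.empty((C, kept, n)), "w1": np.empty((C, kept, n)),
        "sigma_learner": np.empty((C, kept)), "sigma_nonlearner": np.empty((C, kept)),
        "pi": np.empty((C, kept, 4)),
        # sampled group indicators: parity with Gibbs-style fitting of the mixture
        "group_indicator": np.empty((C, kept, n)),
    }
    member = np.zeros((n, 4))
    n_member = 0
    k = 0
    cur = {"a": a, "u": u, "w0": w0, "w1": w1}
    for it in range(config.iterations):
        warm = it < config.burn_in
        for _sweep in range(2):
            for name in ("a", "u", "w0", "w1"):
                prop = steps[name].propose(cur[name], rng)
                args = {kk: (prop if kk == name else vv) for kk, vv in cur.items()}
                if name == "w1":
                    # w0 and w1 are anticorrelated along the mean-strength
                    # direction; move them jointly (pivot fixed by other blocks)
                    args["w0"] = cur["w0"] - (prop - cur["w1"]) * g_pivot
                ll_path_new, g_new = pathway_logliks(
                    args["a"], args["u"], args["w0"], args["w1"], lsig_l, lsig_nl
                )
                ll_new = mix(ll_path_new, pi)
                lp_new = ll_new + indiv_prior(args["a"], args["u"], args["w0"], args["w1"])
                lp_old = ll + indiv_prior(cur["a"], cur["u"], cur["w0"], cur["w1"])
                acc = _accept(lp_new, lp_old, rng)
                cur[name][acc] = prop[acc]
                if name == "w1":
                    cur["w0"][acc] = args["w0"][acc]
                ll[acc] = ll_new[acc]
                ll_path[:, acc] = ll_path_new[:, acc]
                if name in ("a", "u"):
                    g_pivot[acc] = g_new[acc]
                if warm:
                    steps[name].adapt(acc)
        # noise classes (marginalized over groups)
        for name, lsig in (("lsig_l", lsig_l), ("lsig_nl", lsig_nl)):
            prop = lsig + steps[name].scale * rng.standard_normal(C)
            s_l = prop if name == "lsig_l" else lsig_l
            s_nl = prop if name == "lsig_nl" else lsig_nl
            ll_path_new, _ = pathway_logliks(cur["a"], cur["u"], cur["w0"], cur["w1"], s_l, s_nl)
            ll_new = mix(ll_path_new, pi)
            scale = priors.sigma_learner_scale if name == "lsig_l" else priors.sigma_nonlearner_scale
            lp_new = ll_new.sum(1) + _halfnormal_logpdf(np.exp(prop), scale) + prop
            lp_old = ll.sum(1) + _halfnormal_logpdf(np.exp(lsig), scale) + lsig
            acc = _accept(lp_new, lp_old, rng)
            lsig[acc] = prop[acc]
            ll[acc] = ll_new[acc]
            ll_path[:, acc] = ll_path_new[:, acc]
            if warm:
                steps[name].adapt(acc)
        # pi: momentary data augmentation (sample indicators, Dirichlet draw)
        logw = np.log(pi.T)[:, :, None] + ll_path  # (4, C, n)
        w = np.exp(logw - logsumexp(logw, axis=0))
        cum = np.cumsum(w, axis=0)
        z = (rng.uniform(size=(C, n))[None] > cum).sum(0)  # (C, n) group ids
        counts = np.stack([(z == g).sum(1) for g in range(4)], axis=1)
        pi = rng.gamma(np.asarray(priors.dirichlet) + counts)
        pi /= pi.sum(1, keepdims=True)
        ll = mix(ll_path, pi)

        if not warm and (it - config.burn_in) % config.thin == 0:
            alpha = expit(cur["a"])
            uu = expit(cur["u"])
            out["alpha"][:, k] = alpha
            out["lambda_overgen"][:, k] = _htrunc_ppf(uu, priors.lam_scale, zero, lcrit_perc)
            out["lambda_physical"][:, k] = _htrunc_ppf(uu, priors.lam_scale, lcrit_phys, inf)
            out["lambda_perceptual"][:, k] = _htrunc_ppf(uu, priors.lam_scale, lcrit_perc, inf)
            out["w0"][:, k] = cur["w0"]
            out["w1"][:, k] = cur["w1"]
            out["sigma_learner"][:, k] = np.exp(lsig_l)
            out["sigma_nonlearner"][:, k] = np.exp(lsig_nl)
            out["pi"][:, k] = pi
            out["group_indicator"][:, k] = z
            member += w.sum(1).T  # accumulate membership probs over chains
            n_member += C
            k += 1

    member /= n_member
    summary = PosteriorSummary(out, data.participants)
    return GeneralizationFit(summary, member, data.participants, config)
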