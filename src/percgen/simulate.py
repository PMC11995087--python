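"""Synthetic cohorts with known parameters for recovery studies.

The generator runs the full forward model per participant: draw perceptual
and generalization parameters from population distributions anchored on the
published population medians (beta0 near -3, beta1 near 0.02, omega near
0.002, eta near 11), draw a latent group, build a seeded trial schedule, run
the perceptual filter to produce size ratings on the 0-200 scale, derive the
participant's generative distance series, and emit shock-expectancy ratings
on the 1-10 scale.  Ratings are truncated to their scales at emission only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialSchedule, make_schedule
from .distances import DistanceSeries, Metric, build_distance_series
from .generalization import (
    GenParams,
    Group,
    overgeneralizer_lambda_bound,
    simulate_responses,
)
from .perception import GroupPerceptParams, PerceptParams, filter_trajectory


@dataclass
class SimSpec:
    """Study conditions for one synthetic cohort."""

    experiment: int = 1
    n_participants: int = 40
    #: weights over (NON_LEARNER, OVERGENERALIZER, PHYSICAL, PERCEPTUAL)
    group_weights: tuple = (0.1, 0.15, 0.15, 0.6)
    seed: int = 0
    # perceptual population (anchored on the published Experiment-1 medians)
    beta0_mean: float = -3.05
    beta0_sd: float = 0.4
    beta1_mean: float = 0.023
    beta1_sd: float = 0.006
    sigma_S_mean: float = 0.8
    sigma_S_sd: float = 0.4
    omega_mean: float = 0.002
    omega_sd: float = 0.001
    eta: float = 11.04
    # generalization population
    alpha_range: tuple = (0.2, 0.9)
    lam_overgen_spread: float = 1.0  # uniform fraction of the critical bound
    lam_learner_scale: float = 1.2  # half-normal spread above the bound
    w0_mean: float = -1.0
    w0_sd: float = 0.5
    w1_mean: float = 4.0
    w1_sd: float = 1.0
    sigma_learner: float = 0.75
    sigma_nonlearner: float = 2.5
    normalize_distances: bool = True
    #: metric the Overgeneralizer/Perceptual pathways generate from
    perceptual_metric: Metric = Metric.OVERLAP

    def __post_init__(self) -> None:
        w = np.asarray(self.group_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("group_weights must be 4 nonnegative weights summing to 1")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


@dataclass
class Cohort:
    """A simulated cohort: trial table, ground-truth table, raw pieces."""

    spec: SimSpec
    trials: pd.DataFrame
    truth: pd.DataFrame
    schedules: list[TrialSchedule] = field(default_factory=list)
    distances: dict[int, dict[str, DistanceSeries]] = field(default_factory=dict)


def _truncnorm(rng, mean, sd, lo, size=None):
    x = rng.normal(mean, sd, size=size)
    while np.any(bad := x < lo):  # redraw: simple and exact for mild truncation
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
    return x


def simulate_cohort(spec: SimSpec) -> Cohort:
    """Generate a full synthetic cohort under the study conditions in ``spec``."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    schedules = []
    dist_map: dict[int, dict[str, DistanceSeries]] = {}
    groups = rng.choice(4, size=spec.n_participants, p=np.asarray(spec.group_weights))
    group_pp = GroupPerceptParams(eta=spec.eta)
    for i in range(spec.n_participants):
        seed_i = int(rng.integers(2**31 - 1))
        schedule = make_schedule(
            spec.experiment, seed_i,
            counterbalance="A" if i % 2 == 0 else "B",
        )
        schedules.append(schedule)
        pp = PerceptParams(
            beta0=float(rng.normal(spec.beta0_mean, spec.beta0_sd)),
            beta1=float(_truncnorm(rng, spec.beta1_mean, spec.beta1_sd, 0.005)),
            sigma_S=float(_truncnorm(rng, spec.sigma_S_mean, spec.sigma_S_sd, 0.2)),
            omega=float(_truncnorm(rng, spec.omega_mean, spec.omega_sd, 0.0)),
        )
        diam = np.array([schedule.stimuli.diameter(e.stimulus) for e in schedule.entries])
        states = filter_trajectory(diam, pp, group_pp)
        mu = np.array([s.mu_psi for s in states])
        sd = np.array([s.sigma_psi for s in states])
        size_ratings = np.clip(rng.normal(mu, sd), 0.0, 200.0)

        phys = build_distance_series(
            schedule, Metric.PHYSICAL, normalize=spec.normalize_distances
        )
        overlap = build_distance_series(
            schedule, Metric.OVERLAP, mu_psi=mu, sigma_psi=sd,
            normalize=spec.normalize_distances,
        )
        point = build_distance_series(
            schedule, Metric.POINT, ratings=size_ratings,
            normalize=spec.normalize_distances,
        )
        dist_map[i] = {"PHYSICAL": phys, "OVERLAP": overlap, "POINT": point}
        active = overlap if spec.perceptual_metric is Metric.OVERLAP else point

        group = Group(int(groups[i]))
        d_max = {
            Group.PHYSICAL: float(
                max(phys.d_plus.max(), 0 if phys.d_minus is None else phys.d_minus.max())
            ),
        }.get(group, float(
            max(active.d_plus.max(), 0 if active.d_minus is None else active.d_minus.max())
        ))
        lam_crit = overgeneralizer_lambda_bound(max(d_max, 1e-9))
        if group is Group.NON_LEARNER:
            alpha, lam = 0.0, 0.0
        elif group is Group.OVERGENERALIZER:
            alpha = float(rng.uniform(*spec.alpha_range))
            lam = float(rng.uniform(0.0, spec.lam_overgen_spread * lam_crit))
        else:
            alpha = float(rng.uniform(*spec.alpha_range))
            lam = float(lam_crit + abs(rng.normal(0.0, spec.lam_learner_scale)))
        gp = GenParams(
            alpha=alpha, lam=lam,
            w0=float(rng.normal(spec.w0_mean, spec.w0_sd)),
            w1=float(rng.normal(spec.w1_mean, spec.w1_sd)),
            group=group,
        )
        gen_dist = phys if group is Group.PHYSICAL else active
        sigma = spec.sigma_nonlearner if group is Group.NON_LEARNER else spec.sigma_learner
        expectancy = simulate_responses(schedule, gp, gen_dist, sigma, rng)

        frame = schedule.to_frame(participant=i)
        frame["size_rating"] = size_ratings
        frame["expectancy_rating"] = expectancy
        rows.append(frame)
        truth_rows.append(
            {
                "participant": i, "group": group.name,
                "alpha": gp.alpha, "lambda": gp.lam, "w0": gp.w0, "w1": gp.w1,
                "beta0": pp.beta0, "beta1": pp.beta1,
                "sigma_S": pp.sigma_S, "omega": pp.omega,
                "schedule_seed": seed_i,
            }
        )
    trials = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return Cohort(spec, trials, truth, schedules, dist_map)


@dataclass
class RecoveryReport:
    """Parameter- and group-recovery diagnostics for a fitted cohort."""

    table: pd.DataFrame  # parameter, rank_corr, coverage95, bias
    group_agreement: float | None = None

    def rank_corr(self, parameter: str) -> float:
        row = self.table.loc[self.table.parameter == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row.rank_corr.iloc[0])


def _param_recovery(truth_vals, draws):
    """(rank corr, 95% coverage, median bias) for one parameter."""
    from scipy.stats import spearmanr

    flat = draws.reshape(-1, draws.shape[-1])  # (all draws, n)
    med = np.median(flat, axis=0)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    rc = float(spearmanr(truth_vals, med).statistic)
    cover = float(np.mean((truth_vals >= lo) & (truth_vals <= hi)))
    bias = float(np.mean(med - truth_vals))
    return rc, cover, bias


def recovery_report(
    truth: pd.DataFrame,
    percept_fit=None,
    gen_fit=None,
) -> RecoveryReport:
    """Compare ground truth against fitted posteriors, participant by
    participant.

    Perceptual parameters (beta0, beta1, sigma_S, omega) come from the
    perceptual fit; generalization parameters (alpha, lambda, w0, w1) from
    the latent-mixture fit, with lambda read off the perceptual-generalizer
    pathway.  Raises on participant-id mismatch.
    """
    rows = []
    agreement = None
    truth = truth.sort_values("participant").reset_index(drop=True)
    for fit, pairs in (
        (percept_fit, [("beta0", "beta0"), ("beta1", "beta1"),
                       ("sigma_S", "sigma_S"), ("omega", "omega")]),
        (gen_fit, [("alpha", "alpha"), ("lambda", "lambda_perceptual"),
                   ("w0", "w0"), ("w1", "w1")]),
    ):
        if fit is None:
            continue
        if list(truth.participant) != list(fit.participants):
            raise ValueError("participant ids in truth table do not match the fit")
        for tcol, pname in pairs:
            rc, cover, bias = _param_recovery(
                truth[tcol].to_numpy(dtype=float), fit.summary.draws[pname]
            )
            rows.append(
                {"parameter": tcol, "rank_corr": rc, "coverage95": cover, "bias": bias}
            )
    if gen_fit is not None:
        modal = gen_fit.modal_group()
        true_groups = np.array([Group[g].value for g in truth.group])
        agreement = float(np.mean(modal == true_groups))
    return RecoveryReport(pd.DataFrame(rows), agreement)
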