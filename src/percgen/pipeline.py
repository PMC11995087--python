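"""End-to-end wiring of the two-step analysis.

Step 1 fits the perceptual model to size ratings; step 2 builds trial-wise
distance series from the fitted states and fits the latent-mixture
generalization model (or the super model) on the expectancy ratings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Phase, Role, TrialEntry, TrialSchedule, make_stimulus_set
from .distances import DistanceSeries, Metric, build_distance_series
from .inference import (
    GenData,
    GeneralizationFit,
    MCMCConfig,
    PerceptualFit,
    build_gen_data,
    fit_generalization,
    fit_perceptual,
)


def schedules_from_trials(trials: pd.DataFrame) -> tuple[list[TrialSchedule], list]:
    """Reconstruct per-participant trial schedules from the long-format table."""
    has_minus = (trials.role == Role.CS_MINUS.value).any()
    experiment = 2 if has_minus else 1
    schedules = []
    participants = sorted(trials.participant.unique())
    for pid in participants:
        sub = trials[trials.participant == pid].sort_values("trial")
        if experiment == 2:
            cs_plus = sub.loc[sub.role == Role.CS_PLUS.value, "stimulus"].iloc[0]
            counterbalance = "A" if cs_plus == "S1" else "B"
        else:
            counterbalance = "A"
        stimset = make_stimulus_set(experiment, counterbalance)
        entries = [
            TrialEntry(
                Phase(row.phase), int(row.block), row.stimulus,
                bool(row.reinforced), int(row.k), int(row.r),
            )
            for row in sub.itertuples()
        ]
        schedules.append(TrialSchedule(experiment, stimset, entries))
    return schedules, participants


def ratings_matrix(trials: pd.DataFrame, col: str) -> np.ndarray:
    wide = trials.pivot(index="trial", columns="participant", values=col).sort_index()
    return wide.to_numpy(dtype=float)


def distance_series(
    trials: pd.DataFrame,
    metric: Metric,
    percept_fit: PerceptualFit | None = None,
    normalize: bool = True,
) -> list[DistanceSeries]:
    """Per-participant distance series under ``metric``.

    OVERLAP requires a fitted perceptual model (two-step contract); POINT
    uses the raw size ratings; PHYSICAL only the schedule.
    """
    schedules, participants = schedules_from_trials(trials)
    if metric is Metric.OVERLAP and percept_fit is None:
        raise ValueError(
            "OVERLAP distances require a perceptual fit; run the perceptual "
            "model first (two-step contract)"
        )
    out = []
    ratings = ratings_matrix(trials, "size_rating") if metric is Metric.POINT else None
    for i, sch in enumerate(schedules):
        kwargs = {}
        if metric is Metric.POINT:
            kwargs["ratings"] = ratings[:, i]
        elif metric is Metric.OVERLAP:
            kwargs["mu_psi"] = percept_fit.state_mu[:, i]
            kwargs["sigma_psi"] = percept_fit.state_sigma[:, i]
        out.append(build_distance_series(sch, metric, normalize=normalize, **kwargs))
    return out


def distances_frame(series: list[DistanceSeries], participants: list) -> pd.DataFrame:
    return pd.concat(
        [s.to_frame(participant=p) for s, p in zip(series, participants)],
        ignore_index=True,
    )


def assemble_gen_data(
    trials: pd.DataFrame,
    metric: Metric,
    percept_fit: PerceptualFit | None = None,
    normalize: bool = True,
) -> GenData:
    """GenData with physical distances plus the chosen perceptual metric."""
    schedules, participants = schedules_from_trials(trials)
    phys = distance_series(trials, Metric.PHYSICAL, normalize=normalize)
    perc = distance_series(trials, metric, percept_fit, normalize=normalize)
    y = ratings_matrix(trials, "expectancy_rating")
    return build_gen_data(schedules, y, phys, perc, participants)


def two_step_fit(
    trials: pd.DataFrame,
    metric: Metric = Metric.OVERLAP,
    config_percept: MCMCConfig | None = None,
    config_gen: MCMCConfig | None = None,
) -> tuple[PerceptualFit, GeneralizationFit]:
    """Run the full two-step pipeline on a trial table."""
    config_percept = config_percept or MCMCConfig()
    config_gen = config_gen or MCMCConfig(seed=config_percept.seed + 1)
    pfit = fit_perceptual(trials, config_percept)
    data = assemble_gen_data(trials, metric, pfit)
    gfit = fit_generalization(data, config_gen)
    return pfit, gfit
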