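"""Super-model comparison: overlap-based vs point-based perceptual distance.

Expectancies are generated under the distribution-overlap assumption (M1);
the super model mixes the likelihoods of both assumptions with the weight
beta_M ~ Beta(1,1).  Posterior mass of beta_M above 0.5 favors M1, and the
Savage-Dickey ratio at 0.5 gives the Bayes factor for the two assumptions
performing differently.
"""

import percgen as pg
from percgen.comparison import fit_super
from percgen.inference import build_gen_data
from percgen.pipeline import ratings_matrix, schedules_from_trials

spec = pg.SimSpec(
    experiment=1, n_participants=8, seed=3,
    group_weights=(0.0, 0.0, 0.0, 1.0),
    perceptual_metric=pg.Metric.OVERLAP,  # generate under M1
)
cohort = pg.simulate_cohort(spec)
schedules, parts = schedules_from_trials(cohort.trials)
y = ratings_matrix(cohort.trials, "expectancy_rating")
overlap = [cohort.distances[i]["OVERLAP"] for i in range(8)]
point = [cohort.distances[i]["POINT"] for i in range(8)]
data = build_gen_data(schedules, y, point, overlap, parts)

cfg = pg.MCMCConfig(chains=4, iterations=800, burn_in=400, seed=9)
result = fit_super(data, cfg)
rep = result.report()

lo, hi = rep["beta_m_ci95"]
print(f"beta_M posterior median: {rep['beta_m_median']:.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
print(f"BF (deviation from 0.5): {rep['bf_deviate']:.3g}")
print(f"BF (point hypothesis):   {rep['bf_point']:.3g}")
# beta_M > 0.5 with a large deviation BF: the data generated under the
# overlap assumption are correctly attributed to it.
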