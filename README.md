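# percgen

Computational modeling of how dynamic, probabilistic perception shapes human
fear generalization.

In Pavlovian fear-conditioning experiments, participants learn that one
circle (the CS+) predicts an electrocutaneous shock and then rate both the
*size* of each presented circle (0–200 mm visual-analogue scale) and their
*shock expectancy* (1–10). People do not perceive circle sizes veridically:
percepts drift, differ between individuals, and carry uncertainty. `percgen`
implements a two-step framework that measures these perceptual dynamics from
the size ratings alone and then asks whether they explain generalization of
fear to never-reinforced test stimuli.

**Step 1 — perception.** A hierarchical Kalman-filter state-space model: a
participant-specific sigmoid maps diameter *x* to a sensory mean
μ_S = Ω / (1 + e^−(β₀+β₁x)) with Ω = 200, and the latent percept evolves as

    α_ψ = σ_ψ / (σ_ψ + σ_S)                        (Kalman gain)
    μ_ψ ← μ_ψ + α_ψ (μ_S − μ_ψ)
    σ_ψ ← (1 − α_ψ) σ_ψ + η e^(−ω j)               (decaying process noise)

**Step 2 — generalization.** Trial-wise distances between the current
percept and the CS memory — physical (mm), point-based (|running-mean CS
rating − current rating|), or the distribution overlap d = 1 − ∫min(f₁,f₂)dx
— feed a Rescorla–Wagner + Shepard model with a four-group latent mixture
(Non-Learners, Overgeneralizers, Physical and Perceptual Generalizers):

    v ← v + α (r − v) k                             (error-driven learning)
    g = v⁺ e^(−λ d⁺) + v⁻ e^(−λ d⁻)                 (exponential decay)
    θ = 1 + 9 / (1 + e^−(w₀+w₁g)),   y ~ N(θ, σ²)   (response mapping)

A *super model* mixes the likelihoods of the overlap-based (M1) and
point-based (M2) distance assumptions with a weight β_M ~ Beta(1,1); the
Savage–Dickey density ratio at β_M = 0.5 gives a Bayes factor for the two
assumptions performing differently.

All posterior inference is an in-package adaptive Metropolis-within-Gibbs
sampler vectorized over chains and participants, with Gelman–Rubin R̂
diagnostics, a `paper` preset mirroring the published chain settings
(4 × 100,000 iterations; 4 × 250,000 for the super model) and a `desk`
preset (4 × 2,000) that runs in minutes.

## Worked example

```python
import percgen as pg
from percgen.distances import PerceptualDistribution as N

# an observer with the published population-median parameters
params = pg.PerceptParams(beta0=-3.05, beta1=0.023, sigma_S=0.8, omega=0.002)
print(pg.sensory_mean(96.54, params))          # 60.75 — the CS+ percept (0-200 scale)

# overlap distance between a certain and an uncertain percept
print(pg.overlap_distance(N(60, 2), N(63, 12)))  # 0.7018
print(pg.overlap_distance(N(0, 1), N(1, 1)))     # 0.3829 = 1 - 2*Phi(-1/2)
```

The first number is the sigmoid-mapped sensory mean for the 96.54 mm CS+
circle: this observer experiences it near 61 on the 0–200 rating scale. The
overlap distances show the metric's behavior: a certain percept (sd 2) barely
overlaps an uncertain one (sd 12) three units away, giving a large distance
0.70, while two unit-noise percepts one unit apart overlap heavily (distance
0.38, matching the equal-variance closed form).

A full simulation-and-recovery round trip (`examples/04_simulate_and_recover.py`,
8 synthetic participants, short chains) prints:

```
parameter  rank_corr  coverage95   bias
    beta1      0.952       1.000  0.000
   lambda      0.952       1.000  0.100
...
modal-group agreement: 100%
```

meaning the fitted posterior medians order individuals on the sigmoid slope
β₁ and generalization rate λ almost perfectly, credible intervals cover the
generating truth, and every participant is assigned to the generating latent
group. `examples/05_model_comparison.py` shows the super model attributing
overlap-generated data to M1 (β_M median 0.998, deviation Bayes factor ≫ 1).

Each script in `examples/` is a narrative of one capability: experiment
designs, the perceptual filter, overlap distances, recovery, and model
comparison. A thin CLI (`percgen simulate|fit-percept|distances|fit-gen|compare|recover`)
wraps the same pipeline for shell use.

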