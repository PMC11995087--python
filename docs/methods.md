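# Methods

## The perceptual model

Perception of circle size is modeled as a one-dimensional state-space
process per participant. A sigmoid sensory mapping converts diameter x (mm)
to a sensory mean on the 0–200 rating scale, μ_S = Ω/(1+e^−(β₀+β₁x)) with
Ω = 200 fixed by the scale ceiling. β₀ sets the baseline perceptual
magnitude, β₁ (per mm) the steepness; σ_S (rating units) is the sensory
noise, i.e. how consistently the same physical stimulus is encoded. A single
latent perceptual state (μ_ψ, σ_ψ) is carried across *all* trials regardless
of which stimulus was shown — past perceptual experience is the sole prior —
and updated with the gain α_ψ = σ_ψ/(σ_ψ+σ_S). The gain is deliberately the
ratio of standard deviations, not the textbook variance ratio. Uncertainty
evolves as σ_ψ ← (1−α_ψ)σ_ψ + η·e^(−ωj) with the 0-based trial index j: η
(rating units) is the initial process-noise magnitude and ω (per trial) its
decay rate. The first trial is initialized at μ_ψ = μ_S with σ_ψ = η
(equivalently, gain 1 — no prior experience exists).

The observation equation links the state to the recorded size rating as
y ~ N(μ_ψ, σ_ψ²), truncated to [0, 200] only when simulating. Consequences
worth knowing: the observed rating noise is σ_ψ itself (≈ η at the start),
and σ_S is identified only through the gain dynamics, so it is the least
well recovered parameter — a property of the model, not of the sampler.

Hierarchy and default priors (all overridable through `PerceptPriors`):
μ_β0 ~ N(0,5), μ_β1 ~ N(0,0.1), participant effects normal around these with
Half-Normal(2.5) and Half-Normal(0.05) spreads; σ_S,i ~ Half-Normal(5);
ω_i ~ N(μ_ω, σ_ω) truncated at 0 with μ_ω ~ Half-Normal(0.05); shared
η ~ Half-Normal(20). Weakly informative throughout; the truncation
normalizer Φ(μ_ω/σ_ω) is carried in the hyperparameter conditionals.

## Perceptual distances

Three trial-wise metrics against the CS memory:

* **physical** — |x_CS − x_TS| in mm (constant per stimulus);
* **point** — |cumulative mean of past CS size ratings − current rating|,
  the descriptive representation of perception;
* **overlap** — 1 − ∫min(f₁,f₂)dx between the current percept
  N(μ_ψ, σ_ψ²) and the CS memory, taken to be the state on the most recent
  preceding CS trial (faithful encoding, no memory model).

The overlap integral is evaluated exactly: the two Gaussian densities cross
at the roots of a quadratic, the pointwise minimum is the narrower density
on the outer segments and the wider one between the crossings, and each
piece is a difference of normal CDFs. For equal variances this reduces to
2Φ(−|Δμ|/(2σ)). A hit-or-miss Monte Carlo estimator (points uniform under
the pointwise minimum) is provided for parity with stochastic
approximation; its bounding box is the intersection of the two 6σ ranges
capped by the lower peak, with stratified x draws, giving errors well inside
3/√n.

For fitting, per-trial states are posterior medians (50% quantile of the
MCMC draws), and each participant-metric distance series is normalized by
its maximum (default on). Normalization makes the generalization rate λ
comparable across metrics — mm, rating units and [0,1] would otherwise
demand incompatible λ priors — and makes the Overgeneralizer bound
participant-relative. Trials before the first CS trial of a role get
distance 0 to that role's memory; associative strength is still zero there,
so the value never reaches the likelihood.

A caveat measured during development and worth stating: the overlap metric
lives in a small-distance regime when perceptual uncertainty (≈ η ≈ 11
rating units) dwarfs the percept separations a shallow sigmoid produces.
For such low-sensitivity participants the *estimated* overlap series is
noise-dominated, and max-normalization amplifies that noise; two-step λ
recovery through estimated overlap distances is therefore attenuated
relative to λ recovery through directly observable distances. The recovery
harness accordingly exercises λ through the point metric (identical in
generation and fit), which isolates the mixture model's identification from
perceptual-state estimation error; overlap-specific attenuation is a known
limitation of the two-step design itself.

## The generalization model

Associative strength updates by the delta rule v ← v + α(r−v)k on CS trials
(k = 1), including generalization-phase re-acquisition trials — they exist
precisely to keep learning live. CS+ outcomes are r ∈ {0,1}; the CS− is
never reinforced and carries r = −1 on every trial, the no-shock outcome
that drives inhibitory strength v⁻ toward −1 (with r = 0 the inhibitory
pathway would be inert). Generalized strength decays exponentially with
distance, g = v⁺e^(−λd⁺) (+ v⁻e^(−λd⁻) in the differential design), and maps
to the 1–10 expectancy scale through θ = 1 + 9/(1+e^−(w₀+w₁g)) with Gaussian
response noise.

Four latent groups structure the population. Non-Learners: α = 0, flat
baseline responding θ(w₀), with their own (wider) noise class. Over-
generalizers: λ < λ_crit = −ln(0.7)/d_max, so similarity exceeds 70% even at
the participant's largest observed distance d_max under the active metric.
Physical and Perceptual Generalizers: λ ≥ λ_crit computed on the physical
and the active perceptual metric respectively. The Overgeneralizer pathway
consumes the active perceptual metric's distances; below λ_crit the choice
is nearly immaterial by construction. A single uniform latent u per
participant stands behind λ in every pathway through the group-specific
truncated Half-Normal(2) quantile function, so each pathway sees its own
correctly truncated prior while sharing one degree of freedom. Remaining
priors: α ~ Uniform(0,1), w₀ ~ N(0,2), w₁ ~ N(0,5), σ_learner ~
Half-Normal(2), σ_non-learner ~ Half-Normal(5), π ~ Dirichlet(1,1,1,1).

The discrete group indicator is marginalized out of every continuous
conditional (log-sum-exp over the four pathway likelihoods). π is refreshed
by momentary data augmentation — sample indicators from their exact
conditional, draw π from the conjugate Dirichlet, discard the indicators —
which is also the sampled-indicator parity mode: the drawn indicators are
stored per retained iteration. Reported membership probabilities are the
per-draw posterior group probabilities averaged over retained draws.

## Two-step contract

The perceptual model is fitted on size ratings alone; its posterior-median
states define the distance series; the generalization model is fitted on
expectancy ratings with those distances frozen. The generalization fit never
re-estimates perception, so distributional assumptions about perception
cannot leak into the model comparison. The test suite asserts this as a
bit-identity: perturbing expectancy ratings leaves every perceptual
posterior draw unchanged.

## Super model and Bayes factor

The two generalization variants — M1 with overlap distances, M2 with point
distances, structurally identical otherwise — are nested in one likelihood:
each observation's density is β_M f₁ + (1−β_M) f₂ with β_M ~ Beta(1,1).
Each side carries the learner forward chain (α, λ, w₀, w₁, σ per side); the
desk-scale comparison isolates the distance question, so the four-group
mixture is not duplicated inside the super model. The Savage–Dickey ratio at
β_M = 0.5 uses a moment-matched Beta fit to the draws (default) with a
Gaussian KDE cross-check, both reported. Orientation: `bf_deviate` =
prior density / posterior density at 0.5, so values above 1 mean β_M deviates
from 0.5 (the assumptions perform differently); its reciprocal `bf_point` is
always reported alongside. The posterior density is floored at 1e−12,
capping the reported factor at 1e12 — beyond that the draws simply contain
no mass near 0.5.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs, vectorized so all chains and
participants advance as one numpy batch (participants are conditionally
independent given population parameters, so cross-participant proposals are
accepted elementwise). Proposal scales adapt toward 0.44 acceptance during
burn-in (Robbins–Monro on the log scale) and freeze afterwards; proposals
take an occasional five-fold jump to hop between pathway-induced posterior
modes. Two reparametrized joint blocks fix the strong anticorrelations this
model family exhibits: the sigmoid slope moves jointly with the offset so
the curve pivots around the mean diameter, and w₁ moves jointly with w₀
pivoting around the trial-mean generalized strength. Population means of β₀
and β₁ are conjugate normal draws; spreads and the ω hyperparameters are
cheap Metropolis steps. Positive parameters are sampled on the log scale
with the Jacobian in the target. Chains are initialized from data-derived
moment estimates (a logit-linear regression for the sigmoid, residual
spreads for noise scales), jittered per chain.

Presets: `paper` = 4 chains × 100,000 iterations, 75,000 burn-in, thin 10
(10,000 retained); `paper_super` = 4 × 250,000, 100,000 burn-in, thin 5
(120,000 retained); `desk` = 4 × 2,000, 1,000 burn-in, thin 1 (4,000
retained). Convergence is summarized by the classic Gelman–Rubin R̂
(√(V̂/W)); the suite requires R̂ ≤ 1.05 on the recovery-relevant parameters,
and non-convergence is reported in summaries, never silently ignored.

## Synthetic cohorts

The generator runs the complete forward model with population distributions
anchored on the published medians: β₀ ~ N(−3.05, 0.4), β₁ ~ N(0.023, 0.006)
truncated above 0.005, σ_S ~ N(0.8, 0.4) truncated above 0.2 (most
participants below 1), ω ~ N(0.002, 0.001) truncated at 0, η = 11.04.
Generalization side: α ~ Uniform(0.2, 0.9) for learners; λ uniform below the
critical bound for Overgeneralizers and bound + |N(0, 1.2)| for the two
generalizer groups; w₀ ~ N(−1, 0.5), w₁ ~ N(4, 1); response noise 0.75
(learners) and 2.5 (Non-Learners). Size ratings are drawn from the state
trajectory, expectancies from the group-appropriate distance series; both
are clipped to their scales at emission only. The generator's active
perceptual metric (overlap or point) is part of the cohort specification.

What the generator does *not* emulate: memory encoding/retrieval biases,
physiological response channels, reaction times, dropout, sequential rating
dependencies beyond the state dynamics, and any mis-specification between
the generating and fitting model families. Passing recovery tests therefore
demonstrates internal consistency of the pipeline under its own assumptions,
not robustness to the ways real data deviate from them.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script run at desk
scale, chosen so each study completes in minutes on one CPU: recovery at 40
participants (the experiments' own cohort size), group recovery at 20 per
pure cohort, model-selection checks at 16 with three seeds. Degenerate
inputs: zero-length schedules, empty CS history, nonpositive standard
deviations and single chains raise explicit errors; the overlap evaluator
resolves far-tail segment selection in log densities to avoid 0 = 0 ties;
mixture accumulations use log-sum-exp throughout. Posterior-median state
trajectories are computed from every retained draw thinned to ≈250 per
chain, which bounds memory while leaving the medians unchanged to well below
distance resolution.

## Known limitations

Point estimates (posterior medians) of the perceptual states enter the
distances, so perceptual uncertainty about *parameters* is not propagated
into step two — only the modeled perceptual uncertainty σ_ψ is. The
replication helper draws from median states and thus slightly understates
predictive tail spread. The CS memory is the single most recent CS trial;
no consolidation or decay. The super model reports evidence about the two
distance assumptions only at desk scale with single-pathway sides; a
full-mixture super model at the published chain lengths is reachable through
the `paper_super` preset but costs hours.
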