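# Methods

## Model

Detections are binary per (individual, station, occasion) at operating
trap-nights. Given an activity centre `s_i` on the habitat grid and sex
`x_i ∈ {0 = female, 1 = male}`, the per-trap-night hazard at station `j` is

    λ_ij = λ0 · exp(β_sex · x_i) · exp( − d_ij^(2θ) / 2σ²_{x_i} ),

and the detection probability is `π_ij = 1 − exp(−λ_ij)`, i.e.
`cloglog(π_ij) = log λ0 + β_sex x_i + log f(d_ij)`. The kernel is
half-normal at θ = 1 and exponential-in-distance at θ = 0.5; θ is either
fixed (0.75 or 1) or estimated on [0.5, 1]. Occasions are exchangeable
given effort, so the likelihood reduces to per-(i, j) binomial sufficient
statistics: `y_ij` detections out of `E_j` operating nights. Because the
complement probability is exactly `exp(−λ_ij)`, all log-masses are computed
from the hazard directly (`log(1−π) = −λ`, `log π = log(−expm1(−λ))`),
which is stable for hazards from 1e-300 to hundreds.

Population size uses data augmentation: `M = n + nz` individuals with
inclusion indicators `z_i ~ Bernoulli(ψ)` (detected individuals fixed at 1)
and activity centres uniform over habitat pixels; several individuals may
share a pixel. Realized abundance in a region is `Σ z_i · 1[s_i ∈ region]`
per draw, and density is `100 · N_region / area_region`. Sex is a latent
`Bernoulli(1 − ψ_sex)` where unrecorded. Models without any sex structure
(shared σ and β_sex ≡ 0 — all hyena variants) drop the sex machinery
entirely.

Assumptions worth stating: activity centres are static over the season
(no transience), detections are independent across trap-nights given the
centre (no behavioural response or trap-level saturation), both cameras of
a paired station act as one binary proximity detector, and the 24-hour
independence filter is applied upstream — loading collapses duplicate
(individual, station, occasion) records to a single 1, which enforces it.

## Priors and defaults

| parameter | prior | rationale |
|---|---|---|
| log λ0 | flat on [log 1e-6, log 10] | scale-free vague prior for a rate |
| σ | Uniform(0, half state-space diagonal) | movement scale cannot exceed the state space |
| β_sex | Normal(0, 10²) | vague on the cloglog scale |
| θ | Uniform(0.5, 1) | the kernel family's full range |
| ψ, ψ_sex | Beta(1, 1) | uniform; ψ_sex conjugate with the latent sexes |

`nz` defaults to `4n`; the sampler logs a warning when the upper 97.5%
quantile of `Σz` exceeds `0.9·M`, the sign that the augmentation ceiling is
binding and `nz` must be raised. Iteration defaults (20,000 with 5,000
burn-in, four chains) follow common practice for surveys of this size; all
are configurable.

## Sampler

Metropolis-within-Gibbs, per iteration: (1) random-walk Metropolis on
log λ0, log σ (Jacobian-corrected against the uniform-on-σ prior), β_sex
and θ (proposals outside [0.5, 1] rejected); (2) activity centres — a Gibbs
draw from the uniform prior for excluded individuals (their likelihood is
flat), and for included individuals a symmetric proposal over a
(2w+1)²-pixel window (w = 3) mixed with a 10% uniform jump, rejecting
proposals off the habitat; (3) Gibbs inclusion draws with odds
`ψ e^{−H_i} : 1−ψ`, `H_i` the summed hazard over operating trap-nights;
(4) Gibbs sex imputation; (5) conjugate Beta draws for ψ and ψ_sex.
Proposal scales adapt toward 0.35 acceptance during burn-in only
(Robbins-Monro, batches of 50), frozen afterwards so the retained chain
targets the exact posterior. σ initialises at the RMS spread of each
recaptured individual's detection stations — a cheap moment estimate that
starts chains near the likelihood ridge instead of on the flat
large-σ/small-λ0 shelf. Chains are deterministic functions of
`(seed, chain index)`.

## Diagnostics

Convergence: the classic (non-split) Gelman-Rubin PSRF
`sqrt(((m−1)/m·W + B/m)/W)`; the split-chain variant is available via
`split=True`. Below 1.2 for every free parameter is reported as converged.

Adequacy: a posterior predictive p-value with the Freeman-Tukey discrepancy
`T = Σ_i (√e_i − √E_i)²` over individual total encounter counts, comparing
observed with replicated surveys at each retained draw; by default
replicates condition on the retained latent states (a marginal mode that
redraws latents is also provided). Two properties matter for
interpretation: conditioning on fitted latents makes the p-value
conservative (it clusters near 0.5 under the true model), and a statistic
built on *totals* has little power against purely spatial misfit — the
activity-centre distance acts as a per-individual random effect that can
absorb striking total-count heterogeneity. What it does catch is
variance-level misfit, e.g. totals more regular than Bernoulli sampling
allows, which drives the p-value to the boundary.

## Marginal likelihood and model ranking

The Gelfand-Dey identity `1/ML = E_post[g(u)/(L(u)p(u))]` is evaluated with
`g` a multivariate normal fitted to the posterior draws of the free
structural parameters (on transformed scales: log λ0, log σ, logit ψ,
logit ψ_sex) and truncated to its 95% ellipsoid, which keeps the importance
weights bounded; a batch-means standard error accompanies each estimate.
The raw harmonic-mean estimator exists behind a flag for comparison only.

The likelihood entering the identity is the **observed-data likelihood** of
the augmented model — activity centres, inclusion indicators and sexes
marginalised in closed form over the pixel grid. This choice is what makes
ranking across model variants meaningful: with the complete-data likelihood
and latents treated as parameters, the identity integrates to (latent-space
cardinality)/ML when `g` covers only the structural block, so any model
with an extra per-individual latent is penalised by ~M·log 2 nats
regardless of fit. The complete-data convention remains available
(`likelihood="complete-data"`) but is only comparable between models with
identical latent structure, and its absolute values are convention-bound —
which is also why no absolute marginal-likelihood value from any particular
survey report is reproducible without knowing that report's convention.
Two further comparability rules are enforced: all ranked chains must carry
the same data fingerprint and the same augmented size M, and exact ties
break toward fewer free parameters. One caveat observed while validating
the ranking: competitors should model the *same observed data* — a
variant that ignores recorded sex labels competes on a smaller dataset and
its evidence is not comparable to one that includes the sex-label mass.

## Summaries and conventions

Credible intervals are equal-tailed 2.5/97.5 percentiles; posterior SDs use
the sample convention (denominator N−1). Density times region area over
100 equals abundance exactly, per draw. The realized density surface is
the per-pixel average count of included centres and sums to the posterior
mean of `Σz`. Detection rate is `100·n/Σeffort` at full precision;
`format_rate` offers both truncation and rounding to 2 dp because field
reports are not consistent about which they print (100·20/1444 = 1.3850
prints as 1.38 only under truncation, while 100·27/1444 = 1.8698 prints as
1.87 only under rounding).

## Synthetic data

The generator draws centres uniformly over habitat pixels (fixed-N,
Poisson or binomial population modes; fixed-N is the default so recovery
experiments have clean truth) and detections from the same cloglog model
the sampler fits, at operating trap-nights only. The bundled fixture
emulates a 370 km² park survey: a 23.0 × 16.1 km park rectangle, 30
stations on a jittered 6×5 grid at 2.1 km spacing, 53 occasions with
exactly 146 of 1,590 trap-nights failed, a buffered pixel grid (1 km
default, 0.58 km available) with park/buffer region labels and small
non-habitat patches, and generating parameters at the published posterior
means of the comparable real survey (σ = 1.33 km, λ0 = 0.04, β_sex = 0.09,
ψ_sex = 0.69, θ = 0.75, density 6.31/100 km²).

What the fixture does *not* emulate: real home-range movement (detections
come directly from the static-centre model), behavioural responses,
misidentification, spatial covariates of density, or non-random trap
failure. Tests passing on it therefore demonstrate that the estimator
recovers the model's own truth at realistic sparsity — not that the model
is adequate for any particular field system.

## Problem sizes used by the test suite

Chosen as the smallest configurations at which the checks are informative:
recovery experiments use a coarsened fixture (2 km pixels, 8 km buffer, 20
occasions, 3,000 iterations × 4 chains, 20 replicates); the survey-scale
check uses 1 km pixels with a 12 km buffer and 5,000 iterations × 2 chains;
calibration uses 20 replicates of 1,600 iterations; ranking uses 10
replicates of 2,000 iterations. σ in generating configurations is kept
above the pixel size — a centre grid cannot represent movement scales finer
than its own spacing, and fitting such data degrades any model comparison
(observed directly when ranking with σ_f = 0.5 km on 2 km pixels).

## Limitations

Single-session, closed-population only; binary proximity detectors only
(no counts, no multi-catch traps); no density covariates or inhomogeneous
point process for centres; no trap-level behavioural response; the
marginal-likelihood estimator requires reasonably normal posterior draws
and degrades on strongly multimodal posteriors; λ0 and β_sex are weakly
identified at small n (a handful of detected males), which the credible
intervals report honestly.
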