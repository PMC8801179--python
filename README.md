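# bayescr

Bayesian spatially explicit capture-recapture (SECR) for camera-trap
surveys of individually identifiable animals — leopards, spotted hyenas and
other large carnivores whose rosette or spot patterns allow capture
histories to be built from photographs.

Classical capture-recapture estimates abundance but not the area it refers
to; SECR resolves this by giving every individual a latent **activity
centre** `s` on a discrete habitat grid (the state space: the surveyed park
plus a buffer, with settlements and water masked out) and modelling each
detection as a function of the distance between centre and camera station.
`bayescr` implements the Bernoulli observation model with a complementary
log-log link and a flexible hazard kernel:

    cloglog(π_ij) = log λ0 + β_sex·sex_i + log f(d_ij),
    f(d) = exp( − d^(2θ) / 2σ²_sex ),    θ ∈ [0.5, 1],

where `π_ij` is the probability that individual *i* is detected at station
*j* on one operating trap-night, `λ0` the basal encounter hazard at distance
zero, `σ` the movement (home-range) scale in km, and `θ` interpolates
between an exponential (θ = 0.5) and a Gaussian/half-normal (θ = 1) decline.
Population size is handled by **data augmentation**: the `n` detected
individuals are padded with `nz` all-zero histories, each carrying an
inclusion indicator `z ~ Bernoulli(ψ)`; realized abundance in a region is
the number of included centres falling in it, and density is that count per
100 km². Sex enters through the `β_sex` offset and/or sex-specific `σ`,
with unknown sexes imputed from `ψ_sex` (the proportion of females).

The package covers the full analysis pipeline:

- **data_io** — CSV dialects for traps (with per-occasion effort encoding
  failed trap-nights), capture histories (long or wide layout), sex labels
  and habitat masks with region labels; chain output as delimited text with
  YAML metadata.
- **model_core** — kernel, link, complete-data and latent-marginalised
  likelihoods.
- **sampler** — Metropolis-within-Gibbs over parameters and latent states,
  multiple chains, burn-in, adaptive proposals, full seed control.
- **diagnostics** — Gelman-Rubin potential scale reduction factor (< 1.2 →
  converged) and posterior predictive Bayesian p-values on individual
  encounter totals (0.15–0.85 → adequate).
- **model_selection** — Gelfand-Dey log marginal likelihood with a
  truncated-normal weight; ranking of competing model variants.
- **summaries** — realized density/abundance by region with credible
  intervals, per-pixel density surfaces, detection rates per 100 trap-nights.
- **synthetic** — a generator producing surveys with the exact statistical
  structure the model assumes, including a fixture shaped like a real
  370 km² savanna-park survey (30 stations at 2.1 km spacing, 53 daily
  occasions, 1,444 usable trap-nights).

Six predefined leopard model variants (`leopard_model(1..6)`) and two
hyena variants (`hyena_model(1..2)`, no sex covariate) mirror the model
suites typically compared in such surveys.

## Worked example

`examples/02_fit_density_model.py` simulates a survey at the real study's
scale (the generating parameters are the fitted values a comparable field
study reported: σ = 1.33 km, λ0 = 0.04), fits the shared-σ /
sex-dependent-encounter-rate variant with two chains, and prints:

```
detected 20 individuals; fitting 'model5' (5 free parameters) ...
  sigma_f:   1.354  95% CI [1.191, 1.570]
     lam0:   0.039  95% CI [0.027, 0.056]
 beta_sex:   0.260  95% CI [-1.418, 3.345]
  psi_sex:   0.770  95% CI [0.541, 0.923]
park density:   7.51 / 100 km^2 (SD 1.45, 95% CI [5.11, 10.80])
park abundance: 26.42 (SD 5.10)
generating truth: sigma 1.33 km, lam0 0.04, realized park count 21
density surface: 1803 pixels, total 141.28 = posterior mean N in the state space
```

The posterior recovers the generating movement scale and encounter rate;
the park density interval covers the realized truth (21 individuals in
370 km² ≈ 5.7/100 km²). `β_sex` is wide — with ~5 detected males there is
little information about a sex effect, which is exactly what the interval
says. The other examples cover simulation (`01`), diagnostics (`03`) and
model ranking (`04`); each runs in well under a minute.

The same pipeline is scriptable from the shell:

```sh
bayescr simulate --out survey/ --fixture lmnp --seed 1
bayescr fit --traps survey/traps.csv --encounters survey/encounters.csv \
    --sex survey/sex.csv --mask survey/mask.csv \
    --model leopard:5 --model leopard:3 --iters 5000 --burnin 1500 \
    --chains 2 --out fit/
bayescr summarize fit/chain_leopard_5_0.csv fit/chain_leopard_5_1.csv \
    --mask survey/mask.csv
```

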