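"""Rank competing detection models by estimated log marginal likelihood.

Simulates a survey whose detection truly differs between the sexes through
the movement scale (sigma_f = 0.8 km, sigma_m = 2.4 km), fits the correctly
specified sex-specific-sigma model and a shared-sigma alternative, and ranks
them with the Gelfand-Dey evidence estimate.  The correctly specified model
should win.
"""

import bayescr as b

true_spec = b.ModelSpec("leopard", "sex_specific", "fixed_zero", "fixed",
                        0.75, name="sex_specific_sigma")
alt_spec = b.ModelSpec("leopard", "shared", "estimated", "fixed",
                       0.75, name="shared_sigma")

pars = b.Parameters(sigma_f=0.8, sigma_m=2.4, lam0=0.12, beta_sex=0.0,
                    psi_sex=0.6, theta=0.75)
traps, mask, enc, truth = b.make_lmnp_fixture(
    seed=901, pixel_km=1.0, buffer_km=6.0, k_occasions=20,
    density_per_100km2=10.0, params=pars, spec=true_spec)
print(f"detected {enc.n} individuals "
      f"({(enc.sex == 'M').sum()} male, {(enc.sex == 'F').sum()} female)")

chains = {}
for spec in (true_spec, alt_spec):
    cfg = b.McmcConfig(n_iter=2000, burn_in=700, n_chains=1, nz=150, seed=4)
    chains[spec.name] = b.run_mcmc(spec, enc, traps, mask, cfg)[0]

ranking = b.rank_models(chains)
print(ranking)
print(f"selected: {ranking.selected}")
# log_ml differences of a few nats are decisive; the standard error column
# shows the Monte-Carlo uncertainty of each estimate.
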