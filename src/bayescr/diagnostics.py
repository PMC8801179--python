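"""Convergence and adequacy diagnostics for fitted SECR chains.

Convergence uses the classic (non-split) Gelman-Rubin potential scale
reduction factor; values below 1.2 for every parameter are taken as
converged, following common camera-trap SECR practice.  Adequacy uses a
posterior predictive (Bayesian) p-value on individual encounter totals with
the Freeman-Tukey discrepancy; values inside (0.15, 0.85) are taken as an
adequate fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import Parameters

__all__ = ["gelman_rubin", "gelman_rubin_report", "bayes_pvalue",
           "DiagnosticsReport", "diagnostics_report"]


def _extract(chains, parameter):
    arrs = []
    for c in chains:
        arrs.append(np.asarray(c.get(parameter) if hasattr(c, "get") else c, dtype=float))
    return arrs


def gelman_rubin(chains: Sequence, parameter: Optional[str] = None, split: bool = False) -> float:
    """Potential scale reduction factor sqrt(((m-1)/m * W + B/m) / W).

    ``chains`` may be Chain objects (then ``parameter`` selects the draws) or
    plain 1-D arrays.  ``split=True`` halves each chain first (a more
    conservative variant).  Zero within-chain variance with spread means
    returns ``inf`` with a warning.
    """
    arrs = _extract(chains, parameter)
    if len(arrs) < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    m = min(len(a) for a in arrs)
    if m < 10:
        raise ValueError("chains must have length >= 10")
    arrs = [a[:m] for a in arrs]
    if split:
        half = m // 2
        arrs = [a[:half] for a in arrs] + [a[-half:] for a in arrs]
        m = half
    x = np.stack(arrs)  # (c, m)
    means = x.mean(axis=1)
    w = float(x.var(axis=1, ddof=1).mean())
    b_over_m = float(means.var(ddof=1))  # = B/m
    if w == 0.0:
        if b_over_m == 0.0:
            return 1.0
        warnings.warn("zero within-chain variance; returning inf", stacklevel=2)
        return float(np.inf)
    var_hat = (m - 1) / m * w + b_over_m
    return float(np.sqrt(var_hat / w))


def gelman_rubin_report(chains: Sequence, split: bool = False) -> dict:
    """PSRF for every free parameter of the chains' model spec."""
    spec = chains[0].spec
    return {p: gelman_rubin(chains, p, split=split) for p in spec.free_parameters}


def bayes_pvalue(
    chain,
    data,
    traps,
    mask,
    seed: int = 0,
    n_draws: int = 1000,
    mode: str = "conditional",
) -> float:
    """Posterior predictive p-value on individual encounter totals.

    For each retained draw, data replicated from the model are compared with
    the observed data through the Freeman-Tukey discrepancy
    ``T = sum_i (sqrt(e_i) - sqrt(E_i))^2`` over individual total encounter
    counts (e_i observed or replicated, E_i expected).  Returns the
    proportion of draws with ``T_rep >= T_obs``.

    ``mode="conditional"`` conditions on the retained latent states (z, s,
    sex); ``mode="marginal"`` redraws them from their priors at each draw.
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    if chain.s_draws is None:
        raise ValueError("chain does not retain latent draws; re-run with retain_latents=True")
    rng = np.random.default_rng(seed)
    t = chain.n_draws
    use = np.linspace(0, t - 1, min(n_draws, t)).astype(int)
    hx, hy = mask.habitat_xy
    effort_nights = traps.effort.sum(axis=1).astype(float)
    y_tot = np.zeros(chain.m)
    y_counts = np.zeros((chain.m, traps.n_stations))
    y_counts[: data.n] = data.y.sum(axis=2)
    y_tot[: data.n] = y_counts[: data.n].sum(axis=1)

    n_pix = hx.size
    t_obs = np.empty(use.size)
    t_rep = np.empty(use.size)
    for a, tdx in enumerate(use):
        p = Parameters.from_vector(chain.params[tdx])
        if mode == "conditional":
            z = chain.z_draws[tdx].astype(bool)
            s = chain.s_draws[tdx]
            sex = chain.sex_draws[tdx]
        elif mode == "marginal":
            z = rng.random(chain.m) < p.psi
            z[: data.n] = True  # detected individuals are in the population
            s = rng.integers(0, n_pix, size=chain.m)
            sex = (rng.random(chain.m) >= p.psi_sex).astype(np.int8)
        else:
            raise ValueError("mode must be 'conditional' or 'marginal'")
        rows = np.flatnonzero(z)
        dx = hx[s[rows]][:, None] - traps.x[None, :]
        dy = hy[s[rows]][:, None] - traps.y[None, :]
        sig = np.where(sex[rows] == 1, p.sigma_m, p.sigma_f)
        logk = -((dx * dx + dy * dy) ** p.theta) / (2.0 * sig[:, None] ** 2)
        if chain.spec.uses_sex:
            logk += (p.beta_sex * sex[rows].astype(float))[:, None]
        pi = -np.expm1(-p.lam0 * np.exp(logk))
        e_exp = (effort_nights[None, :] * pi).sum(axis=1)
        t_obs[a] = np.sum((np.sqrt(y_tot[rows]) - np.sqrt(e_exp)) ** 2)
        y_rep = rng.binomial(effort_nights.astype(int)[None, :], pi).sum(axis=1)
        t_rep[a] = np.sum((np.sqrt(y_rep) - np.sqrt(e_exp)) ** 2)
    return float(np.mean(t_rep >= t_obs))


@dataclass
class DiagnosticsReport:
    """PSRF per parameter plus the adequacy p-value and flags."""

    psrf: dict
    bayes_p: Optional[float]
    n_chains: int
    converged: bool = field(init=False)
    adequate: Optional[bool] = field(init=False)

    def __post_init__(self) -> None:
        self.converged = all(v < 1.2 for v in self.psrf.values())
        self.adequate = None if self.bayes_p is None else (0.15 < self.bayes_p < 0.85)

    def to_json(self) -> str:
        return json.dumps(
            {
                "psrf": {k: float(v) for k, v in self.psrf.items()},
                "bayes_p": self.bayes_p,
                "converged": self.converged,
                "adequate": self.adequate,
                "n_chains": self.n_chains,
            },
            indent=2,
        )


def diagnostics_report(chains, data, traps, mask, seed: int = 0,
                       n_draws: int = 500) -> DiagnosticsReport:
    """Convergence + adequacy in one report (p-value from the first chain)."""
    psrf = gelman_rubin_report(chains) if len(chains) >= 2 else {
        p: float("nan") for p in chains[0].spec.free_parameters
    }
    bp = bayes_pvalue(chains[0], data, traps, mask, seed=seed, n_draws=n_draws)
    return DiagnosticsReport(psrf=psrf, bayes_p=bp, n_chains=len(chains))
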