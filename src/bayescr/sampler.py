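"""Metropolis-within-Gibbs sampler for the augmented SECR model.

Each iteration updates, in order:

1. the structural parameters lam0, sigma(s), beta_sex and theta by
   random-walk Metropolis (log scale for lam0 and sigma; plain scale for
   beta_sex and theta, the latter rejected outside [0.5, 1]);
2. activity centres ``s_i``: a Gibbs draw from the uniform habitat prior for
   excluded individuals (their likelihood is flat), and a symmetric
   pixel-window Metropolis proposal (with a small uniform-jump mixture) for
   included individuals;
3. inclusion indicators ``z_i`` of the augmented individuals by a Gibbs draw
   from their Bernoulli full conditional;
4. latent sexes of unknown-sex individuals by Gibbs (only when the model
   carries sex);
5. psi and psi_sex by conjugate Beta draws.

Fixed-mode parameters (beta_sex under ``fixed_zero``; theta under ``fixed``)
are never proposed.  Proposal scales adapt toward a 0.35 acceptance rate
during burn-in only (Robbins-Monro), frozen afterwards.  With the occasions
exchangeable given effort, the Bernoulli likelihood reduces to per-(i, j)
binomial sufficient statistics, which is what the sampler evaluates.

Priors (vague, documented in docs/methods.md): log lam0 flat on
[log 1e-6, log 10]; sigma ~ Uniform(0, half the state-space diagonal);
beta_sex ~ Normal(0, 10^2); theta ~ Uniform(0.5, 1); psi, psi_sex ~ Beta(1,1).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model_core import FEMALE, MALE, PARAM_NAMES, LatentState, ModelSpec, Parameters

__all__ = ["McmcConfig", "Priors", "Chain", "run_mcmc", "SecrSampler",
           "inclusion_probability", "update_inclusion"]

log = logging.getLogger(__name__)


@dataclass
class McmcConfig:
    """Sampler settings; defaults follow the survey protocol (20,000
    iterations, 5,000 burn-in, four chains)."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    n_chains: int = 4
    nz: Optional[int] = None  # default 4 * n
    thin: int = 1
    seed: int = 0
    proposal_scales: dict = field(
        default_factory=lambda: {"lam0": 0.4, "sigma_f": 0.2, "sigma_m": 0.2,
                                 "beta_sex": 0.5, "theta": 0.08}
    )
    adapt: bool = True
    retain_latents: bool = True
    store_observed_loglik: bool = True  # per-draw latent-marginalised loglik
    s_window: int = 3  # pixel radius of the activity-centre proposal window
    s_uniform_prob: float = 0.1  # mixture weight of the uniform jump fallback
    fix_detection_params: bool = False  # hold lam0/sigma/beta/theta at init (testing aid)
    init: Optional[Parameters] = None
    progress: int = 0  # log every N iterations (0 = silent)

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.nz is not None and self.nz < 1:
            raise ValueError("nz must be >= 1")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be >= 1")


@dataclass
class Priors:
    """Vague priors; sigma_max is half the state-space diagonal (km)."""

    lam0_bounds: tuple = (1e-6, 10.0)
    sigma_max: float = 50.0
    beta_sex_sd: float = 10.0
    theta_bounds: tuple = (0.5, 1.0)
    psi_ab: tuple = (1.0, 1.0)
    psi_sex_ab: tuple = (1.0, 1.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "Priors":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


@dataclass
class Chain:
    """Posterior draws of one MCMC chain plus provenance.

    ``params`` is (T, 7) in the canonical :data:`PARAM_NAMES` order (fixed
    parameters appear as constant columns); ``nsuper`` is the realized
    super-population size sum(z) per draw; ``region_counts`` maps each mask
    region label to its per-draw realized count.
    """

    params: np.ndarray
    nsuper: np.ndarray
    region_counts: dict
    loglik: np.ndarray
    spec: ModelSpec
    config: McmcConfig
    seed: int
    fingerprint: str
    m: int
    n: int
    acceptance: dict = field(default_factory=dict)
    priors: Optional[Priors] = None
    obs_loglik: Optional[np.ndarray] = None  # latent-marginalised, for ranking
    z_draws: Optional[np.ndarray] = None
    s_draws: Optional[np.ndarray] = None
    sex_draws: Optional[np.ndarray] = None

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    def get(self, name: str) -> np.ndarray:
        """Column of draws for one parameter name."""
        return self.params[:, PARAM_NAMES.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.params, columns=list(PARAM_NAMES))
        df["Nsuper"] = self.nsuper
        for r, c in sorted(self.region_counts.items()):
            df[f"N_{r}"] = c
        df["loglik"] = self.loglik
        return df


def inclusion_probability(psi, total_hazard):
    """P(z = 1 | all-zero history) = psi e^{-H} / (psi e^{-H} + 1 - psi).

    ``total_hazard`` H is the summed hazard over operating trap-nights, so
    e^{-H} is the probability of the observed all-zero history given
    inclusion.
    """
    total_hazard = np.asarray(total_hazard, dtype=float)
    p1 = psi * np.exp(-total_hazard)
    return p1 / (p1 + (1.0 - psi))


def update_inclusion(rng, psi, total_hazard, detected) -> np.ndarray:
    """Gibbs draw of z for augmented (all-zero history) individuals."""
    detected = np.asarray(detected, dtype=bool)
    if detected.any():
        raise ValueError("update_inclusion must only be called on augmented individuals")
    p = inclusion_probability(psi, total_hazard)
    return (rng.random(p.shape) < p).astype(np.int8)


def _data_fingerprint(data, traps, mask) -> str:
    h = hashlib.sha256()
    h.update(data.y.tobytes())
    h.update(np.ascontiguousarray(traps.xy).tobytes())
    h.update(traps.effort.tobytes())
    h.update(np.ascontiguousarray(mask.x).tobytes())
    h.update(mask.habitat.tobytes())
    return h.hexdigest()[:16]


class SecrSampler:
    """Sampler state machine; :func:`run_mcmc` is the public entry point."""

    def __init__(self, spec, data, traps, mask, config, rng, init=None):
        data.validate_against(traps)
        if traps.total_effort == 0:
            raise ValueError("trap array has zero total effort")
        self.spec, self.data, self.traps, self.mask = spec, data, traps, mask
        self.config, self.rng = config, rng
        n = data.n
        nz = config.nz if config.nz is not None else max(1, 4 * n)
        self.n, self.m = n, n + nz
        if self.m < n:
            raise ValueError("augmented size M must be >= n")

        hx, hy = mask.habitat_xy
        self.hx, self.hy = hx, hy
        self.n_pix = hx.size
        tx, ty = traps.x, traps.y
        self.d2 = (hx[:, None] - tx[None, :]) ** 2 + (hy[:, None] - ty[None, :]) ** 2
        self.effort_nights = traps.effort.sum(axis=1).astype(float)  # (J,)

        # binomial sufficient statistics
        self.y_counts = np.zeros((self.m, traps.n_stations))
        self.y_counts[:n] = data.y.sum(axis=2)
        self.y_tot = self.y_counts.sum(axis=1)

        # pixel grid lookup for windowed proposals
        self._build_grid()

        diag = float(np.hypot(hx.max() - hx.min() + 1, hy.max() - hy.min() + 1))
        self.priors = Priors(sigma_max=max(1e-3, diag / 2.0))

        # region bookkeeping
        self.region_of_pixel = mask.habitat_region
        self.regions = mask.region_labels

        self._theta_pow = None  # cache of d2**theta
        self._theta_cached = None
        self._init_state(init)

    # -- initialisation -----------------------------------------------------
    def _init_state(self, init):
        n, m = self.n, self.m
        rng = self.rng
        if init is None:
            sigma0 = self._sigma_init()
            init = Parameters(
                sigma_f=sigma0,
                sigma_m=sigma0,
                lam0=0.05,
                beta_sex=0.0,
                psi=min(0.9, max(0.1, 2.0 * n / m if m else 0.5)),
                psi_sex=0.5,
                theta=self.spec.theta_value if self.spec.theta_mode == "fixed" else 0.75,
            )
        p = init.copy()
        if self.spec.sigma_mode == "shared":
            p.sigma_m = p.sigma_f
        if self.spec.beta_sex_mode == "fixed_zero":
            p.beta_sex = 0.0
        if self.spec.theta_mode == "fixed":
            p.theta = self.spec.theta_value
        p.validate()
        self.params = p

        s = rng.integers(0, self.n_pix, size=m)
        for i in range(n):
            j, _ = np.nonzero(self.data.y[i])
            cx, cy = self.traps.x[j].mean(), self.traps.y[j].mean()
            s[i] = int(np.argmin((self.hx - cx) ** 2 + (self.hy - cy) ** 2))
        z = np.ones(m, dtype=np.int8)
        z[n:] = rng.random(m - n) < 0.5
        sex_code = self.data.sex_code
        sex = np.where(sex_code >= 0, sex_code, 0).astype(np.int8)
        unknown = np.concatenate([sex_code < 0, np.ones(m - n, dtype=bool)])
        sex = np.concatenate([sex, (rng.random(m - n) > p.psi_sex).astype(np.int8)])
        self.latent = LatentState(z=z, s=s, sex=sex)
        self.sex_unknown = unknown  # individuals whose sex is imputed

        self.scales = dict(self.config.proposal_scales)
        self.acc = {k: [0, 0] for k in
                    ("lam0", "sigma_f", "sigma_m", "beta_sex", "theta", "s")}
        self._ll = self._det_loglik_rows(np.arange(m), self.latent.s, self.latent.sex, p)

    def _sigma_init(self) -> float:
        """Data-driven starting sigma: RMS spread of each individual's
        detection stations about their centroid (recaptured individuals
        only), floored at half the trap spacing."""
        spreads = []
        for i in range(self.n):
            j, _ = np.nonzero(self.data.y[i])
            if np.unique(j).size < 2:
                continue
            tx, ty = self.traps.x[j], self.traps.y[j]
            spreads.append(np.sqrt(np.mean((tx - tx.mean()) ** 2 + (ty - ty.mean()) ** 2)))
        tx = self.traps.x
        spacing = np.median(np.sort(np.hypot(tx[:, None] - tx[None, :],
                                             self.traps.y[:, None] - self.traps.y[None, :]),
                                    axis=1)[:, 1]) if tx.size > 1 else 1.0
        base = float(np.mean(spreads)) if spreads else float(spacing)
        floor = 0.5 * float(np.sqrt(self.mask.pixel_area))
        return min(max(0.5 * float(spacing), base, floor, 1e-3),
                   0.95 * self.priors.sigma_max)

    def _build_grid(self):
        spacing = np.sqrt(self.mask.pixel_area)
        ix = np.round((self.hx - self.hx.min()) / spacing).astype(np.int64)
        iy = np.round((self.hy - self.hy.min()) / spacing).astype(np.int64)
        self.grid = np.full((ix.max() + 1, iy.max() + 1), -1, dtype=np.int64)
        self.grid[ix, iy] = np.arange(self.n_pix)
        self.pix_ix, self.pix_iy = ix, iy

    # -- likelihood machinery ----------------------------------------------
    def _theta_d2(self):
        th = self.params.theta
        if self._theta_cached != th:
            self._theta_pow = self.d2**th if th != 1.0 else self.d2
            self._theta_cached = th
        return self._theta_pow

    def _hazard_rows(self, rows, s_rows, sex_rows, p, d2t=None):
        """(len(rows), J) hazards at given pixels/sexes under parameters p."""
        d2t = self._theta_d2() if d2t is None else d2t
        sig = np.where(sex_rows == MALE, p.sigma_m, p.sigma_f)
        logk = -d2t[s_rows] / (2.0 * sig[:, None] ** 2)
        if self.spec.uses_sex and p.beta_sex != 0.0:
            logk = logk + (p.beta_sex * sex_rows.astype(float))[:, None]
        return p.lam0 * np.exp(logk)

    def _det_loglik_rows(self, rows, s_rows, sex_rows, p, d2t=None):
        """Per-individual detection log likelihood (ignoring z)."""
        h = self._hazard_rows(rows, s_rows, sex_rows, p, d2t)
        yc = self.y_counts[rows]
        with np.errstate(divide="ignore"):
            log_pi = np.where(yc > 0, np.log(-np.expm1(-h)), 0.0)
        ll = (yc * log_pi).sum(axis=1)
        ll -= ((self.effort_nights[None, :] - yc) * h).sum(axis=1)
        return ll

    def _total_hazard_rows(self, rows, p):
        """Summed hazard over operating trap-nights for given individuals."""
        h = self._hazard_rows(rows, self.latent.s[rows], self.latent.sex[rows], p)
        return (h * self.effort_nights[None, :]).sum(axis=1)

    # -- parameter updates --------------------------------------------------
    def _active_ll(self, p, d2t=None):
        act = np.flatnonzero(self.latent.z == 1)
        return act, self._det_loglik_rows(act, self.latent.s[act],
                                          self.latent.sex[act], p, d2t)

    def _try_param(self, name, proposal_fn):
        """Generic Metropolis step on one structural parameter."""
        act = np.flatnonzero(self.latent.z == 1)
        cur_total = self._ll[act].sum()
        prop, log_prior_ratio, d2t = proposal_fn()
        if prop is None:  # out of bounds -> reject
            self.acc[name][1] += 1
            return
        new_ll = self._det_loglik_rows(act, self.latent.s[act],
                                       self.latent.sex[act], prop, d2t)
        log_r = new_ll.sum() - cur_total + log_prior_ratio
        self.acc[name][1] += 1
        if np.log(self.rng.random()) < log_r:
            self.acc[name][0] += 1
            self.params = prop
            if d2t is not None:
                self._theta_pow, self._theta_cached = d2t, prop.theta
            self._ll[act] = new_ll

    def update_parameters(self):
        p = self.params
        pr = self.priors
        rng = self.rng

        def prop_lam0():
            u = np.log(p.lam0) + rng.normal(0, self.scales["lam0"])
            lo, hi = np.log(pr.lam0_bounds[0]), np.log(pr.lam0_bounds[1])
            if not (lo < u < hi):
                return None, 0.0, None
            q = p.copy(); q.lam0 = float(np.exp(u))
            return q, 0.0, None  # flat prior on log lam0

        self._try_param("lam0", prop_lam0)

        def make_sigma_prop(attr):
            def prop():
                cur = getattr(self.params, attr)
                v = np.log(cur) + rng.normal(0, self.scales[attr])
                sig = float(np.exp(v))
                if not (0 < sig < pr.sigma_max):
                    return None, 0.0, None
                q = self.params.copy()
                setattr(q, attr, sig)
                if self.spec.sigma_mode == "shared":
                    q.sigma_f = q.sigma_m = sig
                # uniform prior on sigma, proposal on log sigma -> Jacobian
                return q, float(v - np.log(cur)), None
            return prop

        self._try_param("sigma_f", make_sigma_prop("sigma_f"))
        if self.spec.sigma_mode == "sex_specific":
            self._try_param("sigma_m", make_sigma_prop("sigma_m"))

        if self.spec.beta_sex_mode == "estimated":
            def prop_beta():
                b = self.params.beta_sex + rng.normal(0, self.scales["beta_sex"])
                q = self.params.copy(); q.beta_sex = float(b)
                lpr = (self.params.beta_sex**2 - b**2) / (2.0 * pr.beta_sex_sd**2)
                return q, float(lpr), None
            self._try_param("beta_sex", prop_beta)

        if self.spec.theta_mode == "estimated":
            def prop_theta():
                t = self.params.theta + rng.normal(0, self.scales["theta"])
                if not (pr.theta_bounds[0] <= t <= pr.theta_bounds[1]):
                    return None, 0.0, None
                q = self.params.copy(); q.theta = float(t)
                return q, 0.0, self.d2**t
            self._try_param("theta", prop_theta)

    # -- latent updates -----------------------------------------------------
    def update_activity_centres(self):
        rng = self.rng
        lat = self.latent
        m = self.m

        # excluded individuals: full conditional is the uniform habitat prior
        off = np.flatnonzero(lat.z == 0)
        if off.size:
            lat.s[off] = rng.integers(0, self.n_pix, size=off.size)
            self._ll[off] = self._det_loglik_rows(off, lat.s[off], lat.sex[off], self.params)

        act = np.flatnonzero(lat.z == 1)
        if act.size == 0:
            return
        w = self.config.s_window
        cur = lat.s[act]
        uni = rng.random(act.size) < self.config.s_uniform_prob
        dix = rng.integers(-w, w + 1, size=act.size)
        diy = rng.integers(-w, w + 1, size=act.size)
        nx, ny = self.grid.shape
        px = self.pix_ix[cur] + dix
        py = self.pix_iy[cur] + diy
        ok = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
        prop = np.full(act.size, -1, dtype=np.int64)
        prop[ok] = self.grid[px[ok], py[ok]]
        prop[uni] = rng.integers(0, self.n_pix, size=int(uni.sum()))
        valid = prop >= 0  # proposals into non-habitat auto-reject
        rows = act[valid]
        if rows.size:
            new_ll = self._det_loglik_rows(rows, prop[valid], lat.sex[rows], self.params)
            accept = np.log(rng.random(rows.size)) < (new_ll - self._ll[rows])
            lat.s[rows[accept]] = prop[valid][accept]
            self._ll[rows[accept]] = new_ll[accept]
            self.acc["s"][0] += int(accept.sum())
        self.acc["s"][1] += act.size

    def update_inclusion(self):
        aug = np.arange(self.n, self.m)
        if aug.size == 0:
            return
        total_h = self._total_hazard_rows(aug, self.params)
        self.latent.z[aug] = update_inclusion(
            self.rng, self.params.psi, total_h, np.zeros(aug.size, dtype=bool)
        )

    def update_sex(self):
        if not self.spec.uses_sex:
            return
        unk = np.flatnonzero(self.sex_unknown)
        if unk.size == 0:
            return
        lat = self.latent
        p = self.params
        llf = self._det_loglik_rows(unk, lat.s[unk], np.zeros(unk.size, dtype=np.int8), p)
        llm = self._det_loglik_rows(unk, lat.s[unk], np.ones(unk.size, dtype=np.int8), p)
        z = lat.z[unk].astype(float)
        a = np.log(p.psi_sex) + z * llf
        b = np.log1p(-p.psi_sex) + z * llm
        pf = 1.0 / (1.0 + np.exp(b - a))
        new_sex = (self.rng.random(unk.size) >= pf).astype(np.int8)  # 0=F, 1=M
        lat.sex[unk] = new_sex
        self._ll[unk] = np.where(new_sex == FEMALE, llf, llm)

    def update_psi(self):
        a0, b0 = self.priors.psi_ab
        k = int(self.latent.z.sum())
        self.params.psi = float(self.rng.beta(a0 + k, b0 + self.m - k))
        if self.spec.uses_sex:
            a0, b0 = self.priors.psi_sex_ab
            nf = int(np.sum(self.latent.sex == FEMALE))
            self.params.psi_sex = float(self.rng.beta(a0 + nf, b0 + self.m - nf))

    # -- bookkeeping --------------------------------------------------------
    def complete_loglik(self) -> float:
        lat, p = self.latent, self.params
        det = float(self._ll[lat.z == 1].sum())
        z = lat.z.astype(float)
        out = det + float(np.sum(z * np.log(p.psi) + (1 - z) * np.log1p(-p.psi)))
        if self.spec.uses_sex:
            fem = (lat.sex == FEMALE).astype(float)
            out += float(np.sum(fem * np.log(p.psi_sex) + (1 - fem) * np.log1p(-p.psi_sex)))
        return out - self.m * np.log(self.n_pix)

    def observed_loglik(self) -> float:
        """Latent-marginalised log likelihood at the current parameters
        (cached-distance twin of model_core.observed_data_loglik)."""
        from scipy.special import logsumexp

        p = self.params
        d2t = self._theta_d2()
        n = self.n
        sex_code = self.data.sex_code if n else np.zeros(0, dtype=np.int8)
        sex_values = (FEMALE, MALE) if self.spec.uses_sex else (FEMALE,)
        per_sex = np.full((len(sex_values), max(n, 1)), -np.inf)
        log_p0 = np.empty(len(sex_values))
        yc = self.y_counts[:n]
        for a, sx in enumerate(sex_values):
            sig = p.sigma_m if sx == MALE else p.sigma_f
            off = p.beta_sex * sx if self.spec.uses_sex else 0.0
            h = p.lam0 * np.exp(off) * np.exp(-d2t / (2.0 * sig**2))
            log_p0[a] = logsumexp(-(h @ self.effort_nights)) - np.log(self.n_pix)
            if n:
                with np.errstate(divide="ignore"):
                    log_pi = np.log(-np.expm1(-h))
                log_pi[~np.isfinite(log_pi)] = -745.0
                ll = yc @ log_pi.T - (self.effort_nights[None, :] - yc) @ h.T
                per_sex[a] = logsumexp(ll, axis=1) - np.log(self.n_pix)
        if self.spec.uses_sex:
            wf, wm = np.log(p.psi_sex), np.log1p(-p.psi_sex)
            mixed = np.logaddexp(wf + per_sex[0], wm + per_sex[1])
            mixed[sex_code == FEMALE] = wf + per_sex[0][sex_code == FEMALE]
            mixed[sex_code == MALE] = wm + per_sex[1][sex_code == MALE]
            lp0 = np.logaddexp(wf + log_p0[0], wm + log_p0[1])
        else:
            mixed, lp0 = per_sex[0], log_p0[0]
        out = float(np.sum(np.log(p.psi) + mixed[:n])) if n else 0.0
        out += (self.m - n) * float(np.logaddexp(np.log(p.psi) + lp0, np.log1p(-p.psi)))
        return out

    def _adapt(self, batch):
        step = 1.0 / np.sqrt(batch)
        for k, (a, t) in self.acc.items():
            if k == "s" or t == 0:
                continue
            rate = a / t
            self.scales[k] = float(np.clip(self.scales[k] * np.exp((rate - 0.35) * step),
                                           1e-4, 50.0))
        for k in self.acc:
            self.acc[k] = [0, 0]

    def step(self):
        if not self.config.fix_detection_params:
            self.update_parameters()
        self.update_activity_centres()
        self.update_inclusion()
        self.update_sex()
        self.update_psi()
        # psi moved after _ll computed: _ll does not involve psi, nothing stale

    def run(self) -> Chain:
        cfg = self.config
        n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
        params_out = np.empty((n_keep, len(PARAM_NAMES)))
        nsuper = np.empty(n_keep, dtype=np.int64)
        loglik = np.empty(n_keep)
        obs_ll = np.empty(n_keep) if cfg.store_observed_loglik else None
        region_counts = {r: np.empty(n_keep, dtype=np.int64) for r in self.regions}
        retain = cfg.retain_latents
        z_d = np.empty((n_keep, self.m), dtype=np.int8) if retain else None
        s_d = np.empty((n_keep, self.m), dtype=np.int32) if retain else None
        x_d = np.empty((n_keep, self.m), dtype=np.int8) if retain else None

        batch, kept = 0, 0
        for it in range(cfg.n_iter):
            self.step()
            if cfg.adapt and it < cfg.burn_in and (it + 1) % 50 == 0:
                batch += 1
                self._adapt(batch)
            if it == cfg.burn_in - 1:
                for k in self.acc:
                    self.acc[k] = [0, 0]
            if cfg.progress and (it + 1) % cfg.progress == 0:
                log.info("iteration %d/%d", it + 1, cfg.n_iter)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
                params_out[kept] = self.params.as_vector()
                nsuper[kept] = self.latent.z.sum()
                loglik[kept] = self.complete_loglik()
                if obs_ll is not None:
                    obs_ll[kept] = self.observed_loglik()
                for r in self.regions:
                    in_r = self.region_of_pixel[self.latent.s] == r
                    region_counts[r][kept] = int(np.sum((self.latent.z == 1) & in_r))
                if retain:
                    z_d[kept] = self.latent.z
                    s_d[kept] = self.latent.s
                    x_d[kept] = self.latent.sex
                kept += 1

        q975 = np.quantile(nsuper, 0.975)
        if q975 > 0.9 * self.m:
            log.warning(
                "augmentation may be too small: upper 97.5%% quantile of "
                "Nsuper (%d) exceeds 0.9*M (M=%d); increase nz", int(q975), self.m
            )
        rates = {k: (a / t if t else np.nan) for k, (a, t) in self.acc.items()}
        return Chain(
            params=params_out, nsuper=nsuper, region_counts=region_counts,
            loglik=loglik, spec=self.spec, config=cfg, seed=cfg.seed,
            fingerprint=_data_fingerprint(self.data, self.traps, self.mask),
            m=self.m, n=self.n, acceptance=rates, priors=self.priors,
            obs_loglik=obs_ll, z_draws=z_d, s_draws=s_d, sex_draws=x_d,
        )


def run_mcmc(spec, data, traps, mask, config: McmcConfig) -> list[Chain]:
    """Run ``config.n_chains`` independent chains; returns one Chain each.

    Chain c uses the generator seeded with ``(config.seed, c)``; identical
    seeds give bit-identical chains.
    """
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        sampler = SecrSampler(spec, data, traps, mask, config, rng, init=config.init)
        chains.append(sampler.run())
    return chains
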