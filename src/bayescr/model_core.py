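"""Observation and state model for Bernoulli spatially explicit capture-recapture.

The model: each individual carries a latent activity centre ``s`` on a discrete
habitat grid. The per-occasion hazard of detection at a trap declines with the
distance ``d`` between centre and trap through a flexible kernel

    f(d) = exp(-d^(2*theta) / (2*sigma^2)),      theta in [0.5, 1],

which is the half-normal (Gaussian) kernel at ``theta = 1`` and an
exponential-in-distance kernel at ``theta = 0.5``.  The detection probability
on one trap-night follows from the complementary log-log link applied to the
hazard ``lam0 * exp(beta_sex * sex) * f(d)``:

    pi = 1 - exp(-lam0 * exp(beta_sex * sex) * f(d)),

so ``cloglog(pi) = log lam0 + beta_sex*sex + log f(d)``.  Population size is
handled by data augmentation: the n detected individuals are padded with nz
all-zero capture histories, each with an inclusion indicator
``z ~ Bernoulli(psi)``; realized abundance in a region is the number of
included centres that fall in it.  Sex (female = 0 baseline, male = 1) enters
the hazard via ``beta_sex`` and/or sex-specific ``sigma``; unknown sexes are
modelled as ``Bernoulli(1 - psi_sex)`` draws (``psi_sex`` = probability
female).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ModelSpec",
    "Parameters",
    "LatentState",
    "leopard_model",
    "hyena_model",
    "hazard_kernel",
    "encounter_prob",
    "complete_data_loglik",
    "n_real_in_region",
]

#: canonical parameter order used by chains and output tables
PARAM_NAMES = ("sigma_f", "sigma_m", "lam0", "beta_sex", "psi", "psi_sex", "theta")

FEMALE, MALE = 0, 1


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices defining one model variant.

    Parameters
    ----------
    species:
        Free-text tag; ``"hyena"`` activates the no-sex constraint (hyenas
        could not be sexed in the field, so their models carry no sex
        covariate and a single shared sigma).
    sigma_mode:
        ``"shared"`` (sigma_f == sigma_m) or ``"sex_specific"``.
    beta_sex_mode:
        ``"fixed_zero"`` or ``"estimated"``.
    theta_mode:
        ``"fixed"`` (at ``theta_value``) or ``"estimated"``.
    """

    species: str = "leopard"
    sigma_mode: str = "shared"
    beta_sex_mode: str = "fixed_zero"
    theta_mode: str = "fixed"
    theta_value: float = 0.75
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma_mode not in ("shared", "sex_specific"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.beta_sex_mode not in ("fixed_zero", "estimated"):
            raise ValueError(f"unknown beta_sex_mode {self.beta_sex_mode!r}")
        if self.theta_mode not in ("fixed", "estimated"):
            raise ValueError(f"unknown theta_mode {self.theta_mode!r}")
        if self.theta_mode == "fixed" and not (0.5 <= self.theta_value <= 1.0):
            raise ValueError("fixed theta must lie in [0.5, 1]")
        if self.species == "hyena" and (
            self.sigma_mode != "shared" or self.beta_sex_mode != "fixed_zero"
        ):
            raise ValueError(
                "hyena models carry no sex covariate: sigma_mode must be "
                "'shared' and beta_sex_mode 'fixed_zero'"
            )

    @property
    def uses_sex(self) -> bool:
        """Whether latent sex matters for the likelihood."""
        return self.sigma_mode == "sex_specific" or self.beta_sex_mode == "estimated"

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of parameters actually sampled under this spec."""
        names = ["lam0"]
        if self.sigma_mode == "sex_specific":
            names = ["sigma_f", "sigma_m"] + names
        else:
            names = ["sigma_f"] + names  # shared sigma stored in sigma_f (== sigma_m)
        if self.beta_sex_mode == "estimated":
            names.append("beta_sex")
        names.append("psi")
        if self.uses_sex:
            names.append("psi_sex")
        if self.theta_mode == "estimated":
            names.append("theta")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)


_LEOPARD_TABLE = {
    # model -> (sigma_mode, beta_sex_mode, theta_mode, theta_value)
    1: ("sex_specific", "estimated", "estimated", 0.75),
    2: ("sex_specific", "fixed_zero", "estimated", 0.75),
    3: ("sex_specific", "fixed_zero", "fixed", 0.75),
    4: ("sex_specific", "estimated", "fixed", 0.75),
    5: ("shared", "estimated", "fixed", 0.75),
    6: ("sex_specific", "estimated", "fixed", 1.0),
}

_HYENA_TABLE = {
    1: ("shared", "fixed_zero", "fixed", 1.0),
    2: ("shared", "fixed_zero", "estimated", 0.75),
}


def leopard_model(number: int) -> ModelSpec:
    """One of the six a-priori leopard model variants (sex covariate active)."""
    try:
        sm, bm, tm, tv = _LEOPARD_TABLE[number]
    except KeyError:
        raise ValueError(f"leopard model number must be 1..6, got {number}") from None
    return ModelSpec("leopard", sm, bm, tm, tv, name=f"leopard_{number}")


def hyena_model(number: int) -> ModelSpec:
    """Hyena variants (no sex covariate): 1 = Gaussian kernel, 2 = theta estimated."""
    try:
        sm, bm, tm, tv = _HYENA_TABLE[number]
    except KeyError:
        raise ValueError(f"hyena model number must be 1 or 2, got {number}") from None
    return ModelSpec("hyena", sm, bm, tm, tv, name=f"hyena_{number}")


@dataclass
class Parameters:
    """Current value of the structural parameters.

    Units: sigmas in km; ``lam0`` is a per-trap-night hazard; ``beta_sex`` on
    the cloglog (log-hazard) scale; ``psi`` and ``psi_sex`` probabilities;
    ``theta`` dimensionless in [0.5, 1].
    """

    sigma_f: float
    sigma_m: float
    lam0: float
    beta_sex: float = 0.0
    psi: float = 0.5
    psi_sex: float = 0.5
    theta: float = 0.75

    def validate(self) -> None:
        if not (self.sigma_f > 0 and self.sigma_m > 0):
            raise ValueError("sigma_f and sigma_m must be positive")
        if not self.lam0 > 0:
            raise ValueError("lam0 must be positive")
        if not (0.0 < self.psi < 1.0):
            raise ValueError("psi must lie in (0, 1)")
        if not (0.0 < self.psi_sex < 1.0):
            raise ValueError("psi_sex must lie in (0, 1)")
        if not (0.5 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0.5, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "Parameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, v))))

    def copy(self) -> "Parameters":
        return replace(self)


@dataclass
class LatentState:
    """Latent variables of the augmented model.

    ``z`` inclusion indicators (detected individuals fixed at 1), ``s``
    indices into the habitat pixels of the mask, ``sex`` in {0 female,
    1 male} (imputed where unknown).  Length of each array is M = n + nz.
    """

    z: np.ndarray
    s: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        if not (self.z.shape == self.s.shape == self.sex.shape):
            raise ValueError("z, s and sex must have equal length")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z entries must be 0/1")

    @property
    def m(self) -> int:
        return self.z.size

    @property
    def n_included(self) -> int:
        return int(self.z.sum())


def hazard_kernel(d, sigma: float, theta: float):
    """Distance-decline kernel exp(-d^(2*theta) / (2*sigma^2)).

    Accepts scalar or array ``d`` (km).  Equals the half-normal kernel at
    ``theta = 1`` and the exponential kernel at ``theta = 0.5``; strictly
    decreasing in ``d`` and equal to 1 at the origin.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not (0.5 <= theta <= 1.0):
        raise ValueError("theta must lie in [0.5, 1]")
    out = np.exp(-(d ** (2.0 * theta)) / (2.0 * sigma**2))
    return out if out.shape else float(out)


def encounter_prob(lam0: float, beta_sex: float, sex, kernel_value):
    """Per-trap-night detection probability under the cloglog link.

    ``pi = 1 - exp(-lam0 * exp(beta_sex * sex) * kernel_value)`` so that
    ``cloglog(pi) = log(lam0) + beta_sex*sex + log(kernel_value)``.
    """
    if not lam0 > 0:
        raise ValueError("lam0 must be positive")
    kernel_value = np.asarray(kernel_value, dtype=float)
    if np.any((kernel_value <= 0) | (kernel_value > 1)):
        raise ValueError("kernel_value must lie in (0, 1]")
    sex = np.asarray(sex, dtype=float)
    haz = lam0 * np.exp(beta_sex * sex) * kernel_value
    out = -np.expm1(-haz)
    return out if out.shape else float(out)


def _hazard_matrix(spec, params, s, sex, data_xy, mask):
    """Per-(individual, trap) hazard at the current latent state.

    ``data_xy`` is the (J, 2) array of trap coordinates; ``s`` indexes habitat
    pixels of ``mask``.  Returns (M, J) hazards.
    """
    hx, hy = mask.habitat_xy
    dx = hx[s][:, None] - data_xy[:, 0][None, :]
    dy = hy[s][:, None] - data_xy[:, 1][None, :]
    d2 = dx * dx + dy * dy
    sig = np.where(np.asarray(sex) == MALE, params.sigma_m, params.sigma_f)
    log_kern = -(d2 ** params.theta) / (2.0 * sig[:, None] ** 2)
    off = params.beta_sex * np.asarray(sex, dtype=float) if spec.uses_sex else 0.0
    off = np.broadcast_to(np.atleast_1d(off), (len(s),))
    return params.lam0 * np.exp(off[:, None] + log_kern)


def complete_data_loglik(spec, params, latent, data, traps, mask) -> float:
    """Complete-data log likelihood of the augmented model.

    Sums, over the M = n + nz individuals, the Bernoulli log-mass of the
    binary detections at every operating trap-night (success probability
    ``z_i * pi_ij``; excluded individuals contribute probability one through
    their all-zero histories), plus ``Bernoulli(z | psi)``, the sex mass
    ``Bernoulli(sex female | psi_sex)`` when the spec carries sex, and the
    uniform activity-centre prior over the habitat pixels.
    """
    params.validate()
    m = latent.m
    n = data.n
    if m < n:
        raise ValueError("augmented size M is smaller than number detected")
    if np.any(latent.s < 0) or np.any(latent.s >= mask.n_habitat):
        raise ValueError("activity centre index outside habitat support")
    y_counts = data.y.sum(axis=2)  # (n, J) detections per individual x trap
    if np.any((latent.z[:n] == 0) & (y_counts.sum(axis=1) > 0)):
        raise ValueError("impossible state: detections recorded for an individual with z = 0")
    if data.y.shape[1] != traps.n_stations or data.y.shape[2] != traps.n_occasions:
        raise ValueError("encounter array does not match trap array dimensions")

    effort_nights = traps.effort.sum(axis=1).astype(float)  # (J,)
    haz = _hazard_matrix(spec, params, latent.s, latent.sex, traps.xy, mask)

    det = 0.0
    included = np.flatnonzero(latent.z == 1)
    if included.size:
        h = haz[included]
        yc = np.zeros((included.size, traps.n_stations))
        obs = included[included < n]
        yc[np.searchsorted(included, obs)] = y_counts[obs]
        with np.errstate(divide="ignore"):
            log_pi = np.log(-np.expm1(-h))
        det = float(np.sum(np.where(yc > 0, yc * log_pi, 0.0))
                    - np.sum((effort_nights[None, :] - yc) * h))

    z = latent.z.astype(float)
    z_mass = float(np.sum(z * np.log(params.psi) + (1 - z) * np.log1p(-params.psi)))
    sex_mass = 0.0
    if spec.uses_sex:
        fem = (latent.sex == FEMALE).astype(float)
        sex_mass = float(
            np.sum(fem * np.log(params.psi_sex) + (1 - fem) * np.log1p(-params.psi_sex))
        )
    s_prior = -m * np.log(mask.n_habitat)
    return det + z_mass + sex_mass + s_prior


def observed_data_loglik(spec, params, data, traps, mask, n_augmented: int = 0) -> float:
    """Observed-data log likelihood of the augmented model.

    Marginalises the latent activity centre (uniform over habitat pixels),
    inclusion ``z ~ Bernoulli(psi)`` and — where unknown — sex out of the
    likelihood, leaving a function of the structural parameters alone: for a
    detected individual ``L_i = psi * mean_sex mean_pixel P(y_i | s, sex)``,
    and each of the ``n_augmented`` all-zero histories contributes
    ``psi * p0 + (1 - psi)`` with ``p0`` the marginal all-zero probability.
    This is the likelihood under which marginal-likelihood model ranking is
    well defined across models with different latent structures.
    """
    params.validate()
    from scipy.special import logsumexp

    hx, hy = mask.habitat_xy
    d2 = (hx[:, None] - traps.x[None, :]) ** 2 + (hy[:, None] - traps.y[None, :]) ** 2
    d2t = d2 ** params.theta
    effort_nights = traps.effort.sum(axis=1).astype(float)
    y_counts = data.y.sum(axis=2).astype(float)  # (n, J)
    n = data.n
    n_pix = mask.n_habitat
    sex_code = data.sex_code if n else np.zeros(0, dtype=np.int8)

    sex_values = (FEMALE, MALE) if spec.uses_sex else (FEMALE,)
    per_sex_ll = np.full((len(sex_values), max(n, 1)), -np.inf)
    log_p0_sex = np.empty(len(sex_values))
    for a, sx in enumerate(sex_values):
        sig = params.sigma_m if sx == MALE else params.sigma_f
        off = params.beta_sex * sx if spec.uses_sex else 0.0
        h = params.lam0 * np.exp(off) * np.exp(-d2t / (2.0 * sig**2))  # (P, J)
        neg_h_nights = -(h @ effort_nights)  # (P,) log P(all-zero | s)
        log_p0_sex[a] = logsumexp(neg_h_nights) - np.log(n_pix)
        if n:
            with np.errstate(divide="ignore"):
                log_pi = np.log(-np.expm1(-h))
            log_pi[~np.isfinite(log_pi)] = -745.0
            # (n, P): log P(y_i | s = p, sex)
            ll = y_counts @ log_pi.T - (effort_nights[None, :] - y_counts) @ h.T
            per_sex_ll[a] = logsumexp(ll, axis=1) - np.log(n_pix)

    if spec.uses_sex:
        wf, wm = np.log(params.psi_sex), np.log1p(-params.psi_sex)
        mixed = np.logaddexp(wf + per_sex_ll[0], wm + per_sex_ll[1])
        known_f, known_m = sex_code == FEMALE, sex_code == MALE
        mixed[known_f] = wf + per_sex_ll[0][known_f]
        mixed[known_m] = wm + per_sex_ll[1][known_m]
        log_p0 = np.logaddexp(wf + log_p0_sex[0], wm + log_p0_sex[1])
    else:
        mixed = per_sex_ll[0]
        log_p0 = log_p0_sex[0]

    out = 0.0
    if n:
        out += float(np.sum(np.log(params.psi) + mixed[:n]))
    if n_augmented:
        aug = np.logaddexp(np.log(params.psi) + log_p0, np.log1p(-params.psi))
        out += float(n_augmented * aug)
    return out


def n_real_in_region(latent, mask, region: Optional[str]) -> int:
    """Number of included individuals whose activity centre lies in ``region``.

    ``region=None`` (or ``"all"``) counts over all habitat pixels, i.e. the
    realized super-population size sum(z).
    """
    if region is None or region == "all":
        return int(latent.z.sum())
    labels = mask.habitat_region
    if region not in mask.region_labels:
        raise KeyError(f"unknown region label {region!r}")
    in_region = labels[latent.s] == region
    return int(np.sum((latent.z == 1) & in_region))
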