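"""Shared test utilities: independent brute-force oracles and random
small-instance generators (kept deliberately naive — triple loops and
scalar math — so they cannot share bugs with the vectorised package code)."""

from __future__ import annotations

import math

import numpy as np

from bayescr import EncounterData, HabitatMask, LatentState, ModelSpec, Parameters, TrapArray


def loglik_bruteforce(spec, params, latent, data, traps, mask) -> float:
    """Triple-loop complete-data log likelihood (independent oracle)."""
    hx, hy = mask.habitat_xy
    total = 0.0
    m = latent.m
    n = data.n
    for i in range(m):
        sig = params.sigma_m if latent.sex[i] == 1 else params.sigma_f
        off = params.beta_sex * latent.sex[i] if spec.uses_sex else 0.0
        px, py = hx[latent.s[i]], hy[latent.s[i]]
        if latent.z[i] == 1:
            for j in range(traps.n_stations):
                d = math.hypot(px - traps.x[j], py - traps.y[j])
                kern = math.exp(-(d ** (2 * params.theta)) / (2 * sig**2))
                haz = params.lam0 * math.exp(off) * kern
                # Bernoulli masses: P(y=0) = exp(-haz) exactly under the
                # cloglog link, so its log is -haz; stable for any hazard
                log_p1 = math.log(-math.expm1(-haz))
                for k in range(traps.n_occasions):
                    if traps.effort[j, k] == 0:
                        continue
                    yijk = data.y[i, j, k] if i < n else 0
                    total += log_p1 if yijk else -haz
        total += math.log(params.psi) if latent.z[i] == 1 else math.log(1.0 - params.psi)
        if spec.uses_sex:
            total += math.log(params.psi_sex) if latent.sex[i] == 0 else math.log(
                1.0 - params.psi_sex
            )
        total += math.log(1.0 / mask.n_habitat)
    return total


def random_instance(rng):
    """A random small but valid (spec, params, latent, data, traps, mask)."""
    j = int(rng.integers(2, 5))
    k = int(rng.integers(1, 6))
    n = int(rng.integers(1, 4))
    m = n + int(rng.integers(1, 4))
    p = int(rng.integers(2, 7))

    traps = TrapArray(
        np.array([f"t{a}" for a in range(j)], dtype=object),
        rng.uniform(0, 4, j),
        rng.uniform(0, 4, j),
        (rng.random((j, k)) < 0.85).astype(np.int8),
    )
    if traps.total_effort == 0:
        traps.effort[0, 0] = 1
    mask = HabitatMask(
        x=np.arange(p, dtype=float),
        y=np.zeros(p) + rng.uniform(0, 4),
        pixel_area=1.0,
        habitat=np.ones(p, dtype=int),
    )
    sigma_mode = rng.choice(["shared", "sex_specific"])
    beta_mode = rng.choice(["fixed_zero", "estimated"])
    theta_mode = rng.choice(["fixed", "estimated"])
    spec = ModelSpec("synthetic", sigma_mode, beta_mode, theta_mode, 0.75)
    sf = rng.uniform(0.5, 3.0)
    params = Parameters(
        sigma_f=sf,
        sigma_m=sf if sigma_mode == "shared" else rng.uniform(0.5, 3.0),
        lam0=rng.uniform(0.01, 1.0),
        beta_sex=0.0 if beta_mode == "fixed_zero" else rng.uniform(-1.5, 1.5),
        psi=rng.uniform(0.1, 0.9),
        psi_sex=rng.uniform(0.1, 0.9),
        theta=0.75 if theta_mode == "fixed" else rng.uniform(0.5, 1.0),
    )
    # detections only where effort allows; every detected individual >= 1
    y = np.zeros((n, j, k), dtype=np.int8)
    cells = np.argwhere(traps.effort == 1)
    for i in range(n):
        take = cells[rng.integers(0, len(cells), size=int(rng.integers(1, 4)))]
        y[i, take[:, 0], take[:, 1]] = 1
    data = EncounterData(
        np.array([f"i{a}" for a in range(n)], dtype=object),
        y,
        rng.choice(["F", "M", "U"], size=n).astype(object),
    )
    z = np.concatenate([np.ones(n, dtype=np.int8),
                        (rng.random(m - n) < 0.5).astype(np.int8)])
    latent = LatentState(
        z=z,
        s=rng.integers(0, p, size=m),
        sex=(rng.random(m) < 0.5).astype(np.int8),
    )
    return spec, params, latent, data, traps, mask
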