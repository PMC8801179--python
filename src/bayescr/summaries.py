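"""Posterior summaries: density, abundance, density surface, detection rate.

Density is realized density: per retained draw, the number of included
activity centres in a region divided by the region's habitat area, times 100
(individuals per 100 km^2).  Abundance is the realized count itself.
Credible intervals are equal-tailed percentile intervals (2.5/97.5); the
posterior SD is the sample SD over retained draws (denominator N-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensityEstimate",
    "density_in_region",
    "abundance_in_region",
    "realized_density_surface",
    "detection_rate",
    "format_rate",
    "summary_table",
]


@dataclass
class DensityEstimate:
    """Posterior mean/SD and central 95% CI for a density or abundance."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    region: Optional[str]
    area_km2: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("credible interval bounds out of order")
        if self.area_km2 <= 0:
            raise ValueError("region area must be positive")


def _as_chains(chain) -> list:
    return list(chain) if isinstance(chain, (list, tuple)) else [chain]


def _region_counts(chains, region):
    parts = []
    for c in chains:
        if region is None or region == "all":
            parts.append(np.asarray(c.nsuper, dtype=float))
        else:
            if region not in c.region_counts:
                raise KeyError(f"unknown region label {region!r}")
            parts.append(np.asarray(c.region_counts[region], dtype=float))
    return np.concatenate(parts)


def _summarise(values, region, area) -> DensityEstimate:
    lo, hi = np.percentile(values, [2.5, 97.5])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return DensityEstimate(float(values.mean()), sd, float(lo), float(hi), region, area)


def density_in_region(chain, mask, region: Optional[str] = None) -> DensityEstimate:
    """Posterior realized density (individuals / 100 km^2) in a region."""
    chains = _as_chains(chain)
    area = mask.area_of_region(region)
    counts = _region_counts(chains, region)
    return _summarise(100.0 * counts / area, region, area)


def abundance_in_region(chain, mask, region: Optional[str] = None) -> DensityEstimate:
    """Posterior realized abundance (count of included centres) in a region."""
    chains = _as_chains(chain)
    area = mask.area_of_region(region)
    counts = _region_counts(chains, region)
    return _summarise(counts, region, area)


def realized_density_surface(chain, mask) -> np.ndarray:
    """Per-habitat-pixel posterior mean count of included activity centres.

    Sums over pixels to the posterior mean of Nsuper.  Requires chains run
    with ``retain_latents=True``.
    """
    chains = _as_chains(chain)
    counts = np.zeros(mask.n_habitat)
    total = 0
    for c in chains:
        if c.s_draws is None:
            raise ValueError(
                "chain does not retain activity-centre draws; re-run the "
                "sampler with retain_latents=True to export a surface"
            )
        sel = c.z_draws.astype(bool)
        counts += np.bincount(c.s_draws[sel].ravel(), minlength=mask.n_habitat)
        total += c.n_draws
    return counts / total


def detection_rate(data, traps) -> float:
    """Detected individuals per 100 trap-nights: 100 * n / total effort."""
    eff = traps.total_effort
    if eff == 0:
        raise ValueError("zero total effort")
    return 100.0 * data.n / eff


def format_rate(value: float, convention: str = "truncate", decimals: int = 2) -> float:
    """Render a rate at 2 dp under either the truncation or rounding
    convention (survey reports are not always consistent about which)."""
    f = 10.0**decimals
    if convention == "truncate":
        return math.floor(value * f) / f
    if convention == "round":
        return round(value, decimals)
    raise ValueError("convention must be 'truncate' or 'round'")


def summary_table(chains_by_model: dict, mask, regions: Sequence[Optional[str]],
                  species: str = "") -> pd.DataFrame:
    """Density + abundance rows per (model, region); delimited-text friendly."""
    rows = []
    for model, chain in chains_by_model.items():
        for region in regions:
            d = density_in_region(chain, mask, region)
            a = abundance_in_region(chain, mask, region)
            rows.append({
                "species": species, "model": model,
                "region": "all" if region is None else region,
                "area_km2": d.area_km2,
                "density_mean": d.mean, "density_sd": d.sd,
                "density_ci_low": d.ci_low, "density_ci_high": d.ci_high,
                "abundance_mean": a.mean, "abundance_sd": a.sd,
                "abundance_ci_low": a.ci_low, "abundance_ci_high": a.ci_high,
            })
    return pd.DataFrame(rows)
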