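"""Input containers and on-disk dialects for SECR camera-trap surveys.

Three file kinds are read and validated:

* ``traps.csv`` — ``station_id,x,y[,occ_1..occ_K]``: station coordinates in
  planar km plus an optional per-occasion binary operational indicator
  (missing effort columns mean "operational throughout").
* ``encounters.csv`` — long ("record") layout ``individual_id,station_id,
  occasion`` with one row per detection, or the wide alternative
  ``individual_id,station_id,occ_1..occ_K`` holding a binary matrix block per
  individual x station.  An optional ``sex.csv`` (``individual_id,sex`` with
  F/M/U) supplies sex labels.
* ``mask.csv`` — ``x,y,habitat[,region]`` pixel centres with a binary habitat
  flag; the (single) pixel area in km^2 comes from a ``# pixel_area_km2=...``
  header comment, the ``pixel_area`` argument, or — with a warning — the
  inferred grid spacing.

Chains are written as plain delimited text (one row per retained draw, one
column per parameter plus realized N per region) beside a YAML metadata
sidecar; latent draws go to an optional extra CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model_core import PARAM_NAMES

__all__ = [
    "TrapArray",
    "EncounterData",
    "HabitatMask",
    "read_traps",
    "read_encounters",
    "read_mask",
    "write_traps",
    "write_encounters",
    "write_mask",
    "write_chain",
    "read_chain",
    "recentre",
    "validate_geometry",
]

SEX_LABELS = ("F", "M", "U")


@dataclass
class TrapArray:
    """Camera-trap stations: coordinates (km) and per-occasion effort."""

    station_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    effort: np.ndarray  # (J, K) binary

    def __post_init__(self) -> None:
        self.station_id = np.asarray(self.station_id, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=np.int8)
        j = self.station_id.size
        if j < 2:
            raise ValueError("a trap array needs at least 2 stations")
        if len(set(self.station_id)) != j:
            dup = pd.Series(self.station_id).value_counts()
            dup = dup[dup > 1].index.tolist()
            raise ValueError(f"duplicate station_id: {dup}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("trap coordinates must be finite")
        if self.effort.ndim != 2 or self.effort.shape[0] != j:
            raise ValueError("effort must be a stations x occasions matrix")
        if self.effort.shape[1] < 1:
            raise ValueError("need at least one occasion")
        if not np.isin(self.effort, (0, 1)).all():
            raise ValueError("effort entries must be 0/1")

    @property
    def n_stations(self) -> int:
        return self.station_id.size

    @property
    def n_occasions(self) -> int:
        return self.effort.shape[1]

    @property
    def total_effort(self) -> int:
        """Usable trap-nights: sum of the operational indicator."""
        return int(self.effort.sum())

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def station_index(self, station_id) -> int:
        idx = np.flatnonzero(self.station_id == station_id)
        if idx.size == 0:
            raise KeyError(f"unknown station_id {station_id!r}")
        return int(idx[0])


@dataclass
class EncounterData:
    """Binary detections y[i, j, k] with per-individual sex labels."""

    individual_id: np.ndarray
    y: np.ndarray  # (n, J, K) binary
    sex: np.ndarray  # per-individual label in {F, M, U}
    species: str = "unknown"

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=object)
        if self.y.ndim != 3:
            raise ValueError("y must be individuals x stations x occasions")
        if self.individual_id.size != self.y.shape[0] or self.sex.size != self.y.shape[0]:
            raise ValueError("individual_id/sex length must match y")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("detections must be binary")
        if self.y.shape[0] and not self.y.reshape(self.y.shape[0], -1).any(axis=1).all():
            bad = self.individual_id[~self.y.reshape(self.y.shape[0], -1).any(axis=1)]
            raise ValueError(f"individuals without any detection: {list(bad)}")
        if not np.isin(self.sex, SEX_LABELS).all():
            raise ValueError(f"sex labels must be one of {SEX_LABELS}")

    @property
    def n(self) -> int:
        """Number of detected individuals."""
        return self.y.shape[0]

    @property
    def sex_code(self) -> np.ndarray:
        """0 = female, 1 = male, -1 = unknown."""
        return np.select([self.sex == "F", self.sex == "M"], [0, 1], default=-1).astype(np.int8)

    def validate_against(self, traps: TrapArray) -> None:
        if self.y.shape[1] != traps.n_stations or self.y.shape[2] != traps.n_occasions:
            raise ValueError("encounter dimensions do not match the trap array")
        bad = self.y.astype(bool) & (traps.effort[None] == 0)
        if bad.any():
            i, j, k = np.nonzero(bad)
            recs = [
                (str(self.individual_id[a]), str(traps.station_id[b]), int(c) + 1)
                for a, b, c in zip(i[:10], j[:10], k[:10])
            ]
            raise ValueError(f"detections at non-functional trap-nights: {recs}")


@dataclass
class HabitatMask:
    """Discrete state space of candidate activity-centre pixels."""

    x: np.ndarray
    y: np.ndarray
    pixel_area: float  # km^2, equal for all pixels
    habitat: np.ndarray  # binary flag
    region: Optional[np.ndarray] = None  # per-pixel label

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.habitat = np.asarray(self.habitat).astype(bool)
        if not self.pixel_area > 0:
            raise ValueError("pixel_area must be positive")
        if self.habitat.sum() < 1:
            raise ValueError("mask contains no habitat pixel")
        if len({(a, b) for a, b in zip(self.x, self.y)}) != self.x.size:
            raise ValueError("pixel centres must be unique")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
            if self.region.size != self.x.size:
                raise ValueError("region labels must match pixel count")

    @property
    def n_pixels(self) -> int:
        return self.x.size

    @property
    def n_habitat(self) -> int:
        return int(self.habitat.sum())

    @property
    def habitat_xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.x[self.habitat], self.y[self.habitat]

    @property
    def habitat_region(self) -> np.ndarray:
        """Region label per habitat pixel ('' where none given)."""
        if self.region is None:
            return np.full(self.n_habitat, "", dtype=object)
        return self.region[self.habitat]

    @property
    def region_labels(self) -> tuple[str, ...]:
        if self.region is None:
            return ()
        return tuple(sorted({str(r) for r in self.region[self.habitat]}))

    def area_of_region(self, region: Optional[str]) -> float:
        """Habitat area (km^2) of a region, or of all habitat if None/'all'."""
        if region is None or region == "all":
            return self.n_habitat * self.pixel_area
        if region not in self.region_labels:
            raise KeyError(f"unknown region label {region!r}")
        return float(np.sum(self.habitat_region == region) * self.pixel_area)


# ---------------------------------------------------------------------------
# readers


def _numeric(series: pd.Series, column: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise ValueError(f"non-numeric value in column {column!r} at row {row + 2} (1-based incl. header)")
    return out.to_numpy(dtype=float)


def read_traps(path, n_occasions: Optional[int] = None, units: str = "km") -> TrapArray:
    """Read a trap-deployment file.

    Effort columns (any beyond station_id/x/y, in file order) define the
    per-occasion operational indicator; with none present, ``n_occasions`` is
    required and effort defaults to all-ones.  ``units="m"`` divides
    coordinates by 1000.
    """
    df = pd.read_csv(path)
    required = {"station_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"traps file must have columns {sorted(required)}")
    scale = {"km": 1.0, "m": 1e-3}[units]
    x = _numeric(df["x"], "x") * scale
    y = _numeric(df["y"], "y") * scale
    eff_cols = [c for c in df.columns if c not in required]
    if eff_cols:
        effort = df[eff_cols].to_numpy(dtype=float)
        if n_occasions is not None and effort.shape[1] != n_occasions:
            raise ValueError(
                f"file has {effort.shape[1]} effort columns but n_occasions={n_occasions}"
            )
        effort = effort.astype(np.int8)
    else:
        if n_occasions is None:
            raise ValueError("no effort columns in file: n_occasions is required")
        effort = np.ones((len(df), n_occasions), dtype=np.int8)
    return TrapArray(df["station_id"].astype(str).to_numpy(), x, y, effort)


def read_encounters(
    path,
    traps: TrapArray,
    sex_path=None,
    species: str = "unknown",
) -> EncounterData:
    """Read a capture-history file (long record or wide matrix layout).

    Duplicate (individual, station, occasion) records collapse to a single
    binary 1 — the binary proximity-detector convention that also enforces
    the upstream one-record-per-day rule at load time.
    """
    df = pd.read_csv(path)
    long_cols = {"individual_id", "station_id", "occasion"}
    k = traps.n_occasions
    ids: list[str]
    if long_cols.issubset(df.columns):
        ids = sorted(df["individual_id"].astype(str).unique())
        idx = {v: i for i, v in enumerate(ids)}
        y = np.zeros((len(ids), traps.n_stations, k), dtype=np.int8)
        occ = _numeric(df["occasion"], "occasion").astype(int)
        if np.any((occ < 1) | (occ > k)):
            raise ValueError(f"occasion outside 1..{k}")
        for ind, st, o in zip(df["individual_id"].astype(str), df["station_id"].astype(str), occ):
            y[idx[ind], traps.station_index(st), o - 1] = 1
    elif {"individual_id", "station_id"}.issubset(df.columns):
        occ_cols = [c for c in df.columns if c not in ("individual_id", "station_id")]
        if len(occ_cols) != k:
            raise ValueError(f"wide layout needs {k} occasion columns, found {len(occ_cols)}")
        ids = sorted(df["individual_id"].astype(str).unique())
        idx = {v: i for i, v in enumerate(ids)}
        y = np.zeros((len(ids), traps.n_stations, k), dtype=np.int8)
        block = df[occ_cols].to_numpy(dtype=float)
        for r, (ind, st) in enumerate(zip(df["individual_id"].astype(str), df["station_id"].astype(str))):
            y[idx[ind], traps.station_index(st)] |= (block[r] > 0).astype(np.int8)
    else:
        raise ValueError(
            "encounters file must be long (individual_id,station_id,occasion) "
            "or wide (individual_id,station_id,occ_1..occ_K)"
        )
    sex = np.full(len(ids), "U", dtype=object)
    if sex_path is not None:
        sdf = pd.read_csv(sex_path)
        if not {"individual_id", "sex"}.issubset(sdf.columns):
            raise ValueError("sex file must have columns individual_id,sex")
        lookup = dict(zip(sdf["individual_id"].astype(str), sdf["sex"].astype(str).str.upper()))
        for i, ind in enumerate(ids):
            lab = lookup.get(ind, "U")
            if lab not in SEX_LABELS:
                raise ValueError(f"bad sex label {lab!r} for {ind!r}")
            sex[i] = lab
    data = EncounterData(np.array(ids, dtype=object), y, sex, species=species)
    data.validate_against(traps)
    return data


def read_mask(path, pixel_area: Optional[float] = None) -> HabitatMask:
    """Read a habitat-mask file; see module docstring for the dialect."""
    header_area = None
    with open(path) as fh:
        comments = []
        for line in fh:
            if line.startswith("#"):
                comments.append(line)
            else:
                break
    for line in comments:
        if "pixel_area_km2" in line:
            header_area = float(line.split("=")[1])
    df = pd.read_csv(path, comment="#")
    if "habitat" not in df.columns:
        raise ValueError("mask file must have a 'habitat' column")
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError("mask file must have x and y columns")
    x = _numeric(df["x"], "x")
    y = _numeric(df["y"], "y")
    area = pixel_area if pixel_area is not None else header_area
    ux = np.unique(np.round(np.diff(np.unique(x)), 9))
    if area is None:
        spacing = float(ux[0]) if ux.size else 1.0
        area = spacing**2
        warnings.warn(
            f"pixel_area not supplied; inferred {area:.6g} km^2 from grid spacing",
            stacklevel=2,
        )
    if ux.size > 1 and not np.allclose(ux, ux[0] * np.round(ux / ux[0])):
        warnings.warn("mask grid spacing looks inconsistent", stacklevel=2)
    region = df["region"].astype(str).to_numpy(dtype=object) if "region" in df.columns else None
    return HabitatMask(x, y, float(area), df["habitat"].to_numpy(), region)


def recentre(traps: TrapArray, mask: HabitatMask) -> tuple[TrapArray, HabitatMask]:
    """Shift trap and mask coordinates jointly so the trap centroid is (0, 0).

    Keeping the shift joint preserves the trap-pixel geometry; sigma stays in
    km regardless of the projected origin of the input files.
    """
    cx, cy = float(traps.x.mean()), float(traps.y.mean())
    t = TrapArray(traps.station_id, traps.x - cx, traps.y - cy, traps.effort)
    m = HabitatMask(mask.x - cx, mask.y - cy, mask.pixel_area, mask.habitat, mask.region)
    return t, m


def validate_geometry(traps: TrapArray, mask: HabitatMask) -> None:
    """Check every trap lies within the bounding box of the habitat pixels."""
    hx, hy = mask.habitat_xy
    pad = np.sqrt(mask.pixel_area)
    if (
        traps.x.min() < hx.min() - pad
        or traps.x.max() > hx.max() + pad
        or traps.y.min() < hy.min() - pad
        or traps.y.max() > hy.max() + pad
    ):
        raise ValueError("trap array extends beyond the habitat mask bounding box")


# ---------------------------------------------------------------------------
# writers


def write_traps(traps: TrapArray, path, include_effort: bool = True) -> None:
    df = pd.DataFrame({"station_id": traps.station_id, "x": traps.x, "y": traps.y})
    if include_effort:
        for k in range(traps.n_occasions):
            df[f"occ_{k + 1}"] = traps.effort[:, k]
    df.to_csv(path, index=False)


def write_encounters(data: EncounterData, traps: TrapArray, path, sex_path=None) -> None:
    """Write detections in the long record dialect (one row per detection)."""
    i, j, k = np.nonzero(data.y)
    df = pd.DataFrame(
        {
            "individual_id": data.individual_id[i],
            "station_id": traps.station_id[j],
            "occasion": k + 1,
        }
    )
    df.to_csv(path, index=False)
    if sex_path is not None:
        pd.DataFrame({"individual_id": data.individual_id, "sex": data.sex}).to_csv(
            sex_path, index=False
        )


def write_mask(mask: HabitatMask, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pixel_area_km2={mask.pixel_area!r}\n")
        df = pd.DataFrame({"x": mask.x, "y": mask.y, "habitat": mask.habitat.astype(int)})
        if mask.region is not None:
            df["region"] = mask.region
        df.to_csv(fh, index=False)


def write_chain(chain, path, include_latents: bool = False) -> None:
    """Write a chain as delimited text plus a YAML metadata sidecar.

    The main table has one row per retained draw and one column per
    parameter plus realized N per mask region.  Latent draws (z, s, sex) go
    to ``<path stem>.latents.csv`` when requested.
    """
    path = Path(path)
    if chain.n_draws == 0:
        raise ValueError("refusing to write an empty chain")
    df = pd.DataFrame(chain.params, columns=list(PARAM_NAMES))
    for label in sorted(chain.region_counts):
        df[f"N_{label}"] = chain.region_counts[label]
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    meta = {
        "spec": {
            "species": chain.spec.species,
            "sigma_mode": chain.spec.sigma_mode,
            "beta_sex_mode": chain.spec.beta_sex_mode,
            "theta_mode": chain.spec.theta_mode,
            "theta_value": chain.spec.theta_value,
            "name": chain.spec.name,
        },
        "seed": chain.seed,
        "n_iter": chain.config.n_iter,
        "burn_in": chain.config.burn_in,
        "thin": chain.config.thin,
        "nz": chain.m - chain.n,
        "m": chain.m,
        "n": chain.n,
        "fingerprint": chain.fingerprint,
        "param_names": list(PARAM_NAMES),
        "regions": sorted(chain.region_counts),
        "acceptance": {k: float(v) for k, v in chain.acceptance.items()},
        "priors": chain.priors.to_dict() if chain.priors is not None else None,
        "nsuper_mean": float(np.mean(chain.nsuper)),
    }
    with open(path.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    if include_latents:
        if chain.s_draws is None:
            raise ValueError("chain does not retain latent draws")
        lat = pd.DataFrame(
            np.hstack([chain.z_draws, chain.s_draws, chain.sex_draws]),
            columns=[f"z_{i}" for i in range(chain.m)]
            + [f"s_{i}" for i in range(chain.m)]
            + [f"sex_{i}" for i in range(chain.m)],
        )
        lat.to_csv(path.with_suffix(".latents.csv"), index=False)


def read_chain(path):
    """Round-trip companion of :func:`write_chain`."""
    from .model_core import ModelSpec
    from .sampler import Chain, McmcConfig, Priors

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    with open(path.with_suffix(".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    spec = ModelSpec(**meta["spec"])
    params = df[list(PARAM_NAMES)].to_numpy()
    regions = {r: df[f"N_{r}"].to_numpy(dtype=np.int64) for r in meta["regions"]}
    cfg = McmcConfig(
        n_iter=meta["n_iter"], burn_in=meta["burn_in"], thin=meta["thin"],
        nz=meta["nz"], seed=meta["seed"], n_chains=1,
    )
    z = s = sx = None
    lat_path = path.with_suffix(".latents.csv")
    if lat_path.exists():
        lat = pd.read_csv(lat_path).to_numpy(dtype=np.int64)
        m = meta["m"]
        z, s, sx = lat[:, :m].astype(np.int8), lat[:, m:2 * m], lat[:, 2 * m:].astype(np.int8)
    nsuper = (
        sum(regions.values()) if regions else params[:, 0] * 0
    )
    if regions:
        nsuper = np.sum([regions[r] for r in regions], axis=0)
    elif z is not None:
        nsuper = z.sum(axis=1)
    priors = Priors.from_dict(meta["priors"]) if meta.get("priors") else None
    return Chain(
        params=params,
        nsuper=np.asarray(nsuper, dtype=np.int64),
        region_counts=regions,
        loglik=np.full(len(df), np.nan),
        spec=spec,
        config=cfg,
        seed=meta["seed"],
        fingerprint=meta["fingerprint"],
        m=meta["m"],
        n=meta["n"],
        acceptance={k: float(v) for k, v in meta.get("acceptance", {}).items()},
        priors=priors,
        z_draws=z,
        s_draws=s,
        sex_draws=sx,
    )
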