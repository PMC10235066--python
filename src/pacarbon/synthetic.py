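"""Synthetic 1-km landscape with confounded protected-area placement.

Generates a self-contained world — covariate grid, protected areas (PAs),
spaceborne-lidar style footprints, forest-loss fractions, and a year-2000
baseline carbon layer — with known ground truth, so every downstream stage
(quality filtering, matching, effect estimation, loss attribution, baseline
check) is verifiable by parameter recovery.

Model
-----
The world is a flat equal-area plane of 1 km square cells.  Quantitative
covariates (elevation, slope, precipitation, temperatures, accessibility,
population) are spatially smooth Gaussian random fields.  A fixed linear
"suitability" index of those covariates drives *both* expected biomass and the
probability that a cell seeds a protected area, so protection is confounded
with biomass; ``confounding_strength`` scales the placement logit, with 0
recovering randomised placement.  Expected aboveground biomass density is

    AGBD(cell) = baseline(covariates) + delta * is_protected

with ``delta = pa_effect_delta`` the true causal effect of protection.
Cell-level heterogeneity not captured by the covariates is white noise, and
lidar shots add independent per-shot noise on top.

Footprints are sampled along parallel tracks (default 60 m along track, 600 m
between tracks, a random track azimuth per world) with random 5-km segment
drop-outs, which is what leaves some cells with fewer than the minimum shot
count required by the aggregation stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .config import LandscapeConfig

logger = logging.getLogger(__name__)

#: Quantitative covariates used by the propensity model (categoricals are
#: matched exactly and live in STRATUM_COVARIATES).
QUANT_COVARIATES = [
    "elevation", "slope", "precip", "tmin", "tmax",
    "dist_city", "dist_road", "travel_time", "pop_count", "pop_density",
]

STRATUM_COVARIATES = ["land_cover", "country", "ecoregion", "biome"]

# Weights of the suitability index over z-scored covariates: remote, wet,
# rugged, low-pressure cells are both carbon-rich and more likely to be
# protected.  The purely geometric accessibility covariates get small weights
# so the index variance is dominated by the fine-textured fields.
_INDEX_WEIGHTS = {
    "elevation": 0.3, "slope": 0.4, "precip": 0.8, "tmin": 0.15,
    "tmax": -0.15, "dist_city": 0.0, "dist_road": 0.0, "travel_time": 0.1,
    "pop_count": -0.15, "pop_density": -0.3,
}

_BIOME_NAMES = [
    "tropical_moist_forest", "grassland_savanna", "temperate_forest",
    "shrubland", "boreal_forest", "flooded_grassland",
]


@dataclass
class Landscape:
    """A generated world: cell table, PA table, and the held-out truth.

    ``truth`` (expected AGBD with and without protection per cell) exists for
    tests and calibration studies only; analysis stages never read it.
    """

    cells: pd.DataFrame
    pas: pd.DataFrame
    truth: pd.DataFrame
    true_delta: float
    config: LandscapeConfig

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.config.grid_rows, self.config.grid_cols)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardised Gaussian random field with correlation length ~sigma cells."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    return (f - f.mean()) / f.std()


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v)


def _grow_blob(rng: np.random.Generator, index_grid: np.ndarray,
               taken: np.ndarray, seed_cell: tuple[int, int],
               target: int, temperature: float = 2.0) -> list[tuple[int, int]]:
    """Grow a connected cell blob from ``seed_cell`` up to ``target`` cells.

    At each step the 4-neighbourhood frontier cell with the highest scaled
    suitability index plus Gumbel noise (scale ``temperature``) joins the
    blob; cells already protected are skipped.  The noise dominates at the
    margin, so cell-level protection probability is tilted toward high
    suitability without being deterministic in it (overlap is preserved).
    """
    nr, nc = index_grid.shape
    members = [seed_cell]
    in_blob = {seed_cell}
    frontier: dict[tuple[int, int], float] = {}

    def push(r: int, c: int) -> None:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and (rr, cc) not in in_blob \
                    and not taken[rr, cc] and (rr, cc) not in frontier:
                frontier[(rr, cc)] = (index_grid[rr, cc]
                                      + temperature * rng.gumbel())
    push(*seed_cell)
    while len(members) < target and frontier:
        best = max(frontier, key=lambda k: (frontier[k], -k[0], -k[1]))
        del frontier[best]
        members.append(best)
        in_blob.add(best)
        push(*best)
    return members


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a deterministic synthetic landscape from ``config``.

    Raises
    ------
    ValueError
        If the grid cannot host ``n_pas`` protected areas of the configured
        size with mutual separation (sizing error).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    nr, nc = config.grid_rows, config.grid_cols
    rows, cols = np.mgrid[0:nr, 0:nc]
    rows, cols = rows.ravel(), cols.ravel()
    x = cols + 0.5  # cell centres, km
    y = rows + 0.5

    # --- quantitative covariates ----------------------------------------------
    # two-scale mixture per field: large-scale climate/terrain structure plus
    # dominant fine texture (elevation, slope and population vary at km scale
    # in real landscapes); the fine component is what gives matching close
    # counterfactuals and the propensity fit a large effective sample
    sig = max(3.0, min(nr, nc) / 12.0)

    def _field() -> np.ndarray:
        coarse = _smooth_field(rng, (nr, nc), sig)
        fine = _smooth_field(rng, (nr, nc), 0.8)
        return (0.35 * coarse + 0.94 * fine).ravel()

    f = {k: _field() for k in ("elev", "slope", "precip", "t", "amp", "pop",
                               "tt")}
    elevation = 800.0 + 400.0 * f["elev"]
    slope = np.clip(10.0 + 6.0 * f["slope"] + 2.0 * np.abs(f["elev"]), 0.0, 60.0)
    precip = np.clip(1500.0 + 500.0 * f["precip"], 50.0, None)
    tmin = 12.0 + 3.0 * f["t"] - 0.006 * (elevation - 800.0)
    tmax = tmin + 10.0 + 2.0 * np.abs(f["amp"])

    n_cities = max(2, (nr * nc) // 2500)
    cities = rng.uniform([0, 0], [nc, nr], size=(n_cities, 2))
    d2 = (x[:, None] - cities[None, :, 0]) ** 2 + (y[:, None] - cities[None, :, 1]) ** 2
    dist_city = np.sqrt(d2.min(axis=1))
    road_xs = rng.uniform(0, nc, size=max(2, nc // 25))
    road_ys = rng.uniform(0, nr, size=max(2, nr // 25))
    dist_road = np.minimum(np.abs(x[:, None] - road_xs[None, :]).min(axis=1),
                           np.abs(y[:, None] - road_ys[None, :]).min(axis=1))
    travel_time = np.clip(0.6 * dist_city + 2.0 * dist_road
                          + 15.0 + 10.0 * f["tt"], 0.0, None)
    pop_density = np.exp(3.0 - 0.05 * dist_city + 0.6 * f["pop"])
    # cells are 1 km^2, so count ~ density up to settlement clustering
    pop_count = pop_density * np.exp(0.3 * _smooth_field(rng, (nr, nc), 2.0).ravel())

    cov = {
        "elevation": elevation, "slope": slope, "precip": precip,
        "tmin": tmin, "tmax": tmax, "dist_city": dist_city,
        "dist_road": dist_road, "travel_time": travel_time,
        "pop_count": pop_count, "pop_density": pop_density,
    }

    # --- suitability index: drives both biomass and protection ---------------
    # an exact linear combination of the observed covariates (so conditioning
    # on covariates fully removes confounding); fine-texture-dominated fields
    # keep its correlation length short, which is what lets a pixel-level
    # propensity model estimate the direction accurately
    index = np.zeros(nr * nc)
    for k, w in _INDEX_WEIGHTS.items():
        index += w * _zscore(cov[k])
    index = _zscore(index)

    # --- categorical strata ---------------------------------------------------
    country = np.minimum((cols * config.n_countries) // nc, config.n_countries - 1)
    n_continents = min(2, config.n_countries)
    continent = country % n_continents
    biome_idx = np.minimum((rows * config.n_biomes) // nr, config.n_biomes - 1)
    biome_names = [(_BIOME_NAMES[i % len(_BIOME_NAMES)] if i < len(_BIOME_NAMES)
                    else f"biome_{i}") for i in range(config.n_biomes)]
    # shorter correlation length than the climate fields so every ecoregion /
    # land-cover class occurs throughout each country x biome block and exact
    # strata retain unprotected members outside the PA buffers
    sig_cat = 3.0
    eco_field = _smooth_field(rng, (nr, nc), sig_cat).ravel()
    ecoregion = np.searchsorted(
        np.quantile(eco_field, np.linspace(0, 1, config.n_ecoregions + 1)[1:-1]),
        eco_field)
    # land cover forms large zones (coarse field): it is the categorical
    # protection priority (forest-type covers attract parks), and because it
    # is matched exactly it can never leak confounding into the pairs
    # independent of the quantitative covariates, so land-cover-driven
    # placement alone leaves their distributions balanced
    lc_field = _smooth_field(rng, (nr, nc), max(6.0, min(nr, nc) / 8.0)).ravel()
    land_cover = np.searchsorted(
        np.quantile(lc_field, np.linspace(0, 1, config.n_landcovers + 1)[1:-1]),
        lc_field)

    # --- protected-area placement (confounded) --------------------------------
    hw_lo, hw_hi = config.pa_halfwidth_range
    margin = hw_hi + 1
    sep = 2 * hw_hi + 3  # Chebyshev separation of centres keeps PAs disjoint
    if nr <= 2 * margin or nc <= 2 * margin:
        raise ValueError(
            f"grid {nr}x{nc} too small for PAs of half-width up to {hw_hi}")
    # placement: logistic in observed quantities — the suitability index
    # scaled by confounding_strength plus a land-cover priority offset
    # (high-cover classes attract parks; their large zones keep the exclusion
    # buffers overlapping instead of tiling the map)
    k = max(1, config.n_landcovers - 1)
    lc_offset = (2.0 * land_cover - k) / k  # in [-1, 1] by class
    logit = (config.confounding_strength * index
             + config.pa_clustering * lc_offset)
    weight = 1.0 / (1.0 + np.exp(-logit))
    eligible = ((rows >= margin) & (rows < nr - margin)
                & (cols >= margin) & (cols < nc - margin))
    weight = np.where(eligible, weight, 0.0)

    centers: list[tuple[int, int]] = []
    for _ in range(config.n_pas):
        total = weight.sum()
        if total <= 0:
            raise ValueError(
                f"grid {nr}x{nc} cannot host {config.n_pas} PAs with "
                f"half-width up to {hw_hi} and separation {sep}")
        idx = rng.choice(nr * nc, p=weight / total)
        r0, c0 = int(rows[idx]), int(cols[idx])
        centers.append((r0, c0))
        near = (np.abs(rows - r0) < sep) & (np.abs(cols - c0) < sep)
        weight = np.where(near, 0.0, weight)

    # PA shapes are grown cell-by-cell from each centre, preferring
    # high-suitability frontier cells (parks follow forests and terrain); this
    # keeps cell-level protection probability increasing in the suitability
    # index, which is what a pixel-level propensity model can learn.
    is_protected = np.zeros(nr * nc, dtype=bool)
    pa_id = np.full(nr * nc, -1, dtype=int)
    pa_rows = []
    index_grid = index.reshape(nr, nc)
    for pid, (r0, c0) in enumerate(centers):
        hw_r = int(rng.integers(hw_lo, hw_hi + 1))
        hw_c = int(rng.integers(hw_lo, hw_hi + 1))
        target = (2 * hw_r + 1) * (2 * hw_c + 1)
        members = _grow_blob(rng, config.confounding_strength * index_grid,
                             is_protected.reshape(nr, nc), (r0, c0), target)
        flat = np.array([r * nc + c for r, c in members])
        is_protected[flat] = True
        pa_id[flat] = pid
        rr = np.array([r for r, _ in members])
        cc2 = np.array([c for _, c in members])
        status_yr = int(rng.integers(config.pa_status_year_range[0],
                                     config.pa_status_year_range[1] + 1))
        pa_rows.append({
            "pa_id": pid, "status_yr": status_yr,
            "country": int(country[r0 * nc + c0]),
            "row_min": int(rr.min()), "row_max": int(rr.max()),
            "col_min": int(cc2.min()), "col_max": int(cc2.max()),
            "area_km2": float(len(members)),
        })
    pas = pd.DataFrame(pa_rows)

    # --- biomass truth ---------------------------------------------------------
    cell_noise = rng.normal(0.0, config.cell_noise_sd, size=nr * nc)
    baseline = np.clip(config.baseline_mean_agbd
                       + config.baseline_index_effect * index + cell_noise, 5.0, None)
    agbd_unprot = baseline
    agbd_prot = np.clip(baseline + config.pa_effect_delta, 0.0, None)
    agbd_expected = np.where(is_protected, agbd_prot, agbd_unprot)

    # --- forest-cover loss 2000-2019 ------------------------------------------
    conc = 50.0
    rate = np.where(is_protected, config.loss_rate_protected,
                    config.loss_rate_unprotected)
    loss = np.zeros(nr * nc)
    pos = rate > 0
    if pos.any():
        loss[pos] = rng.beta(rate[pos] * conc, (1.0 - rate[pos]) * conc)

    # --- year-2000 baseline carbon map ----------------------------------------
    status = np.where(pa_id >= 0, pas.set_index("pa_id")["status_yr"]
                      .reindex(pa_id.clip(min=0)).to_numpy(), 9999)
    years_pre2000 = np.clip(2000 - status, 0, None) * is_protected
    baseline_2000_agbd = np.clip(
        baseline + config.baseline_growth_per_year * years_pre2000, 0.0, None)
    baseline_agcd_2000 = 0.49 * baseline_2000_agbd

    cells = pd.DataFrame({
        "cell_id": np.arange(nr * nc), "row": rows, "col": cols, "x": x, "y": y,
        "country": pd.Series(country).map(lambda i: f"country_{i}"),
        "continent": pd.Series(continent).map(lambda i: f"continent_{i}"),
        "biome": pd.Series(biome_idx).map(lambda i: biome_names[i]),
        "ecoregion": pd.Series(ecoregion).map(lambda i: f"ecoregion_{i}"),
        "land_cover": pd.Series(land_cover).map(lambda i: f"landcover_{i}"),
        **{k: cov[k] for k in QUANT_COVARIATES},
        "is_protected": is_protected,
        "pa_id": np.where(pa_id >= 0, pa_id, np.nan),
        "loss_fraction": loss,
        "baseline_agcd_2000": baseline_agcd_2000,
    })
    pas["country"] = pas["country"].map(lambda i: f"country_{i}")
    # biome/continent of a PA: label of its centre cell
    center_ids = [(r0 * nc + c0) for (r0, c0) in centers]
    pas["continent"] = cells.loc[center_ids, "continent"].to_numpy()
    pas["biome"] = cells.loc[center_ids, "biome"].to_numpy()

    truth = pd.DataFrame({
        "cell_id": cells["cell_id"],
        "agbd_unprotected": agbd_unprot,
        "agbd_protected": agbd_prot,
        "agbd_expected": agbd_expected,
    })
    return Landscape(cells=cells, pas=pas, truth=truth,
                     true_delta=float(config.pa_effect_delta), config=config)


def sample_footprints(landscape: Landscape,
                      config: LandscapeConfig | None = None) -> pd.DataFrame:
    """Sample lidar footprints along parallel tracks crossing the grid.

    Per-shot AGBD is the cell expectation plus truncated Gaussian noise; height
    (RH98), canopy cover and plant area index are saturating monotone
    transforms of AGBD with independent noise, so structure metrics carry the
    same protection signal qualitatively.  Quality flag and sensitivity follow
    the configured contamination model.
    """
    config = config or landscape.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    nr, nc = landscape.grid_shape
    w, h = float(nc), float(nr)

    theta = np.deg2rad(rng.uniform(-20.0, 20.0))  # track azimuth from north
    d = np.array([np.sin(theta), np.cos(theta)])   # along-track unit vector
    nvec = np.array([np.cos(theta), -np.sin(theta)])
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]])
    v_proj, t_proj = corners @ nvec, corners @ d
    dv = config.track_spacing_m / 1000.0
    dt = config.footprint_spacing_along_m / 1000.0
    phase = rng.uniform(0, dv)
    v_vals = np.arange(v_proj.min() + phase, v_proj.max(), dv)
    t_vals = np.arange(t_proj.min(), t_proj.max(), dt)
    V, T = np.meshgrid(v_vals, t_vals, indexing="ij")
    X = V * nvec[0] + T * d[0]
    Y = V * nvec[1] + T * d[1]
    inside = (X >= 0) & (X < w) & (Y >= 0) & (Y < h)

    # 5-km along-track segment drop-outs
    seg = np.floor(T / 5.0).astype(int)
    seg -= seg.min()
    keep_seg = rng.random((len(v_vals), seg.max() + 1)) >= config.track_gap_fraction
    keep = inside & keep_seg[np.arange(len(v_vals))[:, None], seg]

    xs, ys = X[keep], Y[keep]
    cell = np.floor(ys).astype(int) * nc + np.floor(xs).astype(int)
    expect = landscape.truth["agbd_expected"].to_numpy()[cell]
    n = len(xs)
    agbd = np.clip(expect + rng.normal(0.0, config.shot_noise_sd, n), 0.0, None)
    rh98 = np.clip(45.0 * (1.0 - np.exp(-agbd / 80.0))
                   + rng.normal(0.0, 2.0, n), 0.0, None)
    cover = np.clip(agbd / (agbd + 60.0) + rng.normal(0.0, 0.05, n), 0.0, 1.0)
    pai = np.clip(6.0 * (1.0 - np.exp(-agbd / 100.0))
                  + rng.normal(0.0, 0.3, n), 0.0, None)
    quality = (rng.random(n) >= config.p_bad_quality).astype(int)
    a, b = config.sensitivity_beta
    sensitivity = rng.beta(a, b, n)

    return pd.DataFrame({
        "shot_id": np.arange(n), "cell_id": cell, "x": xs, "y": ys,
        "rh98": rh98, "canopy_cover": cover, "pai": pai, "agbd": agbd,
        "quality_flag": quality, "sensitivity": sensitivity,
    })


def pa_polygon(cells: pd.DataFrame, pid: int):
    """Shapely outline of a PA's cell set (union of 1-km cell squares)."""
    own = cells.loc[cells["pa_id"] == pid]
    boxes = [box(c, r, c + 1, r + 1)
             for r, c in zip(own["row"], own["col"])]
    return unary_union(boxes)


def write_landscape(landscape: Landscape, out_dir: str | Path,
                    footprints: pd.DataFrame | None = None) -> dict:
    """Write the landscape to ``out_dir``: PA GeoJSON, CSV tables, manifest.

    The truth table goes to a separate ``truth.csv`` so analysis stages cannot
    silently read it alongside the observable tables.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape.cells.to_csv(out / "cells.csv", index=False)
    landscape.pas.to_csv(out / "pas.csv", index=False)
    landscape.truth.to_csv(out / "truth.csv", index=False)
    if footprints is not None:
        footprints.to_csv(out / "footprints.csv", index=False)

    features = []
    for _, pa in landscape.pas.iterrows():
        features.append({
            "type": "Feature",
            "geometry": mapping(pa_polygon(landscape.cells, int(pa["pa_id"]))),
            "properties": {
                "pa_id": int(pa["pa_id"]), "status_yr": int(pa["status_yr"]),
                "country": pa["country"], "area_km2": float(pa["area_km2"]),
            },
        })
    geojson = {"type": "FeatureCollection", "features": features}
    (out / "pas.geojson").write_text(json.dumps(geojson, indent=1))

    manifest = {"seed": landscape.config.seed, "true_delta": landscape.true_delta,
                "config": landscape.config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("wrote landscape (%d cells, %d PAs) to %s",
                len(landscape.cells), len(landscape.pas), out)
    return manifest


def read_landscape(out_dir: str | Path) -> Landscape:
    """Round-trip reader for :func:`write_landscape` output."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    cfg_d = manifest["config"]
    for key in ("sensitivity_beta", "pa_halfwidth_range", "pa_status_year_range"):
        cfg_d[key] = tuple(cfg_d[key])
    config = LandscapeConfig(**cfg_d)
    cells = pd.read_csv(out / "cells.csv")
    pas = pd.read_csv(out / "pas.csv")
    truth = pd.read_csv(out / "truth.csv")
    return Landscape(cells=cells, pas=pas, truth=truth,
                     true_delta=manifest["true_delta"], config=config)


def read_pa_geojson(path: str | Path) -> pd.DataFrame:
    """Read a WDPA-style PA GeoJSON into a table with shapely geometries."""
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        props = dict(feat["properties"])
        props["geometry"] = shape(feat["geometry"])
        rows.append(props)
    return pd.DataFrame(rows)
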