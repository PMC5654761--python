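"""Synthetic worlds with known generative structure.

Real inputs to the pipeline — twenty global covariate surfaces, a
literature-derived reporting-effort layer, and geocoded emergence events with
uncertainty footprints — cannot be redistributed or rebuilt at desk scale.
This module generates structurally analogous worlds in which the truth is
known, so every stage (effort smoothing, resampling, boosting, validation,
bias correction) can be tested for recovery:

* spatially autocorrelated predictor fields (Gaussian-smoothed noise) with
  decadal drift for the time-varying trio (population, cropland, pasture)
  and derived inter-decadal change layers;
* an urban surface correlated with population (target rank correlation 0.7);
* a logistic true-risk surface driven by a known predictor subset;
* a reporting-effort surface coupled to urban land and population, emitted
  both as a per-article toponym match table and as the smoothed layer;
* events sampled proportional to true risk × effort^bias_strength with
  variable footprint precision (single cells up to k×k blocks).

All randomness flows from one seed through named substreams per stage, and a
world's metadata suffices to recompute its true-risk surface exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from . import reporting_effort as re_mod
from .events import EIDEvent, buffer_point
from .grid import DECADES, GridSpec, Layer, PredictorSet, diff_decades
from .reporting_effort import EffortLayer, ToponymMatch

#: Names of the time-varying covariates (4 decadal layers each) and of their
#: derived change series.
DECADAL_NAMES = ("human_population", "cropland", "pasture")
CHANGE_NAMES = ("population_change", "cropland_change", "pasture_change")

#: Static covariate analogues (land cover percentages, hosts, climate).
STATIC_NAMES = (
    "urban_land", "managed_vegetation", "mammal_richness",
    "livestock_headcount", "poultry_headcount", "gens_climate",
    "needleleaf_trees", "evergreen_broadleaf_trees", "deciduous_broadleaf_trees",
    "mixed_trees", "shrubs", "herbaceous_vegetation", "flooded_vegetation",
)

EFFORT_NAME = "reporting_effort"

#: Default active drivers of the true-risk surface, echoing the leading
#: ecological correlates the method is meant to detect (tropical forest
#: cover, host richness, climate) at equal effect sizes that give moderate
#: model performance (~25-35% training deviance explained) on ~150 events.
#: Static layers are used: a change-layer driver is temporally diluted
#: (samples from years outside its interval carry an unrelated change field)
#: and is exercised separately.
DEFAULT_DRIVERS = {
    "evergreen_broadleaf_trees": 1.5,
    "mammal_richness": 1.5,
    "gens_climate": 1.5,
}


@dataclass
class SynthConfig:
    """Generative parameters of a synthetic world."""

    n_lon: int = 40
    n_lat: int = 20
    n_events: int = 147
    drivers: dict = dc_field(default_factory=lambda: dict(DEFAULT_DRIVERS))
    intercept: float = -0.75
    bias_strength: float = 1.0
    footprint_precision: float = 0.5
    max_block: int = 4
    land_fraction: float = 0.6
    smooth_sigma: float = 1.2
    drift_scale: float = 0.35
    urban_pop_rho: float = 0.7
    effort_urban_coef: float = 1.0
    effort_pop_coef: float = 0.5
    effort_noise: float = 0.3
    n_articles: int = 1500
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 10:
            raise ValueError("n_events must be >= 10")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if not all(np.isfinite(list(self.drivers.values()))):
            raise ValueError("driver coefficients must be finite")


@dataclass
class SynthWorld:
    grid: GridSpec
    predictors: PredictorSet
    true_risk: Layer
    effort: EffortLayer
    matches: list[ToponymMatch]
    events: list[EIDEvent]
    metadata: dict


# ---------------------------------------------------------------------------
# Random-field helpers
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, int], sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian-smoothed white noise (wraps in longitude)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                        mode=("nearest", "wrap"))
    return (z - z.mean()) / z.std()


def _pct(z: np.ndarray, shift: float = 0.0, scale: float = 1.0) -> np.ndarray:
    """Logistic transform of a z-field into a [0, 100] percentage."""
    return 100.0 / (1.0 + np.exp(-(scale * z + shift)))


def gen_grid(config: SynthConfig, rng: np.random.Generator) -> GridSpec:
    """Land mask from a thresholded smooth field (~land_fraction of cells)."""
    shape = (config.n_lat, config.n_lon)
    z = _smooth_field(shape, config.smooth_sigma, rng)
    thr = np.quantile(z, 1.0 - config.land_fraction)
    return GridSpec(n_lon=config.n_lon, n_lat=config.n_lat, land_mask=z >= thr)


def gen_predictors(config: SynthConfig, grid: GridSpec,
                   rng: np.random.Generator) -> PredictorSet:
    """Generate the 19 non-effort covariate analogues.

    Time-varying names get one layer per decade built by drifting a base
    field; their change series are exact inter-decadal differences.  Urban
    land is generated correlated with the 2000 population field.
    """
    shape = grid.shape
    ps = PredictorSet()
    rho = config.urban_pop_rho

    # decadal trio with smooth drift
    z_pop = None
    for name in DECADAL_NAMES:
        z = _smooth_field(shape, config.smooth_sigma, rng)
        decade_layers = []
        for decade in DECADES:
            if name == "human_population":
                # log-sd 0.8: at ~9° cells aggregation damps the extremes of
                # the underlying fine-scale population distribution
                vals = 1e5 * np.exp(0.8 * z + 0.1 * (decade - 1970) / 10)
                if decade == 2000:
                    z_pop = z.copy()
            else:
                vals = _pct(z, shift=-0.5)
            decade_layers.append(Layer(name=name, values=vals,
                                       temporal=str(decade)))
            z = z + config.drift_scale * _smooth_field(shape,
                                                       config.smooth_sigma, rng)
            z = (z - z.mean()) / z.std()
        for lay in decade_layers:
            ps.add(lay)

    # change series from the decade layers themselves
    for cname, base in zip(CHANGE_NAMES, DECADAL_NAMES):
        slot = ps.layers_for(base)
        for d0, d1 in zip(DECADES[:-1], DECADES[1:]):
            ch = diff_decades(slot[str(d1)], slot[str(d0)])
            ps.add(Layer(name=cname, values=ch.values, temporal=ch.temporal))

    # static layers
    for name in STATIC_NAMES:
        z = _smooth_field(shape, config.smooth_sigma, rng)
        if name == "urban_land":
            z = rho * z_pop + np.sqrt(1 - rho ** 2) * z
            vals = _pct(z, shift=-1.5, scale=1.5)
        elif name == "mammal_richness":
            vals = 150.0 / (1.0 + np.exp(-z))
        elif name in ("livestock_headcount", "poultry_headcount"):
            vals = 1e4 * np.exp(z)
        elif name == "gens_climate":
            vals = 50.0 + 15.0 * z
        else:
            vals = _pct(z, shift=-0.5)
        ps.add(Layer(name=name, values=vals, temporal="static"))

    # mask all layers to land
    for name in ps.names():
        for lay in ps.layers_for(name).values():
            lay.values[~grid.land_mask] = np.nan
    return ps


def _land_standardize(vals: np.ndarray, land: np.ndarray) -> tuple:
    mu = float(np.nanmean(vals[land]))
    sd = float(np.nanstd(vals[land]))
    return (vals - mu) / sd, mu, sd


def gen_true_risk(predictors: PredictorSet, grid: GridSpec,
                  config: SynthConfig) -> tuple[Layer, dict]:
    """Logistic true-risk surface over the active drivers at the 2000 decade.

    Deterministic given the predictors and coefficients; the returned
    metadata (coefficients plus standardisation constants) suffices to
    recompute the layer exactly.
    """
    land = grid.land_mask
    eta = np.full(grid.shape, config.intercept)
    meta = {"intercept": config.intercept, "drivers": {}}
    for name, beta in config.drivers.items():
        if name not in predictors:
            raise KeyError(f"unknown driver {name!r}")
        vals = predictors.resolve(name, 2000).values
        z, mu, sd = _land_standardize(vals, land)
        eta = eta + beta * z
        meta["drivers"][name] = {"beta": beta, "mean": mu, "sd": sd}
    risk = 1.0 / (1.0 + np.exp(-eta))
    risk[~land] = np.nan
    return Layer(name="true_risk", values=risk, temporal="static"), meta


def recompute_true_risk(predictors: PredictorSet, grid: GridSpec,
                        meta: dict) -> Layer:
    """Rebuild the true-risk layer from stored metadata (bitwise identical)."""
    eta = np.full(grid.shape, meta["intercept"])
    for name, d in meta["drivers"].items():
        vals = predictors.resolve(name, 2000).values
        z = (vals - d["mean"]) / d["sd"]  # same op order as the generator
        eta = eta + d["beta"] * z
    risk = 1.0 / (1.0 + np.exp(-eta))
    risk[~grid.land_mask] = np.nan
    return Layer(name="true_risk", values=risk, temporal="static")


def gen_effort(predictors: PredictorSet, grid: GridSpec, config: SynthConfig,
               rng: np.random.Generator
               ) -> tuple[list[ToponymMatch], EffortLayer]:
    """Urban/population-skewed reporting effort with a synthetic match table.

    Per-cell article intensity is log-linear in standardised urban land and
    log-population plus smooth noise.  Articles draw a home cell from that
    intensity and emit 1–4 toponym matches with random raw weights; the
    match table is aggregated and smoothed through the reporting-effort
    module itself (population, urban and managed vegetation as covariates).
    """
    land = grid.land_mask
    z_urb, _, _ = _land_standardize(
        predictors.resolve("urban_land", 2000).values, land)
    logpop = np.log(predictors.resolve("human_population", 2000).values)
    z_pop, _, _ = _land_standardize(logpop, land)
    noise = _smooth_field(grid.shape, config.smooth_sigma, rng)
    lam = np.exp(config.effort_urban_coef * z_urb
                 + config.effort_pop_coef * z_pop
                 + config.effort_noise * noise)
    lam[~land] = 0.0
    p = (lam / lam.sum()).ravel()

    lons, lats = grid.lon_centers, grid.lat_centers
    matches: list[ToponymMatch] = []
    for a in range(config.n_articles):
        n_match = 1 + rng.poisson(0.8)
        cells = rng.choice(p.size, size=n_match, p=p)
        for flat in cells:
            r, c = divmod(int(flat), grid.n_lon)
            matches.append(ToponymMatch(
                article_id=f"a{a:05d}", lon=float(lons[c]), lat=float(lats[r]),
                raw_weight=float(rng.uniform(0.5, 1.5))))

    raw = re_mod.aggregate_matches(matches, grid)
    effort = re_mod.smooth_effort(
        raw, predictors, grid,
        covariate_names=["human_population", "urban_land",
                         "managed_vegetation"],
        seed=int(rng.integers(0, 2**31 - 1)))
    return matches, effort


def gen_events(true_risk: Layer, effort: Layer, grid: GridSpec,
               config: SynthConfig, rng: np.random.Generator
               ) -> list[EIDEvent]:
    """Sample events proportional to true risk × effort^bias_strength.

    With probability ``footprint_precision`` an event is precise: its
    footprint is the single sampled cell (point + 5 km buffer convention).
    Otherwise the footprint is the land portion of an up-to-``max_block``²
    cell block around the sampled cell (a coarse geocode).  Years are
    uniform over 1970–2008.
    """
    land = grid.land_mask
    w = np.where(land,
                 np.nan_to_num(true_risk.values)
                 * np.nan_to_num(effort.values) ** config.bias_strength,
                 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate all-zero event sampling weights")
    p = (w / total).ravel()

    events = []
    for i in range(config.n_events):
        flat = int(rng.choice(p.size, p=p))
        r, c = divmod(flat, grid.n_lon)
        year = int(rng.integers(1970, 2009))
        if rng.random() < config.footprint_precision:
            lon = float(grid.lon_centers[c])
            lat = float(grid.lat_centers[r])
            events.append(EIDEvent(id=f"ev{i:04d}", year=year,
                                   footprint=((r, c),), precise=True,
                                   geometry=buffer_point(lon, lat, 5.0)))
        else:
            k = int(rng.integers(2, config.max_block + 1))
            r0 = int(np.clip(r - rng.integers(0, k), 0, grid.n_lat - k))
            c0 = int(np.clip(c - rng.integers(0, k), 0, grid.n_lon - k))
            cells = [(rr, cc) for rr in range(r0, r0 + k)
                     for cc in range(c0, c0 + k) if land[rr, cc]]
            if not cells:
                cells = [(r, c)]
            lon0, lat0, _, _ = grid.cell_bounds(r0, c0)
            _, _, lon1, lat1 = grid.cell_bounds(r0 + k - 1, c0 + k - 1)
            events.append(EIDEvent(id=f"ev{i:04d}", year=year,
                                   footprint=tuple(cells), precise=False,
                                   geometry=box(lon0, lat0, lon1, lat1)))
    return events


def generate_world(config: SynthConfig | None = None) -> SynthWorld:
    """Generate a complete synthetic world from a single seed.

    Named substreams (grid, predictors, effort, events) keep each stage
    reproducible independently of the others.
    """
    config = config or SynthConfig()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_grid, rng_pred, rng_eff, rng_ev = \
        (np.random.default_rng(s) for s in streams)

    grid = gen_grid(config, rng_grid)
    predictors = gen_predictors(config, grid, rng_pred)
    true_risk, risk_meta = gen_true_risk(predictors, grid, config)
    matches, effort = gen_effort(predictors, grid, config, rng_eff)
    predictors.add(effort.smoothed.copy_with(name=EFFORT_NAME))
    events = gen_events(true_risk, effort.smoothed, grid, config, rng_ev)

    metadata = {
        "config": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in config.__dict__.items()},
        "true_risk": risk_meta,
        "n_land_cells": int(grid.land_mask.sum()),
    }
    return SynthWorld(grid=grid, predictors=predictors, true_risk=true_risk,
                      effort=effort, matches=matches, events=events,
                      metadata=metadata)


# ---------------------------------------------------------------------------
# Persistence (a complete world as plain-text files)
# ---------------------------------------------------------------------------

def write_world(world: SynthWorld, outdir: str | Path) -> dict[str, str]:
    """Write a world as CSV layers, a match table, GeoJSON events and
    JSON metadata; returns the path map."""
    from .events import events_to_geojson
    from .grid import layers_to_csv
    from .reporting_effort import matches_to_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers = [lay for name in world.predictors.names()
              for lay in world.predictors.layers_for(name).values()]
    layers += [world.true_risk, world.effort.raw]
    paths = {
        "layers": str(outdir / "layers.csv"),
        "matches": str(outdir / "matches.csv"),
        "events": str(outdir / "events.geojson"),
        "metadata": str(outdir / "metadata.json"),
        "land_mask": str(outdir / "land_mask.csv"),
    }
    layers_to_csv(layers, world.grid, paths["layers"])
    matches_to_csv(world.matches, paths["matches"])
    events_to_geojson(world.events, world.grid, paths["events"])
    mask = Layer(name="land_mask",
                 values=world.grid.land_mask.astype(float), temporal="static")
    layers_to_csv([mask], world.grid, paths["land_mask"])
    with open(paths["metadata"], "w") as fh:
        json.dump(world.metadata, fh, indent=2)
    return paths
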