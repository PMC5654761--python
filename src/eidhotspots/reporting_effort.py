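"""Reporting-effort surface: where the biomedical literature looks.

Observed disease-emergence events are conditioned on surveillance: places
that publish more get more events recorded.  The effort proxy starts from a
table of per-article place-name (toponym) matches with raw weights.  Weights
are normalised within each article (so one prolific article counts once),
scattered to the grid and summed; the raw surface is then smoothed and its
zero cells imputed with a Poisson boosted-regression-tree model driven by
covariates that plausibly explain publication intensity (population, urban
land, ...).

The text-mining pipeline that produces the match table is out of scope: this
module consumes the table as an input contract, and the synthetic-data
generator produces one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd

from .grid import GridSpec, Layer, PredictorSet

logger = logging.getLogger(__name__)

#: Relative floor applied to smoothed effort so that effort-weighted sampling
#: and the bias-correction division are always well defined.
EFFORT_FLOOR_REL = 1e-9


@dataclass
class ToponymMatch:
    """One place-name match inside one article."""

    article_id: str
    lon: float
    lat: float
    raw_weight: float

    def __post_init__(self):
        if self.raw_weight < 0:
            raise ValueError(
                f"article {self.article_id}: negative raw weight")


@dataclass
class EffortLayer:
    """Raw (article-normalised) and smoothed reporting-effort surfaces."""

    raw: Layer
    smoothed: Layer
    covariates_used: list[str] = field(default_factory=list)

    @property
    def floor(self) -> float:
        vals = self.smoothed.values
        return float(np.nanmax(vals)) * EFFORT_FLOOR_REL


def aggregate_matches(matches: Sequence[ToponymMatch], grid: GridSpec,
                      name: str = "reporting_effort_raw") -> Layer:
    """Normalise match weights per article and sum them onto the grid.

    Each article contributes total mass 1 (its weights are rescaled to sum
    to 1); articles whose weights are all zero are dropped with a warning.
    The global total therefore equals the number of contributing articles.
    """
    vals = np.zeros(grid.shape)
    if matches:
        df = pd.DataFrame({
            "article": [m.article_id for m in matches],
            "lon": [m.lon for m in matches],
            "lat": [m.lat for m in matches],
            "w": [m.raw_weight for m in matches],
        })
        totals = df.groupby("article")["w"].transform("sum")
        dead = totals == 0
        if dead.any():
            logger.warning(
                "aggregate_matches: dropping %d article(s) with all-zero weights",
                df.loc[dead, "article"].nunique())
            df = df[~dead]
            totals = totals[~dead]
        df = df.assign(w=df["w"] / totals)
        for r in df.itertuples():
            row, col = grid.cell_of(r.lon, r.lat)
            vals[row, col] += r.w
    out = vals.copy()
    out[~grid.land_mask] = np.nan
    return Layer(name=name, values=out, temporal="static")


def matches_to_csv(matches: Sequence[ToponymMatch], path: str | Path) -> None:
    pd.DataFrame([m.__dict__ for m in matches]).to_csv(path, index=False)


def matches_from_csv(path: str | Path) -> list[ToponymMatch]:
    df = pd.read_csv(path)
    return [ToponymMatch(str(r.article_id), float(r.lon), float(r.lat),
                         float(r.raw_weight))
            for r in df.itertuples()]


def smooth_effort(raw: Layer, covariates: PredictorSet, grid: GridSpec,
                  covariate_names: Sequence[str] | None = None,
                  year: int = 2000, learning_rate: float = 0.05,
                  max_trees: int = 500, cv_folds: int = 5,
                  seed: int = 0) -> EffortLayer:
    """Smooth/impute the raw effort surface with a Poisson boosted-tree model.

    The booster regresses raw per-cell effort on the covariates over land
    cells (Poisson deviance loss, log link), with the tree count chosen by
    internal cross-validated deviance.  Predictions — strictly positive by
    the log link, plus a small relative floor — replace the raw surface
    everywhere on land, imputing raw zeros.

    If the covariates are degenerate (all constant on land) the model falls
    back to the global mean rate with a warning.
    """
    names = list(covariate_names) if covariate_names is not None \
        else covariates.names()
    land = grid.land_mask & np.isfinite(raw.values)
    for n in names:
        land &= np.isfinite(covariates.resolve(n, year).values)
    rows, cols = np.nonzero(land)
    X = np.column_stack([covariates.resolve(n, year).values[rows, cols]
                         for n in names])
    y = raw.values[rows, cols]

    degenerate = all(np.nanstd(X[:, j]) == 0 for j in range(X.shape[1]))
    if degenerate or y.sum() == 0:
        logger.warning("smooth_effort: degenerate covariates or empty raw "
                       "surface; falling back to the global mean rate")
        mean_rate = max(float(y.mean()), EFFORT_FLOOR_REL)
        pred = np.full(len(rows), mean_rate)
    else:
        params = dict(objective="poisson", learning_rate=learning_rate,
                      num_leaves=8, min_data_in_leaf=10, verbosity=-1,
                      num_threads=1, deterministic=True, force_row_wise=True,
                      seed=seed, bagging_seed=seed, feature_fraction_seed=seed)
        cv = lgb.cv(params, lgb.Dataset(X, label=y),
                    num_boost_round=max_trees, nfold=cv_folds,
                    stratified=False, seed=seed,
                    callbacks=[lgb.early_stopping(25, verbose=False)])
        key = [k for k in cv if k.endswith("-mean")][0]
        best = int(np.argmin(cv[key])) + 1
        bst = lgb.train(params, lgb.Dataset(X, label=y), num_boost_round=best)
        pred = bst.predict(X)

    out = np.full(grid.shape, np.nan)
    out[rows, cols] = pred
    floor = np.nanmax(out) * EFFORT_FLOOR_REL
    out[rows, cols] = np.maximum(out[rows, cols], floor)
    smoothed = Layer(name="reporting_effort", values=out, temporal="static")
    return EffortLayer(raw=raw, smoothed=smoothed, covariates_used=names)
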