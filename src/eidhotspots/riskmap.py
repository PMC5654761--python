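"""Ensemble aggregation and the reporting-bias algebra for risk maps.

The bootstrap ensemble refits the presence/background BRT on replicate
resamples of the events (spatial-uncertainty resampling).  The per-cell mean
of the replicate predictions is the *relative response*: the probability that
a cell sampled under the effort-weighted regime contains an event, i.e. risk
relative to reporting effort.  The bias algebra then maps this onto
interpretable indices::

    observed index  = response × reporting effort
    reporting bias  ∝ reporting effort / population
    corrected index = observed × population / effort  (= response × population)

The corrected index assumes "optimal" surveillance would be proportional to
population; it is masked wherever effort sits at its numerical floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .brt import BoostConfig, BRTFit, fit_step, partial_dependence, predict
from .events import EIDEvent
from .grid import GridSpec, Layer, PredictorSet, sd_scale
from .reporting_effort import EffortLayer
from .sampling import PairSampler, ResamplingConfig, assemble_design, \
    bootstrap_replicate

logger = logging.getLogger(__name__)


@dataclass
class EnsembleResult:
    """Aggregates over replicate BRT fits."""

    mean_response: Layer
    influence: pd.DataFrame            # replicate × predictor, rows sum to 100
    pd_bands: dict[str, pd.DataFrame]  # per predictor: probe, median, q05, q95
    n_replicates: int
    n_null_replicates: int
    n_trees: np.ndarray
    deviance_explained: np.ndarray

    def influence_summary(self) -> pd.DataFrame:
        """Box-plot statistics per predictor (whiskers at 1.5×IQR rule)."""
        rows = []
        for name in self.influence.columns:
            v = self.influence[name].to_numpy()
            q25, med, q75 = np.percentile(v, [25, 50, 75])
            iqr = q75 - q25
            # furthest datum within 1.5×IQR; whiskers never cross the box
            lo = min(v[v >= q25 - 1.5 * iqr].min(), q25)
            hi = max(v[v <= q75 + 1.5 * iqr].max(), q75)
            rows.append({"predictor": name, "min": v.min(), "whisker_lo": lo,
                         "q25": q25, "median": med, "q75": q75,
                         "whisker_hi": hi, "max": v.max()})
        return (pd.DataFrame(rows).set_index("predictor")
                .sort_values("median", ascending=False))


@dataclass
class RiskMaps:
    response: Layer
    observed_index: Layer
    corrected_index: Layer


def run_ensemble(events: Sequence[EIDEvent], predictors: PredictorSet,
                 effort: EffortLayer, grid: GridSpec,
                 resampling: ResamplingConfig, boost: BoostConfig,
                 rng: np.random.Generator, reference_year: int = 2000,
                 pd_predictors: Sequence[str] | None = None,
                 pd_points: int = 15) -> EnsembleResult:
    """Fit the bootstrap replicate ensemble and aggregate its outputs.

    Each replicate resamples the events with replacement, draws one
    presence/background pair per draw, fits the stagewise BRT and predicts
    every eligible land cell at the reference decade.  Aggregates are the
    per-cell mean prediction, the distribution of relative influence, and
    partial-dependence bands (median and empirical 90% CI) on a common probe
    grid spanning the 10th–90th percentile of pooled sampled values.
    Replicates whose fit degenerates to the null model are excluded from the
    aggregates and counted.
    """
    if resampling.n_replicates < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    sampler = PairSampler(grid, predictors, effort.smoothed, resampling.mode)
    names = predictors.names()

    eligible = sampler.eligible
    rows, cols = np.nonzero(eligible)
    cell_X = pd.DataFrame(
        np.column_stack([predictors.resolve(n, reference_year).values[rows, cols]
                         for n in names]), columns=names)

    fits: list[BRTFit] = []
    designs: list[pd.DataFrame] = []
    pred_sum = np.zeros(len(rows))
    n_null = 0
    for rep in range(resampling.n_replicates):
        pairs = bootstrap_replicate(events, sampler, rng)
        X, y = assemble_design(pairs, predictors, names)
        fit = fit_step(X, y, boost, rng)
        if fit.is_null:
            n_null += 1
            logger.warning("replicate %d degenerated to the null model", rep)
            continue
        fits.append(fit)
        designs.append(X)
        pred_sum += predict(fit, cell_X)
        if (rep + 1) % 25 == 0:
            logger.info("ensemble: %d/%d replicates fitted",
                        rep + 1, resampling.n_replicates)
    if not fits:
        raise RuntimeError("every replicate degenerated to the null model")

    mean_vals = np.full(grid.shape, np.nan)
    mean_vals[rows, cols] = pred_sum / len(fits)
    mean_response = Layer(name="response", values=mean_vals, temporal="static")

    influence = pd.DataFrame([f.relative_influence for f in fits],
                             columns=names).reset_index(drop=True)

    pd_names = list(pd_predictors) if pd_predictors is not None else names
    pd_bands: dict[str, pd.DataFrame] = {}
    for name in pd_names:
        pooled = np.concatenate([X[name].to_numpy() for X in designs])
        q0, q1 = np.quantile(pooled, [0.10, 0.90])
        probes = np.linspace(q0, q1, pd_points)
        curves = np.array([partial_dependence(f, X, name, probes)[1]
                           for f, X in zip(fits, designs)])
        pd_bands[name] = pd.DataFrame({
            "probe": probes,
            "median": np.median(curves, axis=0),
            "q05": np.quantile(curves, 0.05, axis=0),
            "q95": np.quantile(curves, 0.95, axis=0),
        })

    return EnsembleResult(
        mean_response=mean_response, influence=influence, pd_bands=pd_bands,
        n_replicates=resampling.n_replicates, n_null_replicates=n_null,
        n_trees=np.array([f.n_trees_selected for f in fits]),
        deviance_explained=np.array([f.deviance_explained for f in fits]))


# ---------------------------------------------------------------------------
# Bias algebra
# ---------------------------------------------------------------------------

def observed_index(response: Layer, effort: Layer) -> Layer:
    """Observed event-risk index: response × reporting effort, elementwise."""
    if response.shape != effort.shape:
        raise ValueError("response and effort are on different grids")
    return Layer(name="observed_risk_index",
                 values=response.values * effort.values, temporal="static")


def reporting_bias(effort: Layer, population: Layer) -> Layer:
    """Reporting bias ∝ effort / population (unit proportionality constant).

    Cells with non-positive population are masked, not errors.
    """
    if effort.shape != population.shape:
        raise ValueError("layers are on different grids")
    pop = population.values
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(pop > 0, effort.values / pop, np.nan)
    return Layer(name="reporting_bias", values=vals, temporal="static")


def corrected_index(observed: Layer, population: Layer, effort: Layer,
                    effort_floor: float = 0.0) -> Layer:
    """Bias-corrected ("true") risk index: observed × population / effort.

    Factoring measured effort out and population-proportional "optimal"
    effort in; algebraically identical to response × population wherever
    defined.  Cells with effort at or below the floor are masked.
    """
    if not observed.shape == population.shape == effort.shape:
        raise ValueError("layers are on different grids")
    eff = effort.values
    ok = eff > max(effort_floor, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(ok, observed.values * population.values / eff, np.nan)
    return Layer(name="corrected_risk_index", values=vals, temporal="static")


def build_risk_maps(response: Layer, effort: EffortLayer,
                    population: Layer) -> RiskMaps:
    obs = observed_index(response, effort.smoothed)
    corr = corrected_index(obs, population, effort.smoothed,
                           effort_floor=effort.floor)
    return RiskMaps(response=response, observed_index=obs,
                    corrected_index=corr)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(layer: Layer, out_png: str | Path, k: float = 2.5,
           out_scaled_tiff: str | Path | None = None,
           title: str | None = None) -> Layer:
    """Render a layer as a heat map after standard-deviation scaling.

    The colour palette spans ±k standard deviations around the mean; the
    scaled layer is returned (and optionally written as TIFF).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scaled_vals = sd_scale(layer.values, k=k)
    scaled = Layer(name=f"{layer.name}_sdscaled", values=scaled_vals,
                   temporal=layer.temporal)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    im = ax.imshow(scaled_vals, origin="lower", cmap="inferno",
                   vmin=-k, vmax=k, extent=[-180, 180, -90, 90],
                   aspect="auto")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title or layer.name)
    fig.colorbar(im, ax=ax, label=f"s.d. from mean (clipped at ±{k})")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    if out_scaled_tiff is not None:
        from .grid import layer_to_tiff
        layer_to_tiff(scaled, out_scaled_tiff)
    return scaled
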