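"""Resampling regimes: paired presence/background draws, bootstrap, CV folds.

Each time an event is sampled one presence cell is drawn from its footprint
and one background ("absence") cell from the whole landscape, fixing the
prevalence of every assembled design at exactly 0.5.  In *weighted* mode both
draws are weighted by reporting effort — the effort surface acts as a prior
over where an uncertain event was detected, and background cells mimic the
literature's gaze.  In *unweighted* mode cells are weighted by land area
instead, removing the equirectangular grid's area bias but ignoring effort.

The bootstrap regime redraws events with replacement (spatial + sampling
uncertainty for the replicate ensemble); the cross-validation regime draws
one pair per event and partitions pairs into k near-equal folds, keeping each
pair's presence and absence in the same fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .events import EIDEvent
from .grid import GridSpec, Layer, PredictorSet, match_decade

logger = logging.getLogger(__name__)

Mode = Literal["weighted", "unweighted"]


@dataclass(frozen=True)
class SamplePair:
    """One presence/background draw for one sampled event."""

    event_id: str
    presence_cell: tuple[int, int]
    absence_cell: tuple[int, int]
    year: int

    @property
    def decade(self) -> int:
        return match_decade(self.year)


@dataclass
class ResamplingConfig:
    n_replicates: int = 1000
    mode: Mode = "weighted"
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mode not in ("weighted", "unweighted"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _weight_surface(grid: GridSpec, effort: Layer, mode: Mode) -> np.ndarray:
    if mode == "weighted":
        return np.nan_to_num(effort.values, nan=0.0)
    return np.where(grid.land_mask, grid.cell_area, 0.0)


def draw_presence(event: EIDEvent, weights: np.ndarray,
                  rng: np.random.Generator) -> tuple[int, int]:
    """Draw one footprint cell with probability proportional to the weights.

    An all-zero-weight footprint falls back to a uniform draw (logged once
    per call site at debug level).
    """
    cells = event.footprint
    if len(cells) == 1:
        return cells[0]
    w = np.array([weights[r, c] for r, c in cells], dtype=float)
    total = w.sum()
    if total <= 0:
        logger.debug("draw_presence: zero-weight footprint for event %s; "
                     "uniform fallback", event.id)
        w = np.ones(len(cells))
        total = float(len(cells))
    idx = rng.choice(len(cells), p=w / total)
    return cells[idx]


def draw_absence(grid: GridSpec, weights: np.ndarray, eligible: np.ndarray,
                 rng: np.random.Generator) -> tuple[int, int]:
    """Draw one background cell among eligible land cells, p ∝ weight."""
    w = np.where(eligible, weights, 0.0).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("no eligible background cell with positive weight")
    flat = rng.choice(w.size, p=w / total)
    return divmod(int(flat), grid.n_lon)


class PairSampler:
    """Caches the weight surface and eligibility mask for repeated draws."""

    def __init__(self, grid: GridSpec, predictors: PredictorSet,
                 effort: Layer, mode: Mode = "weighted"):
        self.grid = grid
        self.mode: Mode = mode
        self.weights = _weight_surface(grid, effort, mode)
        self.eligible = predictors.complete_mask(grid)
        if not (self.eligible & (self.weights > 0)).any():
            raise ValueError("no eligible cell with positive sampling weight")

    def draw_pair(self, event: EIDEvent, rng: np.random.Generator) -> SamplePair:
        pres = draw_presence(event, self.weights, rng)
        abs_ = draw_absence(self.grid, self.weights, self.eligible, rng)
        return SamplePair(event_id=event.id, presence_cell=pres,
                          absence_cell=abs_, year=event.year)


def bootstrap_replicate(events: Sequence[EIDEvent], sampler: PairSampler,
                        rng: np.random.Generator) -> list[SamplePair]:
    """One bootstrap replicate: |events| events redrawn with replacement,
    one presence/background pair per draw (prevalence exactly 0.5)."""
    if not events:
        raise ValueError("no events to resample")
    idx = rng.integers(0, len(events), size=len(events))
    return [sampler.draw_pair(events[i], rng) for i in idx]


def fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random assignment of n items to k near-equal folds (sizes differ ≤ 1).

    The first ``n % k`` folds get one extra item (147 items at k=10 gives 7
    folds of 15 and 3 of 14).
    """
    if k > n:
        raise ValueError(f"k={k} folds exceed {n} items")
    order = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        assign[order[start:start + size]] = j
        start += size
    return assign


def cv_partition(events: Sequence[EIDEvent], sampler: PairSampler,
                 rng: np.random.Generator, k: int = 10,
                 rounds: int = 100) -> list[list[list[SamplePair]]]:
    """Cross-validation rounds: per round, one pair per event (no bootstrap)
    randomly assigned to k near-equal folds.

    A pair's presence and background stay in the same fold, so no pair
    straddles the train/test split.
    """
    n = len(events)
    out = []
    for _ in range(rounds):
        pairs = [sampler.draw_pair(ev, rng) for ev in events]
        assign = fold_assignment(n, k, rng)
        out.append([[pairs[i] for i in np.nonzero(assign == j)[0]]
                    for j in range(k)])
    return out


def assemble_design(pairs: Sequence[SamplePair], predictors: PredictorSet,
                    names: Sequence[str] | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Resolve predictor values for every pair member into a design matrix.

    Two rows per pair (presence first), one column per predictor name,
    values resolved at (cell, event year) through the decade-matching rules.
    Returns the feature frame and the 1/0 label vector.
    """
    names = list(names) if names is not None else predictors.names()
    rows, labels = [], []
    for p in pairs:
        for cell, lab in ((p.presence_cell, 1), (p.absence_cell, 0)):
            rows.append(predictors.design_row(cell[0], cell[1], p.year, names))
            labels.append(lab)
    X = pd.DataFrame(np.array(rows).reshape(-1, len(names)), columns=names)
    y = np.array(labels, dtype=int)
    if len(y) and not np.isfinite(X.to_numpy()).all():
        raise RuntimeError(
            "missing predictor value at a sampled cell; eligibility mask "
            "should have excluded it")
    return X, y


def pairs_to_csv(replicates: Sequence[Sequence[SamplePair]], grid: GridSpec,
                 path: str | Path) -> None:
    """Audit export: one row per pair member (replicate, event, role, lon, lat)."""
    recs = []
    for rep, pairs in enumerate(replicates):
        for p in pairs:
            for cell, role in ((p.presence_cell, "presence"),
                               (p.absence_cell, "absence")):
                recs.append({"replicate": rep, "event_id": p.event_id,
                             "role": role,
                             "lon": grid.lon_centers[cell[1]],
                             "lat": grid.lat_centers[cell[0]],
                             "decade": p.decade})
    pd.DataFrame(recs).to_csv(path, index=False)
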