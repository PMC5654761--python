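"""Model validation: AUC, True Skill Statistic, deviance explained, CV runs.

AUC is the rank-based probability that a randomly chosen presence scores
above a randomly chosen background cell (ties credit 1/2).  TSS is the
maximum over candidate thresholds of sensitivity + specificity − 1 — a
prevalence-insensitive skill score in [−1, 1]; candidate thresholds are the
midpoints between consecutive distinct scores (an exhaustive sweep).

The cross-validation protocol draws one presence/background pair per event
each round, partitions the pairs into k folds (a pair never straddles the
split), trains on k−1 folds and scores the held-out pairs; per-round scores
pool all folds' held-out predictions, and summaries report the median and
the 0.05/0.95 quantiles over rounds.  The background weighting of the
validation draw (reporting effort vs land area) defines the null the model
is scored against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .brt import BoostConfig, fit_step, predict
from .events import EIDEvent
from .grid import GridSpec, Layer, PredictorSet
from .sampling import Mode, PairSampler, assemble_design

logger = logging.getLogger(__name__)


@dataclass
class ScoreSummary:
    """Per-round values of one metric plus quantile summaries."""

    metric: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def q05(self) -> float:
        return float(np.quantile(self.values, 0.05))

    @property
    def q95(self) -> float:
        return float(np.quantile(self.values, 0.95))

    def as_dict(self) -> dict:
        return {"metric": self.metric, "median": self.median,
                "q05": self.q05, "q95": self.q95}


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC (Mann–Whitney form); ties credit 0.5."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    _check_two_classes(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss(labels: Sequence[int], scores: Sequence[float]) -> float:
    """True Skill Statistic: max over thresholds of sens + spec − 1.

    Thresholds are the midpoints of consecutive distinct sorted scores,
    plus sentinels classifying everything as one class (TSS 0).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    _check_two_classes(y)
    uniq = np.unique(s)
    if len(uniq) == 1:
        return 0.0
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    n1 = y.sum()
    n0 = len(y) - n1
    best = 0.0  # all-one-class classification scores 0
    for t in thresholds:
        pos = s > t
        sens = (pos & (y == 1)).sum() / n1
        spec = (~pos & (y == 0)).sum() / n0
        best = max(best, sens + spec - 1.0)
    return float(best)


def deviance_explained(fit, X: pd.DataFrame, y: np.ndarray) -> float:
    """Percent deviance explained: 100·(1 − residual/null mean deviance).

    The null model predicts the observed prevalence for every row.
    """
    from .brt import bernoulli_deviance

    y = np.asarray(y, dtype=int)
    null = bernoulli_deviance(y, np.full(len(y), y.mean()))
    if null == 0:
        raise ValueError("null deviance is zero (single-class labels)")
    resid = bernoulli_deviance(y, predict(fit, X))
    return 100.0 * (1.0 - resid / null)


def cross_validate(events: Sequence[EIDEvent], predictors: PredictorSet,
                   effort: Layer, grid: GridSpec, boost: BoostConfig,
                   rng: np.random.Generator, mode: Mode = "weighted",
                   null_mode: Mode | None = None, rounds: int = 100,
                   k: int = 10,
                   permute_labels: bool = False) -> dict[str, ScoreSummary]:
    """Repeated k-fold cross-validation of the full sampling + BRT pipeline.

    ``mode`` sets the background weighting used to *train* the model;
    ``null_mode`` (default: same as ``mode``) sets the weighting of the
    validation background draw, i.e. the null the model is scored against.
    ``permute_labels`` shuffles labels within each training/evaluation design
    (a negative control: scores should collapse to chance).

    Returns summaries for AUC and TSS pooled per round.
    """
    from .sampling import SamplePair, fold_assignment

    null_mode = null_mode or mode
    train_sampler = PairSampler(grid, predictors, effort, mode)
    valid_sampler = (train_sampler if null_mode == mode
                     else PairSampler(grid, predictors, effort, null_mode))
    n = len(events)
    auc_scores, tss_scores = [], []
    for rnd in range(rounds):
        train_pairs = [train_sampler.draw_pair(ev, rng) for ev in events]
        if valid_sampler is train_sampler:
            valid_pairs = train_pairs
        else:
            # same presence draw, background redrawn under the null weighting
            valid_pairs = [
                SamplePair(event_id=p.event_id, presence_cell=p.presence_cell,
                           absence_cell=valid_sampler.draw_pair(ev, rng).absence_cell,
                           year=p.year)
                for p, ev in zip(train_pairs, events)]
        assign = fold_assignment(n, k, rng)
        held_labels: list[int] = []
        held_scores: list[float] = []
        for j in range(k):
            tr_idx = np.nonzero(assign != j)[0]
            te_idx = np.nonzero(assign == j)[0]
            Xtr, ytr = assemble_design([train_pairs[i] for i in tr_idx],
                                       predictors)
            Xte, yte = assemble_design([valid_pairs[i] for i in te_idx],
                                       predictors)
            if permute_labels:
                ytr = rng.permutation(ytr)
                yte = rng.permutation(yte)
            fit = fit_step(Xtr, ytr, boost, rng)
            held_scores.extend(predict(fit, Xte))
            held_labels.extend(yte)
        y = np.array(held_labels)
        s = np.array(held_scores)
        auc_scores.append(auc(y, s))
        tss_scores.append(tss(y, s))
        logger.debug("cross_validate round %d: AUC=%.3f TSS=%.3f",
                     rnd, auc_scores[-1], tss_scores[-1])
    return {"auc": ScoreSummary("auc", np.array(auc_scores)),
            "tss": ScoreSummary("tss", np.array(tss_scores))}


def scores_to_csv(summaries: dict[str, ScoreSummary], path: str | Path) -> None:
    recs = [{"round": i, "metric": s.metric, "value": v}
            for s in summaries.values() for i, v in enumerate(s.values)]
    pd.DataFrame(recs).to_csv(path, index=False)


def summaries_to_json(summaries: dict[str, ScoreSummary],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: s.as_dict() for k, s in summaries.items()}, fh, indent=2)
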