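# Methods

This note documents the models and procedures implemented in `eidhotspots`,
the assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Problem and model

The package models the global spatial distribution of zoonotic
emerging-infectious-disease (EID) events — documented first emergences of
wildlife-origin pathogens in people — as a presence/background problem on a
coarse equirectangular grid. Observed event locations confound two surfaces:
where emergence risk is genuinely high, and where surveillance and
publication ("reporting effort") are intense enough for an emergence to be
noticed. The pipeline therefore (i) fits boosted-regression-tree (BRT)
models of event occurrence with background samples weighted by a gridded
reporting-effort proxy, so the fitted response is risk *relative to* effort,
and (ii) recovers interpretable indices algebraically:

    observed risk index  = response × reporting effort
    reporting bias       ∝ reporting effort / human population
    corrected risk index = observed × population / effort  (≡ response × population)

The correction assumes "optimal" surveillance of human disease would be
proportional to human population; departures from that are treated as bias
and factored out.

## Grid model

Layers live on a global lon/lat lattice (default 1°, i.e. 360 × 180;
synthetic worlds default to 40 × 20) stored as `(n_lat, n_lon)` arrays,
row 0 at 90°S, NaN for missing. Per-cell areas use the exact spherical band
formula `R² Δλ (sin φ_top − sin φ_bottom)` with R = 6371 km; they depend only
on the latitude row, and the land mask times band area is the package's
notion of land area (no treatment of partial coastal cells — the mask is
binary).

Time-varying covariates carry one layer per decade (1970, 1980, 1990, 2000)
plus inter-decadal change layers (exact elementwise differences, tagged e.g.
"1990-2000"). A sample in calendar year *y* resolves covariates at the
nearest decade with ties (years ending in 5) rounded up; years 2001–2008
clamp to the 2000 layer, since no later decadal layer exists. Change layers
resolve to the interval whose right endpoint is the matched decade, floored
at the first available interval (1970–1980) so that years matching 1970
still resolve; e.g. 1972 and 1975 both use 1970–1980, 2005 uses 1990–2000.

Finer rasters are aggregated to the study grid by integer block sum (missing
cells counted as zero, conserving the global total) or block mean (missing
cells excluded). Map rendering uses standard-deviation scaling: z-scores
clipped at ±2.5, with a zero-variance surface degenerating to zeros.

## Events

An event is a year plus a spatial-uncertainty footprint: the set of land
cells intersected (with positive area) by its geocoded polygon, or by a 5 km
circular buffer for point-precise records. Footprints are rasterised once
and cached; resampling never touches geometry. Study filters keep
wildlife-zoonosis events from 1970 onward (the decades with covariate
coverage). The headline counts of the curated database (335 events 1940–2004
of which 145 wildlife zoonoses; 224 wildlife zoonoses through 2008 of which
147 post-1970) are kept as constants so the filtering arithmetic is
reproducible without the database.

## Reporting effort

Effort starts from a table of per-article place-name matches with raw
weights. Weights are normalised within each article (each article
contributes total mass 1, making the surface invariant to any one article's
weighting scale), scattered to the grid, and summed. Because the raw surface
is sparse and noisy, a Poisson boosted-tree model (log link, tree count by
internal cross-validated deviance, LightGBM engine) regresses it on
covariates plausibly related to publication intensity; its strictly positive
predictions, floored at 10⁻⁹ of the surface maximum, replace the raw surface
on all land cells. The floor guarantees weighted sampling and the
bias-correction division are always defined; cells at the floor are masked
in the corrected index rather than extrapolated. The upstream text-mining
that produces the match table is out of scope — the table is an input
contract.

## Resampling

Every time an event is sampled, one presence cell is drawn from its
footprint and one background cell from all eligible land cells (complete
predictors, positive weight), so every assembled design has prevalence
exactly 0.5. In *weighted* mode both draws use reporting effort as the
weight — for uncertain footprints the effort surface acts as a prior on
where the event was actually detected; in *unweighted* mode the weight is
spherical land area (removing the poleward cell-shrinkage bias of the
equirectangular grid). An all-zero-effort footprint falls back to a uniform
draw. Background draws are true background (they may coincide with other
events' cells), not verified absences.

The bootstrap regime draws |events| events with replacement per replicate
(default 1000 replicates; desk-scale runs use 100) and one pair per draw.
The cross-validation regime draws one pair per event, assigns pairs to k
near-equal folds (147 events at k = 10 gives 7 folds of 15 and 3 of 14), and
keeps each pair's presence and background in the same fold so no pair
straddles the train/test split. When a model trained under one weighting is
scored against a different "null" weighting, the presence draw is shared and
only the validation background is redrawn under the null weighting.

## Boosted regression trees

Fitting follows the stagewise protocol standard in species distribution
modelling: fit `step_size` trees, keep adding `step_size` trees while the
k-fold cross-validated Bernoulli deviance (pooled over held-out samples,
folds stratified by label) keeps improving, and select the tree count at the
CV minimum. Defaults mirror settings tuned for consistent gradient descent
on ~300-row designs: interaction depth 3, learning rate 0.0035, step 35
trees, 10 internal folds, bag fraction 0.75. Fitting stops once the minimum
has stagnated for `patience` steps (default 1; desk-scale runs use 3 — at
higher learning rates the pooled CV trajectory is noisier and patience 1
stops spuriously early). If CV deviance never beats the intercept-only
deviance the fit is flagged a null model (prediction = prevalence) and
excluded, with a count, from ensemble aggregates.

The tree engine is LightGBM behind a fixed contract (incremental fitting,
prediction, per-split gain access): `num_leaves = tree_complexity + 1` with
unlimited depth reproduces best-first trees of `tree_complexity` splits.
Owned by this package, and tested against independent oracles, are: the
step/selection logic, Bernoulli deviance (probabilities clamped at 10⁻⁹),
relative influence (per-predictor share of total split gain, normalised to
sum to 100; never-split predictors score exactly 0), and partial dependence
(mean prediction over the training design with one column replaced by each
probe value, probes spanning the 10th–90th percentile of sampled values).

Numerical notes: histogram binning means predictions are invariant to
monotone predictor transforms only while distinct values per predictor stay
within the bin budget (255); designs here are far smaller. All randomness —
fold assignment, bagging, engine seeds — derives from the caller's generator,
so a fit is bit-reproducible from (design, config, seed).

## Validation

AUC is computed in rank form (ties credit ½) and TSS as the maximum over
candidate thresholds — midpoints of consecutive distinct scores, an
exhaustive sweep — of sensitivity + specificity − 1; a degenerate
all-equal-score vector scores TSS 0. Both are checked against brute-force
pairwise/threshold oracles. Deviance explained is 100·(1 − residual/null)
mean Bernoulli deviance with the null predicting observed prevalence.
Cross-validation scores are pooled per round (one AUC/TSS per round over all
held-out pairs) rather than averaged per fold; summaries report the median
and 0.05/0.95 quantiles over rounds.

## Ensemble aggregation and maps

Each bootstrap replicate predicts every eligible land cell at a reference
decade (2000 layers plus the 1990–2000 change layers — the most recent
covariate state); the per-cell mean over non-null replicates is the response
map. Influence distributions are summarised as box-plot statistics (whiskers
at the furthest datum within 1.5×IQR, clamped to the quartiles).
Partial-dependence bands (median and empirical 90% interval across
replicates) are computed on a common probe grid from the pooled sampled
values so replicate curves are quantile-compatible.

## Synthetic worlds

The generator emulates the *structure* of the real inputs, not their
geography: Gaussian-smoothed random fields (smoothing σ = 1.2 cells, wrapped
in longitude) for 19 covariate analogues — population, cropland and pasture
with four drifting decadal layers (drift scale 0.35 per decade) and derived
change series; urban land correlated with population (generative ρ = 0.7);
land-cover percentages via logistic transforms; population as a log-normal
field (log-sd 0.8 — coarse cells damp the extremes of fine-scale population);
a land mask from a thresholded smooth field (60% land). True risk is
`logistic(β₀ + Σ βⱼ·zⱼ)` over the active drivers at the 2000 decade
(β₀ = −0.75), with standardisation constants stored so the surface is
exactly recomputable from metadata. Reporting effort is log-linear in
standardised urban land (coef 1.0) and log-population (0.5) plus smooth
noise (0.3); 1500 synthetic articles emit toponym matches that flow through
the real aggregation and smoothing code. Events (default 147, matching the
study's post-1970 record count) are drawn proportional to
true risk × effort^bias_strength (default 1), with years uniform on
1970–2008 and half the footprints precise single cells, the rest up-to-4×4
cell blocks.

Default drivers are three *static* analogues of the leading correlates the
method is meant to detect — evergreen broadleaf trees, mammal richness and
climate stratification — at equal β = 1.5, which yields training deviance
explained of roughly 25–35% per world and cross-validated AUC/TSS in the
0.6–0.8 / 0.2–0.45 range, the magnitudes typical of this kind of analysis. A
change-layer driver is configurable but is structurally diluted: true risk
is defined at the 2000 decade, while samples from years matching earlier
decades resolve an *independent* change interval, so only about a third of
rows carry the matched signal and recovery of such a driver is markedly
weaker. This is a faithful property of decade-matched designs, not a defect
of the estimator.

What passing recovery tests do and do not show: the worlds have smooth,
stationary, Gaussian-derived fields, no coastline geometry, no country-level
reporting idiosyncrasies, and a bias mechanism (effort multiplying detection
exactly) that matches the correction's assumption. Success here demonstrates
internal consistency of the pipeline — that the weighted ensemble recovers
known drivers and that the algebraic correction moves the map toward the
generative truth — not that the correction is adequate for any real
surveillance process.

## Problem sizes for desk-scale runs

Ensemble and cross-validation checks run at 100 replicates per world (50 for
mode contrasts), 10 worlds for recovery, and 10 CV rounds, with boosting at
learning rate 0.01, 5 internal folds, up to 1000 trees and patience 3. These
sizes give stable medians on the 40×20 default world while keeping a full
recovery experiment under fifteen minutes on one CPU; the full-scale
defaults (1000 replicates, 100 rounds, learning rate 0.0035 with 10 internal
folds) remain the package defaults.

## Known limitations

* No reprojection or sub-degree analysis; the grid is the analysis frame.
* The corrected index is proportional (unit proportionality constants), so
  only its spatial pattern is meaningful, not its scale.
* TSS uses an optimised threshold; with few held-out pairs it is upward
  biased under the null (medians ~0.03–0.1 rather than exactly 0).
* Footprint polygons are used as given; continent-scale footprints are not
  clipped to plausible sub-regions.
* Whether presence/background pairs should share CV folds is ambiguous in
  this design; keeping them together (the default) prevents leakage of a
  pair's shared event year across the split.
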