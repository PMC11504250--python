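# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data design and the known limitations of `nicheshift`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Presence-background maximum-entropy model

Presence-only occurrence data cannot support a logistic regression against
true absences, so suitability is estimated as the maximum-entropy (Gibbs)
distribution over a finite background sample of the landscape, subject to
soft constraints that tie model feature expectations to their presence-sample
means. Equivalently (`maxent.py`), the coefficients minimize

    J(lambda) = -mean_presence[lambda . f] + ln Z_background
                + sum_j beta_j |lambda_j|,

the L1-penalized negative log-likelihood of q_lambda(x) ∝ exp(lambda · f(x))
evaluated at presences and normalized over the background. Presence rows are
appended to the background for normalization, the standard
presence-background convention: Z and the entropy H are computed over
background ∪ presences.

**Features** (`features.py`). Raw predictors are min-max scaled to [0, 1]
using the pooled presence + background range, then expanded into up to five
classes: linear, quadratic, pairwise products, threshold step indicators, and
forward/reverse hinges. Threshold and hinge knots are `n_knots` equally
spaced interior points of (0, 1); hinges are normalized to reach 1 at the
interval end so all features live on comparable scales. Defaults:
`n_knots = 15` at desk scale (production MaxEnt uses up to 50; configurable).
A constant predictor is excluded from expansion with a warning — it carries
no information and breaks min-max scaling. Because features are functions of
the scaled variable, multiplying a raw predictor by any constant leaves
predictions unchanged (verified by test).

**Penalties.** beta_j = RM × beta_class × s_j/√m, with s_j the feature's
presence-sample standard deviation, m the presence count, and per-class bases
linear/quadratic/product 1.0, threshold 2.0, hinge 0.5 — a deliberately
coarse rendition of MaxEnt's empirically tabulated defaults, configurable per
call. RM is the regularization multiplier tuned by AICc.

**Optimizer.** Deterministic cyclic coordinate descent. Each coordinate takes
a damped prox-Newton step: the 1-D quadratic model of the smooth part
(gradient E_q[f_j] − mean_presence[f_j], curvature Var_q(f_j)) is minimized
under the L1 term by soft-thresholding, and the step is halved until the true
objective does not increase. The normalized background weights are maintained
incrementally (one vector exponential per accepted step), and full sweeps
alternate with cheap sweeps over the nonzero set (glmnet-style active-set
cycling). Convergence is declared when a full sweep moves no coefficient by
more than 1e-7, when the objective decreases by less than 1e-9·(1+|J|)
across an outer cycle, or — if the sweep budget (default 5000) runs out —
when the final iterate satisfies the KKT conditions of the L1 problem within
1e-4. The plateau and KKT clauses exist because large hinge expansions
contain near-collinear features that trade coefficient mass indefinitely at
no objective gain; the iterate is then optimal for every practical purpose
and is accepted rather than reported as failed. Genuinely separable data
(a feature perfectly discriminating presences) has no finite optimum; the
coefficient runs to a cap of 100 (harmless on [0, 1]-scaled features) and
non-convergence is logged with the residual KKT violation.

Correctness is guarded by two independent oracles in the test suite: exact
moment matching at beta = 0 (the KKT stationarity condition), and agreement
of the optimal objective with scipy's L-BFGS-B on the split
positive/negative-part reformulation, on small random instances, to 1e-6.

**Outputs.** "Raw" output is the normalized Gibbs density q. The logistic
output is q·e^H/(1 + q·e^H) — the classical calibration in which a cell with
raw output e^(−H) (a "typical" presence environment) scores exactly 0.5.
When projecting onto future layers, predictor values are clamped to the
training range by default, the usual guard against feature extrapolation.
Cloglog output, sampling-bias correction and categorical features are out of
scope.

## Model selection

`selection.py` fits every (RM, feature-combo) candidate on the full presence
set and ranks by AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), with n the presence
count, k the number of nonzero coefficients, and lnL the sum over presences
of the log of the raw output (normalized over background + presence cells,
the Warren–Seifert convention). Candidates with n − k − 1 ≤ 0 are flagged
invalid and excluded from ranking. Ties break toward fewer parameters, then
lower RM, then combo enumeration order, making selection fully deterministic.

The canonical RM grid is (0.5, 1, …, 4). Feature-combo enumeration offers
three schemes: all 31 non-empty subsets of the five classes; the default
"30", which drops the quadratic-only singleton (never fit without its linear
term in practice); and "29", which additionally drops product-only. The
desk-scale pipeline default is a 4-combo subset (l, lq, lqp, lqh) crossed
with 4 RM values — 16 candidates — purely to keep the demo fast; the full
8 × 30 grid is available by configuration.

The final map is the cellwise mean of replicate models trained on random
75/25 presence splits (subsampling without replacement, ⌊0.75 n⌋ training
rows, a fresh draw per replicate from one seeded stream). Test AUC per
replicate uses the background sample as the negative class.

## Evaluation and variable importance

* **AUC** (`evaluation.py`) is computed in the Mann–Whitney rank form
  (ties count 1/2), which equals trapezoidal integration of the empirical
  ROC; the suite verifies both the closed-form examples and the equivalence
  to an independent trapezoidal implementation at 1e-9. Because the negative
  class is background, not absence, values are rankings against the
  landscape. Qualitative bands: <0.6 Fails, [0.6, 0.7) Poor, [0.7, 0.8)
  Moderate, [0.8, 0.9) Good, ≥0.9 Excellent — half-open on the left
  throughout.
* **Jackknife gains**: training gain (mean log q at presences + ln
  n_background) of the model with only, and without, each variable, plus the
  full model.
* **Percent contribution** attributes each coordinate-descent step's
  objective decrease to the variable whose feature moved (product features
  split evenly between their pair), floored at zero and normalized to 100.
  It is path-dependent by nature: over exactly duplicated variables the first
  coordinate visited takes the larger share. That asymmetry is inherent to
  cyclic descent and is documented rather than hidden; permutation importance
  is the path-free alternative.
* **Permutation importance** shuffles one predictor across presence +
  background rows, measures the training-AUC drop, averages over
  `n_shuffles`, floors at zero and normalizes to 100. A variable with no
  nonzero coefficient scores exactly 0 before normalization.
* **Variable screening** retains predictors with contribution ≥ 5% **or**
  permutation importance ≥ 5% (the inclusive reading; an AND rule is a
  config switch). The pipeline screens before tuning, using a fast
  linear+quadratic model at RM 1 as the screening fit. If screening would
  drop everything, all variables are kept.

## Geographic analysis

Suitability maps are cut at 0.05 / 0.33 / 0.66 into unsuitable / poorly /
moderately / highly suitable, left-closed ([0.33, 0.66) is moderately; 0.66
itself is highly). "Total suitable" is everything ≥ 0.05. Cell areas are
spherical: R²·Δλ·(sin φ_top − sin φ_bottom), R = 6371.0088 km, so
high-latitude cells weigh less; the suite checks the whole-globe sum and the
cos(latitude) limit. Class centroids are area-weighted means of cell-center
coordinates. Displacement between centroids uses an equirectangular
approximation about the mean latitude (111.320·cos φ̄ km/°lon,
110.574 km/°lat) — error below 0.5% for shifts of the ~10–200 km scale the
package reports. The bearing is the two-argument arctangent of (Δy, Δx)
mapped to [0, 360), measured counter-clockwise from due east; a plain
arctan(Δy/Δx) is quadrant-ambiguous and cannot populate all four compass
quadrants. Exact multiples of 90° get cardinal labels (East/North/West/
South); zero displacement raises rather than fabricating a direction.

## Synthetic data

`synthetic.py` emulates the ingredients of a climate-suitability study:

* **Layers**: white noise smoothed by a Gaussian kernel of width
  `autocorr_length` cells and re-standardized — the simplest controllable
  spatially autocorrelated field. Default 23 layers, matching the size of a
  typical bioclimatic predictor pool.
* **Truth**: suitability is the inverse-logit of a linear/quadratic form in
  named layers. The demo study (`make_demo_study`) makes the active layer a
  Gaussian bump (σ = 10 cells) centred slightly south of the grid centre,
  blended with 10% autocorrelated noise, with coefficients (4, 0) and
  intercept −5: a compact, interior suitable region sharp enough that the
  fitted logistic map robustly exceeds the 0.66 "highly suitable" threshold.
  An interior region matters because future stacks are translations.
* **Presences**: uniform cell proposals accepted by Bernoulli thinning with
  probability proportional to suitability, plus uniform within-cell jitter;
  a configurable fraction of records are exact or near copies of others,
  exercising the thinning stage the way raw field compilations do. The demo
  emits 194 raw records, a typical compilation size before de-duplication.
* **Futures**: every layer translated by a registered (Δlon, Δlat) with
  nearest-value edge extension, so the true range shift is known exactly.
  Demo scenarios shift 8 and 15 cells due north (0.40° and 0.75° at 0.05°
  cells, i.e. 44.2 and 82.9 km).

What passing tests on these data do **not** show: real bioclimatic layers are
cross-correlated families (temperature summaries correlate strongly), real
range shifts are not rigid translations, and real occurrence data carry
survey bias that presence-background models inherit. The synthetic study
validates the machinery — estimation, selection, accounting and geometry —
not the ecological fidelity of any particular real-world prediction.

## Scales, determinism and degenerate inputs

Desk-scale defaults (100×100 grid at 0.05°, 2000 background points, 5
replicates, 16-candidate tuning grid) keep the full pipeline under ~5 s and
the whole test suite under a minute; they are the package's own choice of
demonstration size, and every knob scales up by configuration (30 arc-second
cells, 10,000 background, 10 replicates, 240 candidates). All stage seeds
derive from one master seed via `numpy` SeedSequence, and re-running a
pipeline with identical config reproduces byte-identical CSV/ASC outputs
(hash-checked in the manifest and in tests).

Degenerate inputs are handled explicitly: empty occurrence sets, empty masks
and all-zero truth rasters raise; records off the grid and invalid
coordinates are dropped with logged counts; thinning ties (two records
equidistant from a cell centre) break by lexicographic (lon, lat, source)
order so results are order-free; background requests larger than the number
of valid cells fall back to all cells with a warning; an empty suitability
class makes centroid computation raise rather than return NaN.

## Known limitations

* Percent contribution inherits coordinate-descent path dependence (see
  above); compare with permutation importance before interpreting.
* The AICc parameter count k counts nonzero coefficients, an approximation
  inherited from common practice for L1 paths.
* Rasters are ESRI ASCII grid only; the format is text, self-describing and
  universally importable, but large production rasters would want a binary
  format.
* The equirectangular displacement degrades for continental-scale (>1000 km)
  shifts; switch to a geodesic library if that regime matters.
* Logistic output depends on the entropy calibration; absolute values are
  comparable across models only under equal background construction.
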