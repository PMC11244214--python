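# Methods

`lurpm` implements a parsimonious random-forest land-use regression (LUR)
workflow for PM₂.₅ measured from a mobile, low-cost optical particle counter,
together with a synthetic campaign generator that makes every stage testable
against a known ground truth. This note documents the models, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## 1. Sensor preprocessing

Optical PM readings inflate with relative humidity because hygroscopic
particles take up water. We remove this with the κ-Köhler mass-growth
correction

    C(RH) = 1 + (κ/ρ) / (1/RH − 1),        PM_corrected = PM_raw / C,

with RH as a fraction in (0, 1), hygroscopicity κ (default 0.4) and dry
particle density ρ (default 1.6 g/cm³) — typical urban-aerosol values from
the sensor-correction literature, both configurable. C ≥ 1, is monotone in
RH, and diverges as RH → 1, which is why RH = 1 is rejected rather than
clamped.

The per-round pipeline is fixed: **correct → trim → median → background
subtraction**.

* *Trim*: readings strictly below the 5th or above the 95th percentile of
  the round are removed (`trim_fraction = 0.05`). Trimming applies to the
  PM series only, not to temperature/RH.
* *Temporal median*: non-overlapping (tumbling) 30 s windows, each reduced
  to its median with the window-center timestamp and mean position.
  Tumbling rather than rolling windows yield the sample-count reduction
  appropriate for interpolating ~30 s points onto a 25 m route grid.
* *Background*: the round's 5th-percentile concentration is treated as the
  non-local background and subtracted from every value. Because a linear
  sensor drift shifts a whole round by a constant, this per-round
  subtraction also cancels drift between rounds. Negative local values are
  retained — clipping would bias round means.

Every quantile in the package (trimming, backgrounds, station processing)
uses linear interpolation (type 7), stated once here and used everywhere.
Rounds are processed strictly independently.

## 2. Route aggregation

Rounds never follow identical GPS traces, so an *idealized route* is built:
each round is resampled to a common normalized arc-length parameterization,
positions are averaged pointwise, and the mean path is resampled to uniform
25 m spacing (adjacent 25 m buffer disks then abut). Rounds whose arc
length deviates more than 20 % from the mean are rejected by name — they
indicate incomplete rides.

Preprocessed samples from **all rounds pooled** are assigned to every route
point within an inclusive 25 m radius; each point records max, min, mean,
population standard deviation (a descriptive statistic over the pooled
samples, hence denominator *n*) and the contributor count. The per-point
**maximum** local PM₂.₅ is the modelling target: maxima are the
health-relevant quantity for a pollutant with legal threshold values.

## 3. Buffer predictors

Each gridded predictor layer is summarised at every route point and station
in buffers of 25, 50, 75, 100, 150, 200, 250, 500, 750 and 1000 m radius.
Continuous layers contribute max/min/mean; categorical layers (being
regular grid-point data) contribute the most frequent (`cat_max`) and least
frequent (`cat_min`) code. Conventions, chosen once and tested:

* a cell belongs to a buffer when its **center** lies within the radius
  (inclusive at the boundary); the grid resolution must be ≤ half the
  smallest radius so no buffer is empty;
* frequency ties break to the smallest code; `cat_min` considers only codes
  present in the buffer;
* columns are named `layer_statistic_radius` (e.g. `DTV_min_750`) and
  ordered layer → statistic → radius;
* predictors are left unscaled (forests are insensitive to monotone
  rescaling); rows with any missing predictor are dropped.

Both street-type classifications are treated as categorical; with four
continuous and five categorical layers the baseline table has
3·4·10 + 2·5·10 = **220 columns**. Station rows run through the identical
code path as route rows.

## 4. Monte-Carlo random-forest ensemble

The estimator is a `RandomForestRegressor` (squared-error splits, bootstrap
aggregation) with library defaults and 100 trees as the package default.
Model uncertainty is sampled by refitting under a sweep of `random_state`
seeds and carrying all per-seed predictions through validation; the
full-study convention is seeds 0…999 ("trained 1000 times" is read as 1000
models, i.e. seeds 0–999).

The 70/30 train/test split preserves the target distribution: rows are
stratified over 10 target-quantile bins with largest-remainder allocation,
and the rows holding the global target minimum and maximum are forced into
the training partition so the training range covers the whole data set
(the mechanism is this package's choice; the goal — a distribution-
preserving split including both extremes — is the contract). Train size is
exactly `floor(0.7 n)`; 835 rows split into 584/251.

Metrics: MAE, MSE, RMSE, NRMSE = RMSE/(max − min of observations) (scatter
index), and R² = 1 − SS_res/SS_tot, reported unclipped (negative out-of-
sample R² is informative).

## 5. Feature selection

**RFE / RFECV.** Plain RFE refits the forest and drops the feature with the
lowest impurity importance until `n_keep` remain (default 8, matching the
parsimonious model size; the elimination step is configurable for large
tables). Survivors rank 1; eliminated features rank by reverse elimination
order. Importance ties drop the lexicographically last name, an order-free
rule that makes rankings invariant under column permutation. RFECV wraps
the elimination in k-fold cross-validation (k = 5 by default) and keeps the
survivor set at the feature count with the best mean CV R² (ties prefer the
smaller count; scikit-learn's `RFECV` provides this machinery). Both are
repeated over Monte-Carlo seeds; features with **mean rank strictly below
2** form the RFECV-parsimonious set.

A practical finding encoded in the defaults of the experiment scripts:
impurity importance is diluted when the forest subsamples features at each
split, because the signal spreads over many correlated buffer columns.
Importance *ranking* therefore uses forests with all features per split
(`max_features = 1.0`, 100 trees), while prediction ensembles may use
cheaper forests.

**Sobol GSA.** The fitted forest is treated as a black box. Each
predictor's bounds are its observed min/max; lacking knowledge of the true
input distribution, inputs are sampled **uniformly and independently** over
this box so the whole input space is covered. Constant-range columns carry
no variance and are excluded (their constant value is re-attached at
prediction time). The Saltelli design stacks two quasi-random base matrices
A and B (scrambled Sobol' sequence, seedable) and the D cross matrices
AB_i, totalling S = N·(D + 2) evaluations, with N a power of two — the
full-study configuration N = 2048, D = 214 gives 442,368 evaluations; N is
configuration, not derived (the coefficient-of-variation table lookup that
produced it is out of scope). Categorical columns are rounded
half-away-from-zero and clamped to the nearest valid code.

First-order indices use the Saltelli (2010) estimator
S_i = mean(f_B·(f_AB_i − f_A))/V, total-order indices the Jansen (1999)
estimator T_i = mean((f_A − f_AB_i)²)/(2V), with V the variance of the
pooled A/B evaluations — the defaults of the standard sensitivity-analysis
tooling, so results are comparable. Indices are computed on *predictions*
only, averaged over the ensemble, and reported with their across-model
spread; small negative estimates at finite N are reported as-is and flagged
below −0.05. Screening keeps features with mean FOS **strictly above
0.01** (GSA-parsimonious); the street-augmented variant adds every
`street_*` column.

Six model variants are carried through validation: baseline (all columns),
GSA_parsimonious, GSA_streets, RFE, RFECV_baseline (all columns) and
RFECV_parsimonious. All flow through one code path; only the feature subset
differs.

## 6. Station-style validation

A station's *observed local maximum* is the median, over the days with
bicycle measurements, of its background-subtracted daily values, with the
background again the 5th percentile of the series (temporal, per station)
and even-count medians the mean of the central pair. Station targets are
never used for training. Per-station RMSE is taken over the per-seed
predictions against the single observed value; pooled metrics run over all
(seed, station) pairs.

Note the structural asymmetry this encodes: route targets subtract a
*spatial* quantile (the cleanest 5 % of the ride), station observations a
*temporal* quantile (the calmest 5 % of days). The two agree only insofar
as the route actually visits source-free background locations and the
station's calm days carry no local signal. This is exactly the transfer gap
that makes mobile-trained LUR models validate far worse at reference
stations than on hold-out data, and the synthetic experiments reproduce it
(strong hold-out R², weak station R², with the parsimonious model
transferring no worse than the baseline).

## 7. The synthetic campaign generator

The generator is first-class, tested code; its defaults are the package's
reference study conditions.

* **Layers.** Nine layers on a 2000 m × 2000 m grid at 10 m resolution:
  LAI [0–5], DTV [0–30,000 vehicles/day], PD_ha [0–500 /ha], BH [0–40 m]
  continuous; LCZ (11 codes), LUC (8), BT (6), street_StEP (5), street_RBS
  (7) categorical. Continuous fields are Gaussian-filtered white noise
  (filter σ = correlation length, 150–250 m) rescaled to range; categorical
  fields are argmax patches of per-code smoothed fields. Everything derives
  from a single scene seed.
* **Truth.** Three active layers mirror the dominant urban PM drivers:
  PD_ha +8, LAI −4, DTV +6 µg/m³ per min-max-scaled unit over a 10 µg/m³
  background; min-max scaling makes a location with all active layers at
  their minimum read exactly the background. Gaussian noise σ = 1 µg/m³,
  linear drift 0.5 µg/m³ per round (the drift magnitude is unstated in the
  field and is a free configuration value), κ_true = 0.4, ρ = 1.6.
* **Rides.** One ~23.4 km serpentine route, 8 rounds, 2 s logging at up to
  15 km/h with per-round cruising speeds drawn from 75–100 % of the cap —
  realistic, and it staggers the 30 s median windows across rounds so
  route-point coverage accumulates. Smooth correlated GPS jitter (σ = 2 m)
  perturbs positions without inflating arc length. RH and temperature
  follow smooth diurnal curves; raw PM is the dry concentration times
  C(RH; κ_true), making the correction exactly invertible. About 930 route
  points result, truncated to 835 rows for the reference experiments to
  match the campaign sample size the split counts refer to.
* **Stations.** Twelve stations (3 urban background / 3 suburban /
  6 traffic). Day d reads `background + local·(1 + u_d) + δ_d + ε`, with a
  ventilation-like multiplier u_d ~ U(0, 2) and regional term δ_d shared
  across stations, and station noise ε; with `noise_sd = 0` all stochastic
  terms vanish and the series is the constant deterministic field (the
  noise-free contract used for verification).

What the generator does *not* emulate: meteorological transport and
dispersion, street-canyon geometry, seasonal (winter) chemistry, correlated
sensor failures, and real spatial cross-correlations between land-use
layers (layers are generated independently). Passing recovery tests
therefore shows the *pipeline* is correct and the selection methods can
find true drivers under realistic noise — not that the method would
identify the drivers of a real city's PM₂.₅.

## 8. Problem sizes and numerical choices in the experiments

The reference experiments (test suite and `scripts/acceptance.py`) run the
study at reduced scale, chosen once as the package's experiment
configuration:

* Monte-Carlo ensembles of 50 seeds (for the full-study 1000), with
  20-tree forests using `max_features = 1/3` for prediction ensembles and
  100-tree, all-features forests for importance ranking (§5);
* Sobol screening at N = 128 over the 220-column table; estimator
  correctness itself is checked separately at N = 2048 against closed-form
  decompositions (Ishigami with a = 7, b = 0.1; additive and pure-
  interaction models);
* RFECV with 5 folds and an elimination step of 22 columns (10 % of the
  table); plain RFE with step 10;
* recovery rates measured over 20 independent repetitions (fresh ensemble
  seeds and design scramblings on the fixed scene).

Degenerate inputs are handled explicitly: zero-variance predictions yield
all-zero sensitivity indices with a warning; a zero observation range makes
NRMSE (and pooled single-station R²) undefined — an error in `evaluate`,
NaN in pooled station reports; constant-range predictor columns are
excluded from sampling but refilled for prediction; empty GSA selections
warn and return the empty set for the caller to decide.

## 9. Known limitations

* Buffer statistics weight cells by center membership, not area fractions;
  at 10 m resolution against ≥ 25 m radii the discretisation error is
  small, and the convention is exactly oracle-checkable.
* The idealized-route mean is computed in normalized arc length, which
  assumes rounds traverse the same path in the same direction.
* `cat_min` over present-only codes means a buffer containing a single code
  has `cat_max = cat_min`; downstream models see that as informative.
* Station validation compares a predicted *route-style* local maximum with
  a station-derived local maximum; the backgrounds differ by construction
  (§6), so absolute station metrics carry a structural offset and are best
  read comparatively across model variants.
* The RFECV-parsimonious set can be large when CV favors many correlated
  columns; the mean-rank rule bounds membership, not set size.
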