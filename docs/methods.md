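# Methods

This note records the models, parameter choices, and numerical decisions
behind `musselscape`, in the spirit of a package methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The estimation problem

The data are presence-only: occurrence records of freshwater mussel species
consolidated to the catchment level, with no usable absences and strongly
uneven survey effort. The modelling target is, for each species, a relative
suitability surface over all catchments, thresholded into a binary
occupancy map and stacked into richness, which in turn feeds three
conservation-priority scores.

### Maximum-entropy model

For a species with presence catchments `P` and a normalization pool `B` of
catchments (see *Background selection* below), the model is the Gibbs
distribution over `B`,

    q_λ(i) = exp(λ·f_i) / Z(λ),      Z(λ) = Σ_{i∈B} exp(λ·f_i),

where `f_i` is the feature vector of catchment `i`. Fitting maximizes the
penalized presence log-likelihood

    L(λ) = (1/|P|) Σ_{x∈P} λ·f_x − log Z(λ) − Σ_j β_j |λ_j|,
    β_j  = β · s_j / √|P|,

with `s_j` the feature's standard deviation over `B` and `β` the
regularization multiplier. `L` is concave; at the optimum the KKT conditions
bound every feature's expectation gap, `|E_P[f_j] − E_q[f_j]| ≤ β_j`, with
equality on active features. This certificate is recomputed after every fit
and checked in the tests (tolerance 1e-4; the solver targets 5e-5).

The per-feature penalty scale `s_j/√|P|` is a deliberate simplification of
the feature-class-specific default-penalty tables used by the packaged
MaxEnt implementations; the β grid absorbs the difference in overall scale.

**Features.** Covariates are min–max rescaled to [0,1] using the pool's
range, and clamped to that range at prediction time to avoid extrapolation.
Classes: linear `x`, quadratic `x²`, pairwise products `x_j·x_k` of
continuous covariates, forward and reverse hinges and step (threshold)
functions at 10 knots per covariate placed at evenly spaced interior pool
quantiles, and one indicator per level for binary covariates. Ten knots (the
packaged implementations use denser, data-driven knot sets) keep desk-scale
fits fast while retaining the ability to bend the response; the count is
configurable. Covariates constant over the pool contribute no features and
are logged.

**Output transforms.** `raw` is `q_λ` itself (sums to one over the pool);
`logistic` is `e^H r / (1 + e^H r)` and `cloglog` is `1 − exp(−e^H r)`,
where `H` is the entropy of `q_λ` and `r` the raw value. The packaged
default of the era the dismo/maxent.jar workflow comes from is logistic, so
logistic is the default here; both are monotone in `r`, and thresholds and
richness are always computed on the configured transform consistently.
Transforms are evaluated in log space so extreme coefficients cannot
overflow.

**Optimization.** Proximal gradient (FISTA) with backtracking line search,
soft-thresholding against the weighted L1 penalty, adaptive restart, and
warm starts along the β path (strongest penalty first) and into the k-fold
refits. Convergence requires relative objective change below 1e-9 *and* KKT
slack below 5e-5; the iteration cap is 20,000. If a descent direction is
unbounded (see next paragraph) the solver stops when `‖λ‖_∞` exceeds 1e8
and reports `converged=False` rather than overflowing.

**Well-posedness and the normalization pool.** The background-selection
rule below excludes the focal species' presence catchments from the
selected background. If the fit normalized only over that set, the presence
feature mean could fall outside the convex hull of the background features
(products and indicator features make this easy), in which case the
penalized optimum runs to infinity. The packaged MaxEnt implementations
avoid this by adding the presence samples to the background
(`addsamplestobackground`), and the pipeline does the same: the
normalization pool is the union of the selected background and the presence
catchments, while the *selected background alone* remains the pseudoabsence
contrast set for tuning AUC, evaluation, and thresholding. `fit_maxent`
itself normalizes over exactly the matrix it is given, so the library-level
contract stays literal.

**Tuning.** β is chosen from an integer grid (default 1–15) by the training
AUC of presences against the background contrast set, mirroring a
single-dataset selection procedure; ties go to the smallest β. K-fold
cross-validation (default k = 10, presences partitioned, background fixed)
is reserved for the per-catchment standard-deviation maps. Whether the
original workflow's reported AUCs were training or cross-validated values is
not documented; training AUC is reported here and labelled as such.

### Background selection

Candidates are catchment centroids (one per catchment — all points within a
catchment share its environment). Two exclusions follow: every catchment in
a HUC10 with zero survey events across all species (removes areas far
outside the sampled frame without excluding too aggressively), and every
focal-species presence catchment. From the survivors, up to `n_background`
(default 10,000) catchments are drawn without replacement — a catchment is
one centroid, so duplicates would be meaningless — with selection
probability proportional to survey effort; pools at or under the cap are
used whole.

Two effort weightings are implemented because the source procedure is
describable both ways: `catchment_share` (default), each catchment's share
of all survey events, with zero shares floored at `0.1/n_candidates` so
eligible-but-unsurveyed catchments keep measure-positive support; and
`huc10_share`, the encompassing HUC10's share split evenly over its
candidates. "All survey events" means the all-species survey table after
the modelling-year filter. Sampling without replacement uses the Gumbel
top-k construction, which realises successive draw-and-remove with
renormalization exactly and reproducibly.

### Evaluation

* **AUC**: Mann–Whitney pair statistic via average ranks (ties count half);
  values above 0.7 are flagged acceptable by convention.
* **Continuous Boyce Index**: windows of width one tenth of the score range
  slide across 101 evenly spaced midpoints; per window the
  presence-to-evaluation frequency ratio `F = P/E` is formed (windows with
  `E = 0` skipped) and the index is the Spearman correlation of `F` with the
  window midpoint. Window count and width are conventional defaults and
  configurable. Two caveats are inherent to the index: it is only
  approximately invariant under monotone score transforms (window geometry
  changes), and its null distribution is wide — with these defaults a null
  draw has a standard deviation near 0.3 because the overlapping windows
  leave only ~10 effective degrees of freedom. Tests therefore check null
  *centering* on averaged replicates rather than a single draw.
* **Threshold**: the pooled-score value maximizing sensitivity +
  specificity, background as pseudoabsences; a presence exactly at the
  threshold counts as predicted present (the inclusive convention —
  implementations differ), and objective ties resolve to the smallest
  threshold, favouring inclusion over exclusion.
* **Bookkeeping**: false negatives are recorded-presence catchments the
  binary map calls absent; possible-new catchments are predicted-present
  catchments without records, counted over the whole landscape.

### Richness and prioritization

Binary maps (prediction ≥ threshold) are summed into overall richness and
RSGCN richness (ranks very high / high / moderate). All priority inputs are
min–max scaled; a constant vector scales to all zeros (a convention — the
region-scale analysis never encounters it, but degenerate test landscapes
can). Restoration is restricted to species ranked high or very high, by
rank metadata rather than species names, and a catchment is eligible for a
species only if its HUC8 contains a record — ineligible catchments carry
NaN, not zero, and state summaries render them as N/A. Ranked priority
lists break ties by catchment id for reproducible output. The forest-cover
input's spatial scale is accepted as whatever per-catchment column the
caller declares (the source material is ambiguous between catchment and
watershed scale); the synthetic generator supplies a catchment-scale
column.

## The synthetic landscape

The generator emulates the study conditions so that recovery of known truth
is testable:

* **Hierarchy**: HUC8 blocks tile a square region, HUC10s tile each block,
  HUC12s each sub-block, catchment centroids jittered inside their HUC12
  cell; codes follow the nested digit-string convention; HUC8s cycle
  through six state labels. Default 6 × 4 × 5 × 42 = 5,040 catchments with
  12 species — the study's species count at roughly 1/13 its catchment
  count, a deliberate desk-scale choice.
* **Covariates**: Gaussian-kernel-smoothed white noise sampled at the
  centroids, weights normalized to unit marginal variance; range 0
  degenerates to i.i.d. noise, range ≫ extent to a near-constant field.
  Default range 15 (HUC10-scale structure on a 300-unit landscape). One
  binary "tidal" covariate marks the southern coastal strip. A full
  Gaussian process would add nothing: only rank structure matters
  downstream.
* **Truth**: per species, suitability = inverse-logit(intercept + Σ coef·x)
  with 3–5 nonzero coefficients of magnitude 0.8–2.5 and random sign; the
  intercept is root-solved so mean suitability equals the prevalence
  target. The twelve default prevalences (0.04–0.35) span the reported
  range of percent-of-catchments occupancy across the modelled species, and
  the rank composition (2 very-high, 3 high, 2 moderate, 5 unlisted)
  matches the study's RSGCN table. A logistic truth makes parameter
  recovery well-defined even though the estimator is MaxEnt.
* **Surveys**: HUC10 effort shares from a symmetric Dirichlet
  (concentration 1 by default — uneven, with some HUC10s effectively
  unsurveyed), catchments uniform within HUC10; 8,000 events with years
  uniform over 1970–2022 so both the 1952 modelling cutoff and the 1992
  survey-recency binary bite.
* **Observation**: latent occupancy is one Bernoulli(suitability) draw per
  catchment; each survey event in an occupied catchment detects with
  probability 0.7; only detections are recorded (presence-only).

What the generator does *not* emulate: river-network connectivity and flow
direction, dispersal limitation beyond the HUC8-occurrence covariate,
shared environmental responses between species (default coefficient vectors
are independent, so interspecies prediction correlations center near zero
rather than being positive as co-occurring real assemblages are), abundance,
and temporally varying effort. Passing recovery tests therefore shows the
estimator chain is correct under the stated observation model, not that
real mussel data meet its assumptions.

## Pipeline conventions

Record filters use year ≥ cutoff; the modelling cutoff defaults to 1952 and
the survey-recency binary to 1992 (both configurable — the source material
is ambiguous about the intended modelling window, citing both 1952 and "the
last thirty years"). Expert choice among correlated covariates is replaced
by an explicit `keep_priority` order (default: column order); ties at
exactly ρ = 0.70 are not flagged (strict inequality). Constant covariate
columns are rejected at load. VIF is computed from per-column OLS R² and
checked against the inverse-correlation-matrix identity in tests; exact
collinearity reports an `inf` sentinel.

Per-stage seeds derive from the master seed through `SeedSequence` children,
so runs are byte-reproducible and stages are independently invocable; stage
subcommands recompute their upstream (cheap and deterministic) rather than
resuming from partial state. Outputs are plain CSV plus a JSON manifest; no
geometry outputs are produced (inputs arrive as precomputed per-catchment
columns, and centroids are plain coordinate columns).

## Known limitations

* Training AUC on presence-vs-biased-background understates or overstates
  discrimination depending on effort bias; truth-based AUC in the tests is
  the cleaner recovery measure.
* The restoration and protection weights are unweighted sums of scaled
  inputs, as in the source procedure; no attempt is made to learn weights.
* The CBI's wide null distribution (above) means single-model CBI values
  should be read with ±0.3-scale uncertainty at these window defaults.
* `kfold_sd` uses the population standard deviation over the k refit
  predictions.
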