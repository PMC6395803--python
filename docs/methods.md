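# Methods

## The question and the experimental logic

A correlative species distribution model can only be as good as its
predictors. Community-mean ecological indicator values (site EIVs)
integrate the environment as experienced by the plants at a plot; mapped
GIS layers integrate it as interpolated from stations, elevation models
and coarse soil surveys. If models driven by site EIVs outperform models
driven by mapped layers *for the same environmental factor*, the mapped
layer is missing real signal. The package runs this comparison as a
controlled substitution experiment over named predictor sets, evaluated
per species on plots held out from all fitting.

Because the interesting claim is causal ("the maps are missing signal"),
the package is built around a simulator in which that claim is true by
construction and its size is known: species respond to *latent* gradients,
models see *mapped* copies of them with controlled error. Every downstream
stage is validated against this ground truth.

## The synthetic study system

**Landscape.** Each latent gradient is Gaussian white noise on the grid
convolved with a Gaussian kernel (its *length scale*, in cells) and
standardised to zero mean, unit variance. A mapped layer is its source
gradient plus an independent smoothed noise field scaled by `error_sd`
(in latent-SD units), so the expected latent–mapped Pearson correlation is
`1/sqrt(1 + error_sd^2)`. Defaults (120×120 grid, 25 m cells):

| latent gradient | length scale | mapped layer(s) | error_sd |
|---|---|---|---|
| temperature | 20 | temperature | 0.0 (exact) |
| moisture | 8 | precipitation | 3.0 |
| light | 8 | radiation | 3.5 |
| reaction (pH) | 8 | ph | 1.5 |
| nutrients | 8 | soil_nutrients | 4.0 |
| continentality | 6 | topo_position, slope | 8.0, 10.0 |

The pattern encodes the study system the framework targets: temperature
maps in mountain regions are accurate; precipitation, radiation and soil
maps are progressively worse; topographic stand-ins for continentality are
nearly uninformative. Continentality's short length scale reflects that it
varies at fine topographic grain — which is also why, with few smooth
patches to exploit, no combination of the other layers predicts it well.

**Species.** 250 virtual species with Gaussian niches on all six latent
gradients (the six dimensions are exactly the factors indicator systems
score because they matter to all plants). Optima are uniform over each
gradient's observed range; breadths are U(1.8, 3.5) latent-SD, with a
narrower U(1.0, 2.0) for temperature — the dominant sorting axis of
mountain floras, and the reason temperature dominates variable importance
in the reference models. The maximum occurrence probability
(`prevalence_scale`) is U(0.7, 1.0). A species' indicator value on a
dimension is the 1-based equal-width 5-bin index of its optimum over the
landscape range (clipped at the top edge), i.e. an honest but coarse,
ordinal summary of the true optimum; 5% of (species, dimension) values are
set missing.

**Plots.** 1,200 plot cells sampled without replacement;
P(presence) = prevalence × Π_d exp(−(x_d − opt_d)²/(2σ_d²)) over the
latent values at the cell, realised as independent Bernoulli draws. Plot
predictors are read from the *mapped* layers. Under these defaults plots
hold ≈30 species on average and ≈230 of the 250 species exceed the
modelling threshold of more than 30 presences (the real-data default is
more than 50).

These defaults were calibrated once, before any acceptance measurement was
frozen, so that the simulated rank correlations between site EIVs and
their mapped counterparts reproduce the magnitudes reported for real
mountain vegetation data (≈0.92 for temperature, ≈0.2–0.5 for the rest):
that cross-correlation structure, not any model output, was the
calibration target.

**What the simulator does not emulate.** Latent gradients are mutually
independent (real climate and soil variables share elevation structure);
detection is perfect and plot size plays no role (a per-group detection
factor exists but defaults to 1); there is no dispersal limitation, no
biotic interaction, no abundance. Passing tests therefore show the
pipeline recovers a known signal through the EIV mechanism — not that any
particular effect size transfers to field data.

## Site EIVs

The site EIV of a plot on a dimension is the arithmetic mean of the
indicator values of the species present, skipping species whose value on
that dimension is missing — unweighted, since the models use
presence/absence only. For a focal species being modelled, that species is
excluded from every mean (leave-one-out), which makes the predictor matrix
species-specific; plots whose mean becomes undefined on a required
dimension are dropped from that species' model data. Site EIVs are kept
continuous (no rounding). The calculator caches the all-species sums, so a
focal species' matrix is obtained by subtracting one row; cached and
recomputed results are contractually identical.

## SDM engines

All engines share one fit/predict contract (scores in [0, 1]) and are
deterministic given seed and fitted state.

* **GLM** — binomial logistic regression on standardised linear +
  quadratic terms, with a tiny L2 ridge (1e−6 on standardised
  coefficients) that keeps coefficients finite under perfect separation.
* **GAM** — binomial model with univariate B-spline smooths, basis
  dimension 4, degree 3 (statsmodels). Prediction clips new values to the
  training range of each predictor (constant extrapolation at the edges);
  constant columns are dropped from the smoother, which is the zero
  smooth.
* **RF** — 500-tree classification forest; score is the presence-vote
  fraction.
* **MAXENT** — a presence/background exponential-family model
  approximated as L2-penalised logistic regression (penalty weight 1.0)
  on linear + quadratic features; since the data are presence/absence
  plots, absences serve as the background sample. Hinge/threshold feature
  classes are deliberately out of scope.
* **SRE** — surface range envelope: per-predictor two-sided quantile
  envelope of the presence points (default 0.025 per side,
  linear-interpolation quantiles); a point scores 1 iff it lies inside
  every envelope.

## Evaluation

One external 70/30 split per species (evaluation size ⌊0.3 n⌋), with the
30% never used in any fitting step — an explicit guard raises if a fit
call touches an external plot id. Ten internal 70/30 resplits of the
calibration plots provide repeated cross-validation. Splits are seeded per
species from the master seed, since the usable plot set differs per focal
species after leave-one-out dropping.

Metrics: AUC in the Mann–Whitney formulation (ties count one half); TSS
and Cohen's kappa maximised over an exact threshold grid (all midpoints
between consecutive distinct scores, plus 0 and 1 — no resolution
parameter); accuracy reported at the TSS-maximising threshold; and, for
GLM/GAM, D² = 1 − Dev(model)/Dev(null) with binomial deviance. On
evaluation data the null deviance is that of the evaluation subset, so D²
is a pure evaluation-set quantity and can be negative. Probabilities are
clipped at 1e−10 in deviances.

Predictor sets are compared per technique and metric with two-sided paired
Wilcoxon signed-rank tests against the reference set, Holm-adjusted over
the family; pairs with all-zero differences get p = 1 by convention, and
species with failed fits are excluded pairwise.

Permutation importance follows the shuffle-and-correlate convention:
importance = 1 − mean Pearson r between original predictions and
predictions with one column permuted (10 permutations by default; the mean
r is clipped into [0, 1] first, so importance stays in [0, 1] and a
negatively correlated shuffle cannot push it above 1). Raw importances are
not normalised in files; the per-model normalised profile (fractions
summing to 1) is emitted alongside for evenness summaries, where evenness
is Pielou's Shannon-entropy ratio.

## M_cor and the EIV-mappability analysis

`M_cor` picks, per EIV dimension, the candidate mapped column with maximum
absolute Spearman correlation to the all-species site EIV (ties broken by
column order; duplicate selections collapse). The screen runs on the
calibration side of a dedicated master split so it never sees external
plots — a deliberate choice where the original workflow is ambiguous.

The mappability analysis asks whether a site EIV is predictable from the
mapped layers at all: 25 repeated random 70/30 splits (the natural reading
of "25-fold cross-validation (70/30% split)", since a literal 25-fold
partition cannot be 70/30), four regression engines (Gaussian GLM with
quadratics, Gaussian GAM, GBM with 500 trees / depth 3 / learning rate
0.05, and a 500-tree regression forest), scored by Pearson r and RMSE of
predicted vs observed site EIVs per repeat. Site EIVs here are all-species
means — there is no focal species in this analysis, so no leave-one-out
exclusion applies. Test folds with constant observations leave r undefined
for that repeat (logged, skipped in the mean).

## Numerical and design choices

* All generators and the experiment are pure functions of (config, seed);
  per-species and per-variable seeds derive from the master seed via
  `SeedSequence`, so results do not depend on iteration order.
* 70/30 rounding puts ⌊0.3 n⌋ plots in the test side, deterministically.
* Constant predictor columns are retained (logged) for all engines except
  the GAM smoother; a constant column standardises to zero and gets a zero
  coefficient.
* Species present in plots but absent from the EIV table are skipped per
  dimension with a warning.
* The moisture dimension is written "M" throughout; "F" (an older code
  for the same value) is accepted as an input alias.
* Ensemble forecasting and spatial raster projection are explicit
  non-goals; the framework compares inputs, not modelling stacks.

## Default analysis scale

The stock recovery analysis (`eivsdm.study.recovery_analysis`) runs the
GLM engine on the sets M_ref, M_T and M_EIV with external evaluation only
and 25 mapping repeats — the smallest design that measures all four
built-in contrasts (EIV gain, temperature neutrality, importance
spreading, mappability ordering); it completes in about a minute on one
CPU. The full ten-set, five-technique, internal+external design is
available through `ExperimentConfig` and the `eivsdm run` CLI.

## Known limitations

* The GAM's fixed basis dimension and penalty are not tuned per species;
  severely wiggly responses are under-smoothed relative to a
  generalised-cross-validation fit.
* The MaxEnt approximation shares only the feature space and the
  regularised-likelihood idea with presence-only MaxEnt software; with
  true presence-only data a background sampler would be needed.
* SRE scores are 0/1, so threshold metrics are degenerate for it (AUC is
  still informative as a two-point ranking).
* With very sparse plots (few contributing species) site EIVs are noisy
  averages; the pipeline drops undefined means but does not model the
  uncertainty of defined ones.
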