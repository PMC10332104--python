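# Methods

## Data model

Methylation is represented as beta-values β ∈ [0,1] (fraction methylated at a
CpG) in a features × samples matrix; M-values M = log2(β/(1−β)) are supported
as an alternative scale with better variance behaviour near 0 and 1.  The
open-interval definition of β is relaxed to the closed interval because real,
rounded data contains exact 0s and 1s; these are clamped to [1e−6, 1−1e−6]
only inside the β→M transform, never in storage, which makes the β↔M
round-trip exact to 1e−9 on the clamped range.  Missing values are NaN,
accepted on read as `NA`, `NaN` or an empty cell and written as `NA`.

## Signature selection

For target cell type *c* and site *i*, the selector computes the difference
of group means Δᵢ = μᵢ^cell − μᵢ^others and the sum of group variances
σᵢ = varᵢ^cell + varᵢ^others (unbiased, n−1 denominator — the estimator is a
free choice; the biased variant changes a by a common factor per group size
and thus barely affects ranking).  The selection score aᵢ = σᵢ/Δᵢᵇ with an
even exponent b prefers large mean separation and small within-group spread;
b = 2 by default, larger b weights separation more.  Δ = 0 yields a = +∞, so
non-discriminative sites can never be selected; σ = 0 with Δ ≠ 0 (a perfect
separator with zero spread) yields a = 0, the best possible score.  Sites at
or below the 0.5 % quantile of a (finite scores only, ties at the threshold
included) form the *active* set.

A stratified K-fold cross-validation (k = 10 by default, reduced to the
number of target-class samples when that is smaller; folds from
scikit-learn's StratifiedKFold, so each fold's class fraction deviates from
the global one by at most one sample) repeats the pre-selection on each
fold-train portion and scores the active sites as one-feature classifiers by
AUPR on the fold-train and fold-validation portions.  "Balanced stratified"
is implemented as pure stratification, not negative down-sampling, and the
active-set quantile is recomputed per fold.  AUPR is estimated as average
precision with tie-grouping: equal scores collapse into one threshold step
and every positive in the group contributes the precision at the group
boundary.  This estimator is interpolation-free, well defined under ties
(a constant feature scores exactly the class prevalence) and is
cross-checked in the tests against both an exhaustive threshold-enumeration
oracle and scikit-learn's `average_precision_score`.  A site's orientation
(hyper: score = x; hypo: score = −x) follows the sign of its fold Δ.

The final score combines the global selection score with the CV evidence:

    Cᵢ = (α₁·ãᵢ + α₂·AUPR_t,i + α₂·AUPR_v,i) · fᵢ/k

with ãᵢ = 1 − minmax(aᵢ) over the active sites (infinite a maps to ã = 0;
when all finite a are equal, ã = 1 for all), fᵢ the number of folds in which
site *i* was active, and α₁ = 0.8, α₂ = 0.2.  This arrangement — normalising
and direction-flipping a, and multiplying by f/k rather than dividing by f —
makes larger C uniformly better and bounds it by α₁ + 2α₂ = 1.2; summing a
raw to-be-minimised a with to-be-maximised AUPRs and dividing by f would
invert the intended optimisation direction.  Ties are broken by higher
validation AUPR, then lexicographic feature id, so rankings are
reproducible.  Features with missing values in the training split are
excluded from selection (counted and logged) rather than imputed; imputation
is reserved for the deconvolution stage where predictions must be produced
for every sample.

The brute-force baseline ranks every site by test-set AUPR with automatic
orientation; it serves as the selection-quality oracle.  The unsupervised
pre-filter for high-dimension-intolerant downstream models drops
near-constant sites (variance < 1e−8), one of each pair with |Pearson r| >
0.9 (keeping the higher-variance member), and exact linear combinations
(sequential Gram–Schmidt with relative tolerance 1e−8, original order
preserved so earlier features win).

## Deconvolution

The reference W holds, per signature CpG and cell type, the mean training
beta (or, for score-based classifiers, the mean classification score per
classifier per type).  Mixtures are modelled as V = W·H and solved per
column with scipy's NNLS; a rank-deficient W triggers a warning but still
returns a solution.  Negative entries are capped at zero (a no-op for NNLS
proper, relevant for pluggable back-ends).  Columns are renormalised to sum
to one by default because the ground truth (FACS fractions, simulated
Dirichlet proportions) lives on the simplex; raw coefficients are available
with `normalize=False`, and all-zero columns are left at zero with a
warning.  Feature alignment is an inner join on probe id in reference order;
losing over half the reference warns.  Missing mixture entries are filled
with the feature's mean across mixture samples; a feature observed in no
mixture sample falls back to the mean of its reference row, and the imputed
count is reported for the run log.  Aggregation into broader groups
(e.g. neutrophils + eosinophils + basophils → granulocytes) sums member
rows and conserves column totals exactly.

## Evaluation metrics

RMSE and two R² variants are provided.  The diagonal R²,
1 − Σ(true−pred)²/Σ(true−mean(true))², measures fit to the identity line and
penalises systematic bias (it can be negative).  The fitted R² is the
adjusted R² of the OLS regression true = a·pred + b with p = 1 predictor,
1 − (1−R²)(n−1)/(n−p−1); because slope and intercept absorb any affine bias,
pred = true + 0.2 scores a perfect fitted R² while its RMSE is 0.2 — the
reason RMSE or diagonal R² should judge deconvolution accuracy.  The R²
denominator is the total sum of squares of the response, matching the
standard regression summary (R's `lm`/`summary`); a variant using the
predictor's sum of squares is available behind `denominator="printed"` for
comparison with a published formulation, but it does not equal the standard
summary R² and is not the default.

Method comparison uses the Friedman test on a methods × blocks table:
midranks within each block (rank 1 = best; a lower-is-better flag serves
RMSE-like metrics), statistic 12n/(k(k+1))·Σⱼ(R̄ⱼ−(k+1)/2)² with a χ²(k−1)
p-value, deliberately without scipy's tie correction so the statistic equals
the hand-computable closed form (the tests confirm equality with scipy on
tie-free tables).  The Nemenyi critical difference is
q₀.₀₅(k)·√(k(k+1)/(6n)) with an embedded table of q₀.₀₅ =
studentized-range/√2 for k = 2..20 (cross-checked against
`scipy.stats.studentized_range`); only α = 0.05 is supported.

## Synthetic data

The generator emulates purified-cell array panels: per cell type,
`n_markers_per_type` marker CpGs drawn from Beta distributions with mean
0.85 in the own type and 0.10 elsewhere (odd-indexed markers flipped to
hypo-methylated to exercise direction handling), plus `n_background` CpGs
whose mean, uniform in (0.2, 0.8), is shared across types.  Beta
distributions are parameterised by (mean, concentration) with
α = mean·conc, β = (1−mean)·conc; the default concentration 50 gives a
within-group sd of ≈ 0.05 at the marker means, comparable to good-quality
purified references.  Defaults: 6 types, 3 markers each, 5000 background
CpGs, 20 samples per type.  Mixtures are V = profiles·H + N(0, 0.01) clipped
to [0,1], with H columns Dirichlet(1) over the types — i.e. uniform on the
simplex — and 20 mixture samples.  Everything is driven by a single integer
seed through `numpy.random.default_rng`, so runs are bit-reproducible.

What the generator does **not** emulate: probe-level artifacts (type I/II
chemistry, dye bias, detection p-values), between-study batch effects,
correlated background CpGs (CpG islands), cell types with graded rather than
bimodal markers, and realistic marker scarcity.  Passing the recovery tests
therefore shows the selector is correct and robust under its stated model,
not that one CpG suffices for any real tissue panel.

## Problem sizes and numerical choices

The bundled verification runs use the generator defaults above (5018 CpGs ×
120 samples per panel, 20 seeded replicates; brute-force comparisons on
2006 CpGs × 120 samples; 50 random 12-type reference/mixture pairs with
12–120 features), sizes at which every property of interest is already
stable while a full run stays in the minutes range on one CPU.  Notable
numerical decisions: quantile thresholds via `numpy.quantile` (linear
interpolation) with ties at the threshold included; minimum one active
feature even for tiny quantiles; noiseless NNLS recovery asserted to 1e−6;
normalised proportion columns sum to 1 within 1e−9; matrix round-trips
through TSV/CSV use 12-significant-digit output and round-trip float
parsing.

## Known limitations

- One-CpG signatures are only as good as the reference panel; types missing
  from the panel are silently absorbed into the others' proportions.
- The selector evaluates CpGs marginally; it will not find multi-CpG
  combinations whose joint signal exceeds any single site.
- The Nemenyi table covers 2–20 methods at α = 0.05 only.
- `classifier_scores` references assume one score column per cell type;
  multi-output models must be split beforehand.
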