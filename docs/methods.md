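# Methods

## The modelling problem

Road presence on a 1-ha grid is a presence–background problem: absences are
uncertain (roads appear, are abandoned, or are missed by digitisation), the
classes are heavily imbalanced, and the data are spatially autocorrelated.
The routine addresses each point in turn: down-sampled balanced training
draws handle imbalance and imperfect detection; a complex region-balanced
subsampling schedule prevents the largest region from dominating; and a
residuals autocovariate absorbs spatial autocorrelation rather than letting
it masquerade as covariate signal.

## The region-balanced forest

Training data are divided, per region, into subsamples with fixed class
counts (partition mode draws them disjointly and errors on a shortfall;
resample mode serves small pools). An *iteration plan* assigns exactly one
subsample per region to each iteration; a region with `c` subsamples reused
`m` times each requires `c × m` to equal the common iteration count, which
the scheduler enforces — with subsample counts of 60/20/10 a 60-iteration
schedule therefore implies reuse multiplicities of 1/3/6. Pairing across
regions is a seeded random assignment; cyclic pairing would risk systematic
subsample co-occurrence.

Each tree is an ordinary CART classifier (Gini, `mtry = sqrt(p)`, unlimited
depth — the standard random-forest defaults; the contribution is the
sampling and combination scheme, not the split rule) fitted on an
independent with-replacement draw of fixed class counts from the
iteration's pool. Prediction is vote aggregation: the presence probability
is the fraction of trees voting presence, so outputs live on the grid
k/T and the 0.5 classification rule resolves exact ties toward presence.

Permutation importance (MDA) is measured on a held-out draw at original
prevalence, disjoint from every training subsample, because the bespoke
sampling breaks classic out-of-bag bookkeeping. A variable no tree splits
on has MDA exactly 0.

## Rank encoding

Categorical covariates are replaced by integer ranks of their class means
of the response, fitted on the model training sample (the union of all
subsamples) and applied landscape-wide with a median-rank policy for
unseen classes. Ties in class means break lexicographically so the
encoding is seed-free. The per-country variant ranks (country, class)
combinations in one pooled ordering, letting the same protected-area class
rank differently in different countries; both flavours compete as a
variant group in generation-1 filtering.

## Three generations and the SAR term

Generation 1 fits on every candidate (including focal-mean variants of
population density at radii 3 and 8 cells). Filtering drops MDA ≤ 0 —
negative permutation importances are noise, so the cut is at ≤ 0 rather
than exactly 0 — and keeps the arg-max variant per variant group (ties to
the lexicographically first name). Generation 2 refits and predicts the
whole landscape in chunks (chunking provably does not change outputs);
residuals `y − p̂` on each region grid yield the residuals autocovariate:
the neighbourhood mean of residuals, queen scheme, radius 1, focal cell
excluded, edge cells shrinking to available neighbours. The radius is
configurable because no single neighbourhood is canonical at this
resolution. Generation 3 refits with the SAR term appended; every
performance or forecasting path holds it at 0 so it soaks up
autocorrelation during fitting without leaking observed-residual
information into predictions. Moran's I (binary, non-row-standardised
weights) of the residual grids is reported per generation; on the default
synthetic system it falls by roughly two thirds from generation 2 to 3.

## Risk index

The partial prediction surface holds socioeconomic continuous covariates
at their training-sample mean (zero would be meaningless for a
standardized density) and rank-encoded administrative covariates at zero
("below every observed class"); biophysical covariates stay free and the
SAR term is 0. Means are frozen from the training sample, so the surface
is exactly invariant to the prediction table's socioeconomic values. The
threshold maximising sensitivity + specificity is searched over the
observed unique raw scores (vote fractions form a finite grid; ties break
to the smallest candidate), and the two-segment piecewise-linear rescale
pins (min, threshold, max) to (0, 0.5, 1), accepting the slope
discontinuity at 0.5. Degenerate half-intervals map the coincident
endpoint to 0.5 with a warning.

## Impact response and model

The 25-m impact layer is aggregated per 1-ha cell as the fraction of its
16 subcells impacted and binarised at ≥ 10% (inclusive: 2/16 = 0.125 is
present, 1/16 is not), discarding cells where an isolated misclassified
subcell would otherwise count. The impact model reuses the identical
subsampling/scheduling routine with impact presence as the response and
exactly five predictors: the risk index, population density, GDP, and
administrative region and protected-area class rank-encoded against the
impact response.

## Evaluation and sensitivity analyses

Evaluation draws `n` records per region at the region's own prevalence
(presences = round(prevalence × n)), scores with the SAR term at 0, and
reports AUC (Mann–Whitney with half-credit ties) pooled across regions
per iteration — the pooled statistic is the default; per-region values
are always reported alongside. Draws that would be single-class retry
with fresh sub-seeds a bounded number of times before erroring. The
representativeness report compares paired quantiles of the training
sample and the full landscape per covariate, deliberately without a
hypothesis test (at landscape sample sizes any test flags trivial
differences).

The sensitivity harness retrains the same plan under balanced,
original-prevalence, and class-weighted (inverse-frequency) per-tree
draws; subsamples, schedule and every evaluation draw are bit-identical
across frameworks so comparisons are paired. The alternative
variable-selection route scores variables by mean absolute tree-path
attribution — walking each record's decision path and crediting the
change in node presence-fraction to the split variable, which is exactly
additive per record (base + Σ attributions = mean leaf probability) —
and reuses the same filtering rule.

## The synthetic study system

The generator emulates the statistical structure the analysis assumes,
not any real geography. Defaults: three 200×200-cell regions (120,000
1-ha cells). Continuous covariates are stationary Gaussian random fields
(Gaussian-smoothed white noise on a torus; the smoothing scale is the
correlation length in cells; length 0 is i.i.d.), standardized to mean 0,
sd 1 — slope (length 10), roughness (6), silt fraction (12), rainfall
seasonality (20), population density (15), GDP (25), plus two pure-noise
fields (8). Distance to river is the exact Euclidean distance (cell
units, planar) to a random feature set of density 0.002. Administrative
region (6 classes), vegetation class (4) and protected area (3) are
contiguous nearest-seed block partitions.

Roads are Bernoulli with a logistic link over *standardized* covariates
(categorical classes enter via z-scored class codes so coefficients are
comparable): slope −1.0, roughness −0.6, silt +0.8, rainfall seasonality
−0.7, distance-to-river −1.2, population density +0.8/+0.9/+1.3 by
region (deliberately strongest in the sparsest region), GDP +0.6,
administrative region +0.6, vegetation +0.6, protected area −0.8, plus a
spatially correlated noise field (range 6 cells, sd 1.0) that gives the
SAR term something real to absorb. Region intercepts −0.5/−1.0/−1.5
create unequal prevalences (~0.42/0.37/0.32), exercising the
region-balancing machinery. Effect sizes near |1| on standardized
covariates are what moderate, realistic landscape-scale logistic effects
look like; the noise sd matches the strongest single covariate so the
problem is neither trivial nor hopeless. Impact subcells are Bernoulli
with logit −4 + 5·road: road cells are nearly always impacted at the
1-ha/10% aggregation while ~3% of background cells are, concentrating
impact near roads without making the response a copy of the road layer.

What the generator does not emulate: road network connectivity and
topology (cells are conditionally independent given covariates and the
noise field), temporal road dynamics, measurement error structure, and
real covariate inter-correlations. Passing tests therefore demonstrate
that the machinery recovers known structure under the stated model, not
that any real-data result is reproduced.

## Problem sizes and numerical choices

Desk-scale defaults — 6/3/1 subsamples at multiplicities 1/2/6 (6
iterations × 5 trees = 30 trees), 500+1,000-record subsamples,
400+400-per-tree draws, 25 evaluation iterations × 2,000 records per
region — were chosen so a complete run finishes in seconds while every
structural property of the full-scale design (unequal subsample counts,
reuse multiplicities, balanced draws) is exercised. The test suite uses a
further-reduced 80×80 system for unit fixtures. Categorical block
covariates carry little recoverable information at these grid sizes (a
handful of contiguous patches per region), so parameter-recovery
assertions target the continuous causal drivers; the categorical effects
still contribute signal but their MDA sits near the noise floor at desk
scale.

All randomness flows from one master seed through stable BLAKE2 hashing
of (seed, stage-label) paths, so any stage can be recomputed in isolation
and full reruns are byte-identical. Moran's I errors on zero-variance
input; AUC and threshold search error on single-class input; per-tree
class counts of zero are rejected rather than silently accepted. Raster
interchange uses plain multi-band TIFF with a JSON band manifest — the
synthetic world is planar, so no georeferencing is attached.

## Known limitations

Rank encodings are fitted once on the training sample; concept drift
between training sample and prediction domain is handled only by the
median-rank fallback. The risk index's mean-vs-zero hold assignment is a
policy choice (configurable) — only the three rescale anchors are pinned
by the method's definition. Region-specific models rebuild the SAR term
from region-specific generation-2 residuals; sharing the pooled SAR term
is a defensible alternative not implemented. The impact model assumes the
same scheduling structure as the road model.
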