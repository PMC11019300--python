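# Methods

## Model and estimators

The unit of analysis is a paired comparison: one fenced livestock-exclusion
plot versus adjacent grazed land, measured for one of three response
variables (species richness, Shannon diversity, aboveground biomass). The
effect size is the log response ratio `LRR = ln(Xt/Xc)` (treatment =
exclusion, control = grazing), defined only for strictly positive means;
its sampling variance is the delta-method form
`v = st²/(nt·Xt²) + sc²/(nc·Xc²)`. No small-sample correction is applied by
default; the second-order Taylor correction for the bias of `ln` of a
sample mean is available behind `compute_effects(...,
small_sample_correction=True)`.

Pooling is inverse-variance weighting. The fixed-effect (common-effect)
summary uses `w = 1/v`; the random-effects variant estimates the
between-comparison variance τ² by the DerSimonian–Laird moment estimator
`max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw`, and re-pools with
`w* = 1/(v + τ²)`. Both are always computed; the *headline* model is a
configuration switch (default fixed, matching the `w = 1/v` weighting the
formulas above define). All 95% intervals use the conventional multiplier
1.96, not the more decimal places of the normal quantile, because that is
how such intervals are printed and compared in this literature. An effect
is called significant only when both `p < .05` and the 95% CI excludes
zero. Heterogeneity is reported as Cochran's Q against χ²(k−1) and
`I² = max(0, (Q − df)/Q)·100`; Q and I² always refer to the fixed-effect
weights of the pooled set, whatever the headline model. No multiplicity
adjustment is made across the three response variables; each is a separate
synthesis.

Subgroup analysis pools within the levels of a categorical moderator and
tests between-level differences. Under the fixed model the test is the
exact Q partition (`Q_total = Q_between + ΣQ_within` under the shared
weights, checked to 1e-8 in the tests). Under the random model the
mixed-effects variant is used: each level gets its own τ², and Q_between is
formed from the level estimates and their random-effects precisions. The
fixed partition is anticonservative when I² is large, which is why the
mixed variant exists; levels with a single comparison are pooled but
flagged. Rows with a missing moderator value are dropped with a warning
rather than failing the analysis — extraction tables do not always
classify every comparison.

Meta-regression is weighted least squares of the LRR on an intercept plus
one covariate. With known sampling variances the coefficient covariance is
`(X′WX)⁻¹` — deliberately *not* rescaled by the residual mean square, which
is why the solver is written here rather than delegated to a generic WLS
routine (generic WLS treats weights as relative and rescales; the tests
pin both behaviours: coefficients agree with statsmodels, covariance agrees
with the known-variance convention of dedicated meta-analysis software).
The `mixed_mom` method first adds a method-of-moments residual τ²
(the DerSimonian–Laird generalisation using the weighted hat matrix) to
every variance. `QM`/`QE` give the weighted model/residual decomposition.

The cross-response regression joins two effect tables on `comparison_id`
(same site, duration and intensity) and regresses one variable's LRR on
the other's, weighting by the outcome's variances. It refuses to fit below
a configurable minimum of joined pairs (default 5): a handful of points
cannot support a weighted slope, and the refusal is an explicit error
rather than a silently unstable estimate.

Influence diagnostics are re-fitting probes, not closed-form statistics:
`leave_one_out` refits the chosen analysis k times and flags omissions
that flip the significance verdict or move the estimate by more than
`se_multiple` × SE(base) (default 1 — there is no field-standard numeric
criterion, so the flag threshold is explicit and configurable);
`exclude_and_refit` applies a named rule such as `max-duration`, with ties
all excluded and logged.

## Data handling

Input tables are long-format UTF-8 CSV, one row per comparison × response
variable. The dispersion ladder runs per arm in fixed precedence: reported
SD, else `SE·√n` with that arm's own n (the convention when arms differ),
else one tenth of the arm mean. Every rung leaves a provenance flag so a
sensitivity analysis can drop or down-weight `tenth_of_mean` rows. The
ladder is idempotent and never touches means, sample sizes or moderators.
Category harmonization maps qualitative intensity labels (*extensive* →
low, *overgrazing* → high), collapses grassland names to
{tall_grassland, bofedal}, and derives missing grazing history from
geography (camelid-dominated tropical sites → long, i.e. millennial;
subtropical sites stocked with European livestock → short, < 500 years).
Duration 0 (an exclosure measured at establishment) is a legitimate
covariate value and is retained. Zero-variance records (both SDs zero) are
rejected from pooling with an explicit error: infinite weight is never
silently propagated, and the mean/10 imputation rung makes the case
unreachable for real tables.

## Synthetic data

The generator draws, per comparison: a true log ratio
`θ = μ(variable) + β·duration + N(0, τ²)`; a grazed-arm mean from a
log-normal around a per-variable baseline (richness 20 species, Shannon
2.0, biomass 200 g/m² — typical magnitudes for these grasslands), which
guarantees positivity; an excluded-arm mean `Xc·e^θ`; and observed arm
means perturbed on the arithmetic scale with SD `CV·mean/√n`, the noise a
study-level mean inherits from its plot replicates. Arm SDs are reported
as `CV·mean`; one replicate count per comparison serves both arms (a
paired design). Durations come from a discrete mixture concentrated at 0–5
years with a 10% tail at the range maximum, reproducing the many-short /
one-long geometry that makes the longest exclosure influential. Defaults:
13 studies × 1–4 comparisons, durations 0–15 years, n per arm 3–10, CV
0.1–0.4, τ² = 0.05. One PRNG substream is spawned per record from the
table seed, so appending records never perturbs earlier ones and a seed
plus config reproduces a table exactly.

The deterministic `default_paper_fixture` is a hand-constructed 13-study /
27-comparison table (46 variable-level rows: 15 richness, 12 Shannon, 19
biomass, overlapping so that 8 comparisons pair richness with biomass and
only 4 pair Shannon with biomass). It is engineered to the qualitative
surface of published syntheses of these grasslands: exclusion lowers
richness (pooled ≈ −0.15) and Shannon diversity (≈ −0.24 fixed, −0.27
random) and raises biomass (≈ +0.32); I² ≈ 89/95/97%; duration slopes
−0.04, −0.10 and +0.06 per year; and a single 15-year comparison measuring
richness and biomass whose removal flips the richness slope, the biomass
slope and the richness-on-biomass cross-regression to non-significance.
Dispersion routes are 22 reported SDs, 17 SE-derived, 7 mean/10.

What the synthetic data do **not** emulate: real species identities or
community composition, spatial or temporal autocorrelation among
comparisons from one study (records are independent given the config),
non-normal plot-level noise, correlated missingness, or digitization error
from figure extraction. Passing tests therefore demonstrate estimator
correctness and pipeline behaviour under a faithful but idealized sampling
model, not robustness to every pathology of literature-extracted data.

## Numerical choices and verification

Estimators are checked three ways: brute-force plain-Python oracles on
randomized instances (1e-10 relative tolerance for every closed form);
frozen reference values from an independent meta-analysis implementation
(metafor's `rma`, FE / DL / fixed-effect moderator fit, agreement ~1e-10);
and Monte-Carlo recovery of generator truth (fixed- and random-effects
means within 3 MC SEs of μ = 0.4 over seeded replicate ensembles of 27
comparisons; 95% CI coverage within 95% ± 2% at τ² = 0). Monte-Carlo sizes
(300–1000 replicates of k = 27) were chosen so the 3σ bands are a few
times wider than the estimator bias that would matter in practice while
the whole suite stays interactive.

Degenerate inputs fail loudly by design: empty effect sets, non-positive
variances, k below the minimum for τ²/heterogeneity/regression,
rank-deficient designs (constant covariate), exclusion rules matching
nothing or everything, and unmappable category labels all raise typed
errors naming the offending field or row. Output directories holding a
manifest are never silently overwritten.

## Known limitations

- The DerSimonian–Laird estimator and normal-theory CIs are anticonservative
  for very small k with large τ²; Knapp–Hartung adjustments and REML are out
  of scope.
- Comparisons are treated as independent even when one study contributes
  several; no multilevel/robust-variance structure is fitted.
- Publication-bias diagnostics (funnel asymmetry, Egger regression) are not
  implemented.
- The cross-response regression ignores measurement error in the predictor
  LRR (as is conventional, but it attenuates slopes).
- Single-covariate meta-regression only; no interactions or multi-moderator
  models.
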