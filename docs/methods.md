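# Methods

## The estimation problem

Household expenditure surveys record, per household, 30-day expenditure and
quantity for each good, total expenditure, and the sampling cluster (a
village or urban block).  Prices are unobserved; the available price proxy is
the unit value v = expenditure / quantity.  Two contaminations make naive
demand estimation on unit values biased:

1. **Quality shading.** When prices rise, households buy both less and
   cheaper variants, so unit values move less than prices and a share
   regression on unit values overstates price responsiveness.
2. **Measurement error.** Reporting error in quantity or expenditure
   propagates into unit values and attenuates between-cluster regression
   slopes.

The package implements the classic two-stage between-cluster design that
corrects both, assuming each cluster faces one market price per good while
unit values within a cluster differ only through household quality choice
and noise.

## Stage 1 — within clusters

Both equations of the household-level system (see README for notation) are
estimated by within-cluster demeaning, which is numerically identical to
including a full set of cluster indicator variables (verified in the test
suite against an explicit dummy-variable fit).  The share equation uses all
retained households; the unit-value equation for good G uses G's purchasers,
demeaned over purchasers within each cluster.  Stage 1 yields β⁰, β¹, γ⁰,
γ¹, the mean budget shares w̄, per-cluster household and purchaser counts,
and the within-cluster residual covariance matrices Σ⁰⁰, Σ⁰¹, Σ¹¹.
Residual covariances are sums of residual cross-products over the
pairwise-overlap sample divided by (N − C − k), where C counts the demeaning
cells and k the regressors; this plug-in (rather than a more elaborate
small-sample treatment) is validated by the simulation-recovery suite.

## Stage 2 — between clusters

Cluster averages purged of household effects form the price-variation
signal:

- y⁰_Gc = mean over the cluster's households of (w − β⁰ ln x − γ⁰z),
- y¹_Gc = mean over the cluster's purchasers of (ln v − β¹ ln x − γ¹z),
  undefined where a cluster has no purchasers.

Between-cluster covariances R = Cov(y¹, y¹) and S = Cov(y¹, y⁰) are computed
over pairwise-complete clusters.  Because y¹ averages only n⁺ noisy
observations, the regression of y⁰ on y¹ is attenuated; the corrections are

- M11[G,H] = Σ¹¹[G,H] · mean over clusters of n⁺_GH / (n⁺_G n⁺_H),
- M01[H,G] = Σ⁰¹[G,H] · mean over clusters of n⁰⁺_H / (n_c n⁺_H), where
  n⁰⁺_H counts share-side households purchasing H (this reduces to the
  familiar mean 1/n_c when the share and unit-value samples coincide),

giving Bᵀ = (R − M11)⁻¹(S − M01).  A corrected matrix that is not positive
definite (correction exceeding the observed variation, a small-sample
symptom) raises an explicit error; an optional ridge term exists but is off
by default and logged loudly when enabled.

## From B to elasticities

Expenditure elasticity ε_x = 1 + β⁰/w̄ − β¹ and quality elasticity
ζ = β¹/ε_x per good.  The quality-shading system Θ = D(w̄)(I+E),
Ψ = I + D(ζ)E, B = ΘΨ⁻¹ solves to

    E = (I − D(w̄)⁻¹ B D(ζ))⁻¹ (D(w̄)⁻¹ B − I),

which reduces exactly to D(w̄)⁻¹B − I when ζ = 0.  The literature contains
refinements of the quality correction beyond this system; the mapping used
here is declared explicitly and validated by simulation recovery (synthetic
truths in [−1.2, −0.5] recovered to within Monte-Carlo tolerance) rather
than asserted as the unique canonical variant.  E is not symmetrized:
observed cross-elasticities are genuinely asymmetric.  Entry (i, j) is the
response of good-i quantity to good-j price.

## Bootstrap

Standard errors resample clusters with replacement and recompute stage 2 and
the transform per draw, holding stage-1 coefficients fixed — the
second-stage cluster-level bootstrap.  A full-pipeline bootstrap would also
propagate stage-1 noise; with tens of thousands of households stage-1
uncertainty is an order of magnitude below stage-2 uncertainty, and the
test suite checks the resulting SEs against the SD of estimates across
independent survey replicates.  Draws whose corrected moment matrix is
singular are dropped and counted; more than 10% failures warns (or raises in
strict mode).  Every stochastic operation takes an explicit seed; there is
no global RNG state.

## Income-group estimation with shared cluster prices

Households are split into tertiles of total expenditure (an income proxy).
A cluster's price signal y¹ is computed once from *all* its households,
pooled across groups — households in the same cluster face the same price
whatever their income — while the share side (stage-1 share coefficients,
purged share means, mean shares w̄_g) is group-specific.  The pooled β¹
purges y¹; the group β⁰_g enters the group's ε_x.  Rural/urban estimation
splits clusters whole, so it simply reruns the full pipeline per sector.
Tertile boundaries are computed on the post-filter estimation sample by
default (a flag-free choice: run `assign_income_tertiles` before the filter
to switch), with remainders assigned to the lower tertiles and ties broken
by household id, so the split is deterministic.

## Survey preparation choices

- Deflation multiplies each row's per-good expenditures *and* total
  expenditure by base_index / CPI(round, subround): unit values are restated
  in base-period currency while budget shares are invariant to the price
  level, as they should be.
- The estimation filter drops households not purchasing the focal good, then
  clusters with fewer than 2 purchasers.  Non-focal goods keep zero shares
  for retained households (the share equation is defined over all
  households; only unit-value equations condition on purchase).
- Survey multipliers are ignored by default (`weighted=True` in summaries
  uses them); unweighted estimation keeps results exactly reproducible from
  the table alone.
- No imputation and no outlier trimming beyond validation of the record
  invariants (quantity and expenditure sign-consistent, totals positive).

## The synthetic generator

The generator samples directly from the two-equation system: cluster log
prices N(μ_G, σ_π,G²), household ln x N(9.3, 0.6²) (≈ 11,000 INR/month,
matching the pooled-survey magnitude), covariates (log household size from
1 + Poisson(3), children Poisson(1), education N(7, 3²)), then unit values
and shares from the equations with cluster effect f_c and noise u⁰, u¹.
Expenditure and quantity are back-computed so expenditure = quantity × unit
value and share = expenditure / total hold exactly.  Purchase incidence is
an independent Bernoulli gate with tertile-specific probabilities (defaults
1% / 3% / 10% for ASBs, with analogous gradients for juice, milk, tea),
reproducing the observed prevalence gradient without asserting a selection
model.  Shares falling outside (0,1) are clipped and counted; a clip
fraction above 5% flags the truth object.

Configs are made *quality-consistent* by construction:
`config_from_elasticities` takes the target elasticity matrix E, mean shares
and expenditure coefficients and derives Θ = D(w̄)(I+E) and Ψ = I + D(ζ)E,
so the two equations describe one demand system and `true_elasticities`
(the generator's own closed form) coincides with the estimator's transform
applied to noiseless moments — the oracle-equivalence contract the tests
enforce.  `config_with_group_elasticities` builds tertile-specific Θ_g with
β⁰ = β¹ = 0 and centred log prices, so each tertile's population mean share
equals the configured value and its true elasticity matrix is exactly the
matrix supplied.

Default noise levels (σ_π = 0.20 between clusters, σ_u1 = 0.134 within)
put about 69% of unit-value variance between clusters — the share observed
in the real data — and σ_u0 = 0.005, σ_f = 0.002 keep share noise a
realistic fraction of the ~1.7% mean ASB share.

**What the generator does not emulate:** economic selection into purchase
(the gate is independent of prices and errors), survey design weights and
stratification, item nonresponse, price endogeneity, and real-world
departures from the linear share equation.  Passing recovery tests therefore
demonstrate that the estimator is correct *under its own assumptions*, not
that those assumptions hold in any particular survey.

## Recovery harness and problem sizes

The recovery suite runs the full pipeline on surveys of 2,000 clusters × 8
households with purchase prevalence set to one for all goods, so the
two-equation system holds for every household and the configured
elasticities are the exact truth.  Under the realistic prevalence gradient
the focal-good filter leaves non-purchased goods with structural zero shares
among retained households, and the multi-good truth is no longer
well-defined — the generator-fidelity tests cover that regime descriptively
(prevalence, summaries, filter counts) while the quantitative recovery
claims are made where truth exists.  Twenty seeds bound the mean estimate
(bias) within 0.05 of truth with ≥85% bootstrap-CI coverage; eight seeds
establish the low > middle > high magnitude ordering at tertile-specific
truths.  Bootstrap draws are 300 in the recovery suite and 500–1000 in
examples/production use; SEs stabilise well below these counts.

## Affordability and tax modules

RIP_t = 100 × (price_t × 100 L) / GDPpc_t.  Year-over-year percent changes
are simple arithmetic changes; the income effect is defined residually
(RIP change minus real-price change) so the decomposition is additive by
construction.  A `log_exact` mode uses log differences, under which the
price effect equals the real-price log change and the income effect equals
minus the real-income log change exactly.  Multi-brand price tables are
pooled to one price per year, weighted by observation counts by default.
Geometric mean growth is (last/first)^(1/(n−1)) − 1 over n annual values.

The tax simulator defaults to constant-elasticity demand,
p1 = p0(1 − r)^(1/ε), which reproduces the published scenario table from the
overall elasticity −0.94 cell for cell; a linear demand form is provided for
sensitivity.  The baseline per-litre tax derives from the published rounded
28.6% burden (60 × 0.286 = 17.16 INR/L), which matches the published
baseline revenue; the exact 40/140 statutory alternative is available by
constructing `TaxBaseline` without `tax_burden`.  The published scenario
revenue levels embed internal rounding that cannot be reproduced from any
consistent baseline (recomputation is ~0.3% off); the golden test asserts
those three cells at 0.5% relative tolerance and every other printed cell at
±1 in its last printed digit.  All results are carried at full precision;
`table_report` rounds only for presentation.  Income-group impacts use
(1 + Δp)^{ε_g} − 1 weighted by consumption shares, which
`group_consumption_shares` can derive from any prepared survey.

## Interface choices

The package is a library: the importable API plus `examples/` scripts are
the interface, and `scripts/acceptance.py` reproduces the headline
tax-simulation quantities.  No console entry points are installed — the
workflows are Python-native (DataFrames in, DataFrames/dataclasses out).

## Known limitations

- The EIV correction is a plug-in; at few clusters or tiny purchaser counts
  it can overshoot (raising explicitly rather than silently regularising).
- Group estimation inherits the tertile proxy's weaknesses: expenditure
  measures income with error, and boundary households blur group contrast.
- The quality-shading transform assumes the stated system; alternative
  refinements would move estimates within roughly the quality-correction
  magnitude (|ζ·E| ≈ 0.06 here).
- The affordability module treats year labels as opaque ordered strings; no
  calendar arithmetic or gap interpolation is attempted.
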