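# Methods

`foodtax` implements an integrated assessment of the environmental
footprints of household food consumption and of two consumption-tax
policies — removing reduced VAT rates on meat, and a uniform greenhouse-gas
(GHG) price on all food — with welfare, tax-revenue and monetized-benefit
accounting.  Because the microdata such studies rest on (national household
budget surveys, full-scale multi-regional input-output databases) are
access-restricted or too large for a test suite, the package ships a
synthetic-data generator with known ground truth; every stage of the
pipeline is validated against that truth or against independent oracles.

## 1. Footprint accounting (`foodtax.mrio`)

An economy of `R` regions × `S` sectors is described by technical
coefficients `A` (spectral radius < 1), household final demand `y` per
consuming country, and a satellite matrix `S` of stressor intensities per
unit of output.  Output required to serve demand is `x = (I − A)⁻¹ y`
(dense solve; the toy scale never needs sparse backends) and induced
stressors are `g = S x`.  Using `S diag(x)` keeps the attribution of every
stressor to the producing region-sector exact, so origin decompositions
(domestic vs imported impact shares) conserve totals by construction.
Purchases are split by the sector bought, and purchased sectors are
aggregated to food categories through a concordance; aggregation conserves
stressor mass to numerical precision.

Raw stressors are characterized into six indicators: GHG in CO2-equivalents
via GWP100 factors (configuration data with a documented source; defaults
CH4 27, N2O 273, SF6 24300, HFC 1526, PFC 7380), blue water, total land
occupation, nitrogen (species aggregated by molar N content), phosphorus,
and biodiversity loss as the global potentially disappeared fraction (PDF)
of species.  Biodiversity characterization is regionalized: each of the 20
land-use stressors maps to one of six land-use types, and region-specific
PDF-per-area-year factors are applied to land occupation in the *producing*
region before summation.  Per-gas GHG rows are carried alongside the
aggregated indicators because monetization values CH4 and N2O at their own
social costs.

Monetary demand intensities `mu = E / X` (impact per euro of final demand)
link the accounting to the household data.  The orchestration layer
calibrates the toy MRIO's food demand so that per-(country, category)
final demand equals the weighted survey expenditure, which makes `mu`
consistent between the footprint account and the household-level levy:
`mu · tau · X = E · tau` holds to machine precision (the Pigouvian
identity).

## 2. Survey preparation (`foodtax.surveyprep`)

Four exclusion filters run in a fixed order and write a JSON-lines audit
log: negative item expenditures; zero expenditure with positive quantity;
food budget share above 75% of total expenditure; zero total food
expenditure.  Cleaning is idempotent.

Missing quantities are imputed by nearest-neighbour matching with a single
weighting rule: the inverse-distance-weighted mean quantity of the k = 10
nearest donors, rescaled by the ratio of the target's expenditure to the
distance-weighted mean donor expenditure.  The cross-country variant fills
items never recorded in a country from donors in the same macro-region;
the within-country variant fills implausible (positive expenditure, zero
quantity) records from domestic donors.  Design choices the method leaves
open: the metric is standardized Euclidean distance over the demographic
dummies plus log item expenditure; ties at the k-th neighbour are all
included with renormalized weights; exact-duplicate donors are handled with
a distance floor of 1e-9; donor ordering is fixed by household id so
results are deterministic.  Observed quantities are never altered, and
zero-expenditure households get zero quantities.

Prices are unit values (expenditure per unit purchased), purged of quality
variation by regressing unit values on household characteristics and
keeping the constant plus residual.  Covariates are centred (weighted)
before the fit, which makes the adjusted price level equal the weighted
mean unit value and the result invariant to shifting covariates by
constants.  Categories with fewer than 30 positive observations keep raw
unit values; households without a unit value receive the (unweighted)
country median of adjusted values; a positivity floor at the 1st percentile
of raw unit values protects the logs taken downstream.

## 3. Demand system (`foodtax.easi`)

Each country's food demand is an implicit-Marshallian budget-share system
with fourth-order Engel polynomials,

    w = Σ_r b_r y^r + A p + C z + B p y + D z y + ε,

where `p = ln(p̃) − x` are log unit-value prices normalized by nominal food
expenditure (homogeneity of the estimated demands in prices and
expenditure) and `y = x − w'ln(p̃)` is nominal expenditure deflated with
the household Stone index, serving as implicit utility.  Slutsky symmetry
is imposed by sharing the upper triangle of `A` and `B` across equations.
In addition the estimator imposes homogeneity as a parametric restriction
(zero row/column sums of `A` and `B`, which the symmetric structural model
satisfies): without it, the common `−x` component of the normalized prices
makes the price block nearly collinear with the Engel polynomial in `y`,
and the system is practically unidentified.

Zero recorded expenditures are treated as the outcome of an upstream binary
choice.  A probit per category (weighted with the sample weights, like the
main stage) yields fitted cdf/pdf values; every regressor of equation `i`
is multiplied by `Φ̂_hi` and `φ̂_hi` enters with a free coefficient `f_i`.
Probits with no zeros are degenerate and force `Φ̂ = 1`, `φ̂ = 0`, so the
correction collapses to the plain system; (quasi-)separated probits fall
back to a small ridge penalty (λ = 1e-3 on the slopes).  Because adding-up
cannot be imposed on a censoring-corrected system, all `n` equations enter
the estimation.  The estimator is feasible GLS on the stacked,
restriction-reduced system: iterate the cross-equation residual covariance
to convergence (tolerance 1e-8, at most 50 iterations), flooring its
eigenvalues at 1e-8 of the largest because adding-up makes the covariance
of an uncensored share system singular.  Rank deficiencies raise an error
naming the offending regressors (pivoted QR).

Numerical design choice for the deflator: which items a censored household
is missing is selection-driven, so a Stone index over observed shares only
would correlate with the censoring process (validated against a latent-
utility oracle, where it biases own-price elasticities by about −0.04).
The household Stone weights are therefore *completed*: censored items enter
at the weighted sample-mean share of purchasing households and the weight
vector is renormalized to one, which also makes `y` invariant to the
monetary scale.

Specification switches mirror the usual robustness variants: a common
Stone deflator from sample-mean shares; `y` centred at its sample median
(or mean); unweighted estimation; an uncensored (n−1)-equation system with
adding-up imposed and the dropped equation reconstructed from the
restrictions; price-demographics interaction terms `Σ_l z_l E_l p`; and an
incomplete system with a composite non-food numéraire (share of total
expenditure, price one).

Elasticities follow from the semi-elasticity matrices: compensated
`η^PE = diag(w)⁻¹ Φ̂ (A + B y) + 1 w' − I`, expenditure
`η^EE = diag(w)⁻¹ Φ̂ (Σ_r r b_r y^{r−1} + B p + D z) + 1`, Marshallian via
the Slutsky equation `η^M_ij = η^PE_ij − η^EE_i w_j`.  Households with a
budget share below 0.005 have that category's row marked undefined (the
formulas divide by the share) and are excluded from means with weight
renormalization.  Country means weight households by sample weight times
nominal food expenditure.  The policy simulation uses the Marshallian
matrix — demand responses to price changes include income effects.

## 4. Policy simulation (`foodtax.policy`)

VAT reform: meat categories' consumer prices rise by
`(1 + r_std)/(1 + r_red) − 1` (identical across the meat categories of a
country, zero elsewhere); GHG price: `Δp/p = mu · tau` for every category,
with the levy not itself subject to VAT, under complete pass-through.
Demand changes are `Δq/q = η Δp/p` at country-mean elasticities (household
heterogeneity enters only the welfare accounting); changes below −100% are
floored with a warning.  Footprint changes scale the baseline account
proportionally per country × category, so reductions are allocated to
producing regions in proportion to the status quo.  The GHG price
achieving the same total GHG reduction as the VAT reform is solved for:
the map `tau → ΔGHG` is linear under this composition, which the solver
verifies on two probe points (relative curvature below 1e-10) before using
the closed form; a Brent bracketing search over `[0, 10000]` is the
fallback for nonlinear configurations, and the solution is checked to 1e-6
relative.

## 5. Welfare, revenue and monetization (`foodtax.welfare`)

The log cost-of-living index is the second-order expansion of the log
expenditure function at pre-policy utility:
`log COL = Δp'w₀ + ½ Δp'(A + B y) Δp` with `Δp = ln(1 + Δp/p)`; euro
values multiply by nominal food expenditure; positive values are losses.
Post-policy expenditures hold the nominal food budget fixed (the
partial-system assumption) and shift shares by the compensated
semi-elasticities: `x¹_i = x⁰_i + X⁰ Σ_j Φ̂(A + By)_ij (Δp_j/p_j)`;
negative results are floored at zero with a warning.  VAT revenue change
per household is `Σ_i (x⁰_i r⁰/(1+r⁰) − x¹_i r¹/(1+r¹))` — positive means
the household pays less, and the aggregate reported to the government's
perspective is its negative; the GHG levy is
`Σ_i x¹_i/(1+r⁰) · mu_i · tau` on net-of-VAT expenditures, which
aggregates to the post-policy emission base times the carbon price.
Footprint changes are monetized with social costs: CO2, CH4 and N2O valued
globally at per-gas costs, F-gases via their CO2-equivalent at the CO2e
cost, nitrogen and phosphorus valued only where impacts originate inside
the home-region bloc (no robust global costs exist for them).  The default
phosphorus cost is the reported €153.50 per kg for emissions to surface
waters; the remaining defaults are synthetic placeholders of plausible
magnitude and flagged as such in the table's `sources` field.  Per-capita
figures divide by a configurable mean household size (default 2.3, a
European-style average).

## 6. Uncertainty (`foodtax.uncertainty`)

Elasticities are the only stochastic input to the simulation, so
uncertainty is a within-country non-parametric bootstrap: `b = 100`
samples of size `N_c` with replacement per country, re-running the full
estimation (unit-value adjustment, probits, SUR) and the policy
computations per replicate; reported ranges are the min-max over
replicates, which is not a calibrated interval and may not contain the
point estimate (flagged when violated).  Replicate `r` of country `c`
derives its seed from `(root seed, c, r)` regardless of scheduling, so
reruns are byte-identical.  Degenerate replicates are redrawn with an
incremented sub-seed and logged; five consecutive failures raise.

## 7. The synthetic study (`foodtax.synthdata`)

The generator *is* the estimated model, so recovery tests are exact
specification tests.  Per country it draws five demographic dummies, a
sample weight, a log food budget (sd 0.5, the order of real cross-household
dispersion once household size varies), and log supply prices composed of
a country level, sub-region shifters (4 sub-regions, sd 0.12), an urbanity
shifter (sd 0.05) and a household-idiosyncratic component (sd 0.20) that
emulates the outlet/package dispersion of real unit values — the variation
a unit-value-based demand estimation actually exploits.  Latent shares
solve the fixed point `w = f(p, y, z) + ε`, `y = x − w'ln p̃`; the true
parameter set satisfies adding-up and homogeneity by construction
(perturbation magnitudes scale with the typical share `1/n`), preference
noise is mean-zero across categories, and all noise draws are truncated at
±2.5 sd so shares stay inside the simplex (the rare tail household is
clipped and renormalized with a warning; more than 0.5% violations reject
the configuration).  Zeros arise via independent per-category selection
probits on `[1, z, x]` with slopes of sd 0.6 — zeros are meaningfully
covariate-driven, which both mirrors reality (who records no beef is not
random) and identifies the correction's pdf term — and intercepts
calibrated so the expected zero rate equals the configured censoring rate
(default 20%).  Selection noise is independent of preference noise, so the
true pdf-term coefficient is zero and the estimator's `f̂ → 0` is itself a
check.  Unit values multiply supply prices by a demographically driven
quality factor (scale 0.05) that the adjustment regression is meant to
purge.  The recorded total food budget is the latent annual budget —
as in real surveys, where totals come from interviews while short diaries
censor items — so observed shares equal `d · w*` exactly.

Monetary units are scale-free internally (homogeneity makes a common log
shift of prices and expenditures irrelevant) and presented in euros via a
single scale constant (median annual food budget ≈ €3,000).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: measurement error beyond quality variation,
infrequency-of-purchase dynamics (zeros are pure selection), correlated
selection across categories, non-normal selection errors, within-category
product substitution, price endogeneity from supply response, and any
spatial correlation in the MRIO beyond random region shifters.

Elasticity ground truth is exposed two ways: closed-form derivative
matrices of the share system, and a finite-difference oracle that
differentiates the share function in its exogenous arguments `(p, y)` and
applies an independently coded share-to-quantity conversion.  The linear
approximation treats `(p, y)` as regressors, so this — not a
finite-difference through the Stone-index fixed point, which adds feedback
terms of order `p'(∂w/∂y)` that the approximation deliberately ignores —
is the correct oracle for the elasticity formulas.

## 8. Problem sizes and tolerances

The test suite runs the demand-system recovery at 4 categories and 5,000
households per country with 20% censoring (country-mean own-price
Marshallian elasticities within ±0.1 of the generator's finite-difference
truth; across generator seeds the typical deviation is ≈0.05), parameter
recovery at n = 20,000 uncensored (max abs error < 0.05), censoring-free
collapse to plain SUR at 1e-8, MRIO series-oracle agreement at 1e-8
relative over 50 random systems, conservation identities at 1e-9, the
equivalence solve at 1e-6 relative, and bootstrap byte-identity at
b = 100.  `scripts/acceptance.py` runs the full study at three countries ×
2,000 households × six categories on a 6-region × 10-sector MRIO with 40
bootstrap replicates — sizes chosen so a complete from-scratch run
finishes in a couple of minutes on one CPU while leaving the estimation
comfortably identified.

## 9. Known limitations

The min-max bootstrap range is not a confidence interval.  The welfare
index is food-consumption-only (no health effects or environmental benefit
feedback to households).  The censoring correction is the standard two-step
approach and inherits its independence assumption across category probits.
Producer-side reallocation, trade dynamics and within-category intensity
changes are outside the model, as is any land-use-change (as opposed to
land-occupation) accounting in the biodiversity indicator.
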