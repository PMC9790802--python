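# Methods

## The mixing model

The package's core assumption is ideal volumetric mixing: a sediment
sample of unit dry mass with organic-matter proportion `O` occupies the
volume of its organic part at the self-packing density of pure peat `δp`
plus the volume of its mineral part at the self-packing density of pure
mineral sediment `δm`. Bulk density is therefore the harmonic mix

    1/δ = O/δp + (1 − O)/δm   ⇔   δ(O) = δp δm / (δm O + δp (1 − O)),

bounded by `δp ≤ δ ≤ δm` and strictly decreasing in `O`. Organic matter is
tied to elemental carbon fraction `C` by a conversion factor `f`
(`O = f C`, valid domain `C ∈ [0, 1/f]`). Carbon density is
`D(C) = C · δ(fC)`, strictly increasing from 0 to `δp/f`.

Differentiating `D` gives `dD/dC = δ(C)²/δm`, where `δ(C)` is the
model-predicted bulk density. A variant with `δp` in the denominator
circulates in the applied literature; the `δm` form is the one that
matches central finite differences of `D`, and the package's tests enforce
exactly that (relative tolerance 1e−6 on 100-point grids for three
parameter sets). Either form supports the same qualitative conclusion —
the slope collapses as sediment becomes peatier.

Parameter defaults are `δp = 0.085`, `δm = 1.65` g cm⁻³ and `f = 2.2`
(≈45% carbon in organic matter): conservative consensus values for
coastal wetland sediments. All carbon fractions are proportions
internally; percentages are accepted only at the I/O boundary with an
explicit flag, and `f·C > 1` beyond 1e−9 is an error rather than a clamp,
so percent-vs-proportion mistakes fail loudly.

Corer segment volumes follow from geometry at full precision (cylinder,
half-cylinder, constant cross-section, rectangular prism); the standard
instruments give 11.35, 42.41, 26.43 and 27 cm³. (A published figure of
26.46 cm³ for the 8.81 cm² × 3 cm constant-area corer is not reproducible
from its own stated geometry; we compute 26.43 from the geometry.)

## Estimating δp and δm

`fit_mixing_model` minimises Σ(δ_obs − δ(C; δp, δm))² by Gauss–Newton with
analytic Jacobian

    ∂δ/∂δp = δm² f C / A²,   ∂δ/∂δm = δp² (1 − fC) / A²,   A = δp(1−fC) + δm fC,

step-halving (up to 20 halvings) whenever a full step would increase the
residual sum, a positivity floor of 1e−6 on both parameters (logged when
hit), and convergence when the relative change in SSres falls below 1e−10
or the step norm below 1e−8. Default initialisation is (0.1, 1.6), inside
the plausible range for any coastal sediment; non-convergence after 100
iterations is flagged on the result, never silent. `f` is held fixed
during the fit — it is estimated separately from LOI calibration data, and
co-estimating it is confounded with `δp` (only the product `fδp`-shaped
combination is well identified near the peat end).

Standard errors use the linearised-model formula `σ̂²(JᵀJ)⁻¹` with
`σ̂² = SSres/(n−2)`. This assumes iid errors; under strongly
heteroscedastic (e.g. multiplicative) noise the point estimates remain
consistent but the SEs are miscalibrated — verified directly in
simulation, where 3-SE coverage is ~99.7% under additive iid noise and
degrades under 10% multiplicative noise. That caveat is itself part of the
package's subject matter.

Fit quality is summarised by a pseudo-R² (1 − SSres/SStot) and a
lack-of-fit test: with replicate groups (site × depth strata when a
hierarchy exists, otherwise carbon-fraction bins of configurable width,
default 0.005), pure error is the within-group SS around group means and

    F = [ (SSres − SSpe) / (g − 2) ] / [ SSpe / (n − g) ].

The decomposition SSpe + SSlof = SSres is exact. Under the true model with
iid noise the test's type-I error is nominal (measured 0.049 at α = 0.05
over 1000 simulated surveys); against a linear truth its power at n = 100
is ~1.

`calibrate_conversion_factor` regresses LOI on carbon fraction by OLS
*with* intercept (statsmodels); the slope estimates `f` and the intercept
is reported as a diagnostic. A through-origin fit is equally defensible;
the intercept form was chosen because a nonzero intercept is itself
evidence of LOI bias (structural water, carbonates) worth surfacing.

## Corer comparison

Instruments are matched on site × depth strata (not raw depth in cm —
corers cut slightly different ranges, and raw matching would empty the
overlap). For each pair with ≥3 matched strata the package reports the
Pearson correlation and the major-axis slope through the origin

    b = [(Syy − Sxx) + √((Syy − Sxx)² + 4Sxy²)] / (2 Sxy)

with uncentred sums — the symmetric regression appropriate when both
variables carry error — plus a delete-one jackknife SE
(√((n−1)/n · Σ(b₍ᵢ₎ − b̄)²)) and a two-sided t test of b = 1 with
df = n − 1. Major-axis slopes are invariant to common rescaling of both
axes but not equivariant under one-axis rescaling (the perpendicular
objective is not scale-free); tests assert only the true versions of these
properties. `Sxy = 0` (orientation undefined) is an error.

The sequential variance decomposition credits the nonlinear stage with
SStot − SSres, then regresses the running residuals on each factor's
dummies in a configurable order (default: instrument, site, location,
depth), taking the drop in residual SS as that factor's share — type-I
style, order-dependent, but exactly additive by telescoping, so percents
sum to 100. Rank-deficient factors contribute zero, logged rather than
raised.

The replicate-consistency comparison treats the instruments that sampled a
stratum as replicates: each bulk-density estimator (gravimetric vs
carbon-based) is decomposed one-way by stratum, and the within-stratum
mean squares are compared by a variance-ratio F (reported in the
user-given order, two-sided p). Singleton strata contribute no within-SS
and no degrees of freedom.

The heteroscedasticity diagnostic correlates squared residuals with fitted
values and reports `F = r²(n−2)/(1−r²)` on (1, n−2) df — a funnel of error
growing with predicted carbon content shows up as a significantly positive
r.

## Error propagation and the Monte Carlo

For the gravimetric estimator `D = C·δ` with independent measurement
errors, the exact product variance
`V = E(δ)²V(C) + E(C)²V(δ) + V(C)V(δ)` implies absolute error roughly
proportional to `D` itself. For the carbon-only estimator the first-order
delta method gives `V ≈ (δ(C)²/δm)² V(C)`, which *falls* with carbon
content. The Monte Carlo makes both concrete: true carbon levels on a grid
(default 40 levels on [0.005, 0.40]), multiplicative Gaussian errors
(relative SD 0.10 on both measurements by default — a realistic
field-plus-lab error magnitude; "normalized" relative error is the natural
reading for measurements spanning two orders of magnitude of bulk
density), measured values truncated at zero and measured C clamped to the
assumed parameters' domain, with truncation/clamp counts reported because
silently dropping draws would bias means. Runs are bit-reproducible per
seed.

Two deliberate subtleties, both verified in tests:

- The *per-level SD* of the gravimetric estimator is a strictly increasing
  function of C in theory, but adjacent high-C levels differ by <0.2%
  while an SD estimated from 250 replicates carries ~4.5% noise, and the
  domain clamp slightly deflates the very top levels. Rank-correlation
  checks of the funnel therefore use 20 000 replicates per level, where
  the measured Spearman ρ is ≈0.94 (and ≈0.81 at 250).
- The mixing estimator has a second-order (curvature) bias of order
  ½D″(C)·V(C), invisible at small noise but detectable at cv = 0.10 with
  large replication; unbiasedness checks run in the small-noise regime
  where first-order theory applies.

`bias_probe` quantifies parameter-misspecification bias: with assumed
(δp, δm) at the upper limit of reported values (0.10, 2.00) against a true
(0.09, 1.75), the carbon-only estimator is precisely wrong — ~+11% at
C = 0.40 — with sign matching the analytic difference of the two
carbon-density curves.

## The synthetic survey generator

The generator emulates a small bay-scale campaign: 3 locations with 7
sites nested in them (random blocks), shallow/mid strata everywhere plus a
deep stratum at two penetrable sites, and four instruments with
per-stratum availability (the constant-area corer refuses wet sand with
probability 1/8; spade cubes only at the shallow stratum of 6 of 7 sites).
Expected yield ≈52 samples. Per site × depth one true carbon fraction is
drawn from a two-component Beta family on [0, 1/f] — carbon-poor for
mineral sites, carbon-rich for peaty ones — so organic-content-dependent
dispersion is visible at survey scale. True bulk density is the mixing
curve plus small *additive* site (−0.05 g cm⁻³ at one clayey site) and
instrument (+0.03 for the soil probe and spade, which compact or include
coarse material) offsets; additive rather than multiplicative because
instrument artefacts act on the packed mass in the barrel, not
proportionally to density. Measurement error is multiplicative (cv 0.10)
on bulk density and additive (SD 0.005) on carbon fraction, with an
optional relative carbon-error component for experiments that need a
CV-to-CV comparison between the two measurement channels. Dry mass is
back-computed as measured density × corer volume, so CSVs round-trip
measured bulk densities bit-for-bit (written at 17 significant digits,
parsed with round-trip float precision).

What the generator does **not** emulate — and what passing tests therefore
do not establish about field data: natural within-stratum heterogeneity
beyond measurement noise (replicate cores centimetres apart differ for
real), depth autocorrelation within a core, compaction gradients,
carbonate interference in LOI, or spatial structure between sites. One
visible consequence: because the injected corer/site offsets are genuine
departures from the pure mixing curve and there is no extra field scatter
to absorb them, the lack-of-fit test on default synthetic surveys tends to
*reject* — correctly for these data — whereas a field survey with larger
pure error can fit the same curve without detectable lack of fit.

Offsets that could drive bulk density to zero or below are rejected at
spec construction. With zero noise and zero offsets, the full pipeline
recovers the generating parameters exactly (to 1e−6), which anchors the
estimation code end to end.

## Problem sizes and numerical choices

Test and reproduction runs are sized for a laptop: the lack-of-fit
calibration uses 1000 simulated surveys of n = 60; parameter-recovery
coverage uses 200 fits of n = 500; the product-variance check uses 10⁶
draws; Monte Carlo trend checks use 40 levels × 20 000 replicates
(800 000 draws, a few seconds). The whole suite runs in well under a
minute. Ties and degenerate inputs (constant responses, unreplicated
groups, zero cross-products, singular Jacobians) raise informative errors
rather than returning NaNs.

## Known limitations

- No errors-in-variables or weighted fitting: the Gauss–Newton SEs assume
  iid errors (see above). Robust/Bayesian variants are out of scope.
- The variance decomposition is sequential (order-dependent); it mirrors
  the residual-analysis workflow, not a REML mixed model, and location/
  site random effects are treated as fixed factor dummies.
- The per-hectare stock helper is display-only arithmetic; depth
  integration of carbon stocks is outside the estimation machinery.
- The conversion factor f is treated as known during fitting; its
  calibration uncertainty propagates into δp̂ only through the user
  re-running the fit at alternative f values.
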