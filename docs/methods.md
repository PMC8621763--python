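# Methods

## Dose–response model

The package models the lifetime probability of an adverse noncancer health
effect (PrHE) for a dose expressed as a fraction *x* of the chemical's
ED50 as the cumulative lognormal distribution of toxicological
susceptibility:

    PrHE(x) = Φ( log₁₀(x) / σ_log )

This is evaluated in closed form rather than by numerical integration of
the equivalent lognormal density — the two are mathematically identical,
and the closed form is exact and fast. The quadrature route is retained in
the test suite as an independent oracle (relative agreement < 10⁻⁸ over
x ∈ [10⁻⁴, 1]). PrHE(0) is defined as exactly 0 by continuity; the density
is singular at the origin in log space. The inverse and the derivative
(marginal slope) are also closed-form:

    x(p) = 10^(σ_log · Φ⁻¹(p)),
    dPrHE/dx = φ(log₁₀(x)/σ_log) / (σ_log · x · ln 10).

**σ_log** (unitless, in log₁₀-dose units) defaults to 0.26, the central
tendency of the spread of human susceptibility; it is a configurable
parameter because other populations or endpoints may warrant other
spreads. Under this default, ED10 — the dose with a 10% response — sits at
46.4% of ED50.

**Tail handling.** The sigmoid is extraordinarily steep in log space at
screening-level exposures: risks of 10⁻²⁰…10⁻⁷⁰ are routine. Every risk
result therefore carries a `log10_prhe` field computed from the normal
log-CDF (`norm.logcdf`), which stays finite and correctly ordered far
below the smallest representable double; the linear-scale `prhe` field
underflows to 0 in that regime. A corollary used throughout the tests:
comparisons against printed tail values must be multiplicative (a factor),
never absolute — a 0.2% perturbation of x (3-significant-figure rounding)
moves a 10⁻¹⁸ tail value by ~10%.

## Interval segmentation

The working risk range is PrHE ∈ [p_min, p_max] = [10⁻⁶, 0.10]: below
p_min risk is treated as negligible, and p_max is the ED10 anchor, the
upper limit of environmentally plausible risk. The segmentation launches
a tangent at x(p_min) — not at 0, where every derivative of the curve
vanishes — and ends the current interval at the smallest dose where

    PrHE_nonlinear(x) / PrHE_tangent(x) = discrepancy_factor  (default 5).

The discrepancy is measured as nonlinear ÷ linear because on this convex
span the curve outruns its tangent from above; the factor of 5 reflects
the typical magnitude of uncertainty factors in toxicity assessment. The
ratio criterion is solved with Brent's method (xtol 10⁻¹², far tighter
than the ~10⁻⁵ at which boundary positions stabilise). The final boundary
is x(p_max). With defaults exactly four intervals result, with boundaries
at 8.9%, 15.1%, 32.7% and 46.4% of ED50. The published reference values
for the same construction are 9.0%, 15.3%, 33.4% and 46.4%; the first two
and the last agree to printed rounding, while the third computes to 32.7%
under exact tangents (the discrepancy ratio at 33.4% is 5.05, not 5.00).
The package reports the exactly-computed boundaries and additionally
packages the published rounded table (below) verbatim.

For reporting, each interval is replaced by its **secant**: segment 1 is
anchored at the origin (X₀ = 0, R₀ = 0) so the whole exposure range is
covered, and segment k ≥ 2 runs between consecutive boundaries with slope
[PrHE(b_k) − PrHE(b_{k−1})]/(b_k − b_{k−1}) and base R₀ = PrHE(b_{k−1}).
Convexity of PrHE up to the ED10 dose guarantees the secants never
under-predict — a deliberately conservative property for risk screening.
The maximum over-prediction is bounded per interval (dense-grid search,
≥ 10⁴ points with bounded local refinement): ≈ 173% over intervals II and
III and ≈ 9% over interval IV; over interval I the secant-to-curve ratio
diverges as x → 0 but falls below one order of magnitude above 6.3% of
ED50. For comparison, the conventional single slope through the ED10
point overestimates the nonlinear risk ≈ 7000-fold at that same dose.

**Piecewise evaluation** treats spans as half-open (x_start, x_end] —
numerically irrelevant because adjacent secants meet at shared endpoints,
but fixed for determinism. Doses beyond x(p_max) fall back to the
nonlinear model with a warning rather than extrapolating the last slope:
the linearization was constructed only up to the ED10 anchor.

**Two tables.** `build_segment_table()` recomputes the table at full
precision; `reference_segment_table()` returns the published rounded
four-interval table (slopes 0.00031/0.013/0.18/0.51, bases
0/0.000028/0.00085/0.034). The incremental-emission workflow and the CLI
default to the published table, because that lookup table *is* the
published procedure's reference artifact (its worked scenario,
X = 0.279 → 2.35 × 10⁻², is reproduced exactly only with the rounded
parameters); `--computed` switches to the full-precision table.

## Aggregation and the incremental-emission workflow

Route-specific exposures combine as X_inh/ED50_inh + X_ing/ED50_ing;
chemicals combine by summing those combined fractions (dose-additivity of
ED50 fractions — implemented as specified, though toxicological similarity
of the mixture is an assumption, not a derivation). When only one route
has a characterized ED50 the other route borrows it, with a warning —
the usual cross-route extrapolation practice. Risks are then a single
model evaluation of the summed fraction.

The incremental-emission workflow assumes the average daily dose scales
linearly with emission rate: incremental fraction = background fraction ×
(incremental emission / background emission), total = background +
incremental, risk = piecewise table lookup. A zero background emission
with a nonzero increment is rejected with instructions to supply the
incremental dose fraction directly, since the scaling then has no
reference.

Rank comparisons between emission amounts and risks use average-rank ties
(rank 1 = largest) and the product-moment correlation of the rank vectors.

## Unit conversions and I/O

Toxicity databases commonly report ED50 as a lifetime cumulative intake
(kg chemical per lifetime); this converts to mg/kg bodyweight/day over a
standard 70 kg body and 70-year (25,550-day) lifetime as
value × 10⁶ / (70 × 25,550) ≈ value × 0.559. The conversion is linear and
invertible to < 10⁻¹² relative error.

All tables are plain UTF-8 CSV (header row mandatory, comma delimiter,
'.' decimal separator, '#' provenance comments). CASRN strings are opaque
join keys — never reformatted, hyphens and leading zeros preserved.
Chemicals present in one table but missing from another are reported and
skipped, never silently dropped.

## Synthetic-data generator

The generator emulates the statistical structure of a national emission
screen; the defaults are the study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| n_chemicals | 95 | size of the reference screen |
| dose_span_orders | 13 | observed spread of average daily doses |
| age_multiplier_child | 3.0 | 3-year-olds at ~3× teen/adult doses |
| ingestion_dominance | 0.9 | ingestion > inhalation for most chemicals |

Emissions are log-uniform over 7 orders of magnitude (1–10⁷ kg/yr, a
national-inventory-like span) and per-chemical dose-per-emission factors
log-uniform over the remaining span, giving combined doses covering ~13
orders; log-uniform is the minimal-assumption family when only
order-of-magnitude spans are known. Route splits draw a log-ratio up to
~2 × 10⁷-fold in favour of ingestion for dominant chemicals and mildly
reversed otherwise. Teen (age-14) doses are fixed at 1.15× adult,
matching the reference dataset's teen/adult ratio of roughly 1.2. ED50s
are log-uniform over 10⁻²–10³ mg/kg/d, with inhalation rows emitted in
lifetime-intake units so the pipeline exercises the unit conversion. A
final deterministic rescale pins the largest combined age-3 fraction at
0.55% of ED50 (the observed maximum, acrolein-like), keeping every
chemical below 1% of ED50. Doses derive from emissions through the fixed
factors, so dose is exactly linear in emission — the property the
incremental workflow assumes, and a property test of the pipeline.

What the generator does **not** emulate: spatial structure (county/tract),
source categories, chemical-property-driven fate and transport, or
inter-chemical correlations between emission and toxicity. Tests passing
on synthetic data therefore validate the arithmetic and the pipeline
contracts, not the realism of any particular chemical's exposure estimate.

The packaged reference dataset covers the ten highest-risk chemicals of
the screen (combined ED50 fractions and risks at ages 3/14/25) plus the
per-age 95-chemical totals; one explicitly-labelled synthetic remainder
row per age (total minus top-10 sum, ~3% of each total) makes the
fractions sum to the published totals. The full 95-chemical table is not
redistributed here, so per-chemical results beyond the top ten (e.g. the
published rank correlation of 0.59 between emission and risk rankings)
cannot be recomputed from packaged data; the ranking operation itself is
provided and tested on constructed cases.

## Numerical and design notes

- Root finding: Brent (scipy) with tight tolerances everywhere; grid
  searches use ≥ 10⁴ points plus `minimize_scalar(bounded)` refinement.
- Data files carry full-precision scientific notation; only human-readable
  CLI echoes round (3 significant figures), separating the regression
  surface from presentation.
- Determinism: a single integer seed drives the generator
  (`numpy.random.default_rng`); identical seeds give byte-identical CSVs.
  Timestamps never enter data files.
- Degenerate inputs: zero-length segments have zero discrepancy; empty
  chemical lists sum to zero exposure; zero dose is zero risk everywhere.

## Known limitations

- The dose-additive summation of ED50 fractions across dissimilar
  chemicals is a screening convention; it has no mechanistic
  justification for arbitrary mixtures.
- Interindividual susceptibility variability enters only through σ_log;
  no explicit population distribution is modelled.
- Cancer endpoints (slope factors, unit risks), threshold/reference-dose
  models, and hormetic (non-monotonic) curves are out of scope.
- The emission-to-dose link is a fixed linear factor per chemical;
  multimedia fate modelling is deliberately outside the package.
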