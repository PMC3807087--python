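# Methods

## Thermal time and phytomer coordinates

All kinetics run on thermal time: the cumulative sum, from the plant's bud
break, of daily mean air temperature above a base of 2.1 °C (the calibrated
base for *Rosa hybrida* 'Radrazz'). Accumulation is daily — sub-daily
integration adds nothing at glasshouse temperature variance — and days below
the base clamp to zero, the standard degree-day convention (never triggered
near 20 °C, but defined). Phytomer position uses the relative rank
*i* = (*r* − 1)/(*N*ₚ − 1); the peduncle is the topmost phytomer (*i* = 1)
and is treated everywhere as an internode-kind organ with its own timing and
duration parameters. Where results are grouped "per rounded rank", ranks are
rounded to the nearest tenth with ties going to the higher rank (an arbitrary
but fixed convention; grid midpoints such as 0.75 occur for even knot
spacings).

## Leaf-appearance model

Leaves are scored 5–6 times per week, so first-seen times overshoot true
appearance. Per plant, first-seen times against relative rank are fitted
with a continuous two-phase linear function: a rapid basal phase (slope β,
reflecting preformed leaves emerging almost together), a slow upper phase
(slope γ, the neoformed-leaf phyllochron × (*N*ₚ − 1)), and a breakpoint *c*
estimated by profiling: for any fixed *c* the model is linear in
(α, β, γ) and solved in closed form, so the residual sum of squares is
minimised over a dense grid of candidate breakpoints and refined by bounded
scalar minimisation in the winning interval. This avoids the non-smooth
optimisation failures of joint four-parameter fitting and guarantees the fit
is never worse than a single straight line (the nested β = γ case). The
upper branch is α + β·c + γ·(i − c): the two lines meet at the breakpoint;
without that constraint the model would be over-parameterised. Adjusted
appearance times are read off the fitted function, including a "virtual
leaf" time for the leafless peduncle by extrapolating the slow phase to
*i* = 1. Scaly and stipular basal leaves are ordinary observations.

## Logistic organ fits

Each organ series (length vs thermal time) with an observed final length of
at least 12 mm is fitted with the symmetric logistic in the parameters
(*L*ᵐ, *t*⁰, *v*ᵐ); *w*ᵐ = *v*ᵐ/*L*ᵐ is exact by construction. Sub-12-mm
organs (basal scale-bearing internodes, occasional sub-peduncle internodes)
cannot be resolved at ruler precision and are flagged excluded, carrying no
parameters. Initialisation is data-driven: *L*ᵐ ← 1.05 × max length,
*t*⁰ ← first half-max crossing by linear interpolation, *v*ᵐ ← max forward
difference. Trust-region least squares runs at tolerance 1e-12 with up to
three deterministic jittered restarts; parameter bounds are loose physical
ones (*L*ᵐ ≤ 5 × max length, *t*⁰ within five spans of the observation
window) that never bind for a healthy sigmoid but stop near-flat series from
running off to absurd rates. R² is computed against the mean-length null and
RMSE as the root mean squared residual.

**Observed final length** is the mean of the last three readings, not the
maximum: with ±0.8 mm noise and 1-mm rounding, a max over readings is
rectified noise, biased high by ~1 mm, and occasionally promotes a truly
sub-12-mm organ across the exclusion threshold, after which a flat series
fitted by a sigmoid yields meaningless parameters that poison the crop-level
profiles. The plateau mean is the natural estimator of what a technician
records as "final length" once expansion has ceased.

The 10–90 % expansion duration is ln(81)/(4*w*ᵐ), independent of size and
timing; leaflet–internode timing offsets (internode window nested inside the
leaflet window at the same phytomer) come from the analytic quantile times
of the fitted curves.

## Coordination and rank profiles

Mid-expansion time is predicted from the appearance time of the leaf at the
same phytomer: a quadratic for terminal leaflets (expansion duration drifts
with rank), and separate lines for vegetative internodes and peduncles.
Sub-models are ordinary least squares, fitted independently, with adjusted
R² reported per sub-model; peduncle pairs are identified strictly by
*i* = 1. The shipped default coefficients are the calibration pooled over
the three glasshouse crops (intercepts 61.5 and 70.6 °Cd for leaflets and
internodes — the lag between leaf appearance at bud break and maximal organ
expansion — and the peduncle line 220 + 0.893 *t*ᵃ).

Crop-level profiles of *w*ᵐ, *t*⁰ and *L*ᵐ against relative rank are
estimated by LOESS — locally weighted polynomial regression with tricube
weights. The smoother is implemented here because the statsmodels `lowess`
is restricted to locally *linear* fits, while these profiles need the
classical local quadratic (degree 2) to track curvature near the shoot top;
the degree-1 case is cross-checked against statsmodels in the tests. Span
0.5 and degree 2 are the defaults (the calibration software's defaults are
not recoverable; both are configurable). Profiles are evaluated on the fixed
tabulation grid {0, 0.05, …, 0.9, 0.93, 1.0} restricted to the observed rank
range, and interpolated linearly between knots — at 0.05 pitch, higher-order
interpolation is immaterial. Evaluation outside the tabulated range is an
error by default (an explicit clamp mode exists), because the basal leaflet
profile genuinely does not exist (scale leaves) and extrapolating *t*⁰ or
*w*ᵐ beyond the data is not meaningful.

**The peduncle is never smoothed together with vegetative internodes.** At
the shoot top there is a genuine discontinuity (final length drops to ~8 mm
at *i* ≈ 0.93 then jumps to ~53 mm for the peduncle; *w*ᵐ drops by a third);
a smoother dragged across it corrupts both sides. Profiles for internodes
are therefore LOESS over *i* < 1 with the peduncle added as its own knot at
*i* = 1 (the plain mean of peduncle estimates), mirroring the structure of
the shipped table.

## Scenarios and cross-validation

S0 uses *adjusted* (fitted) appearance times — raw first-seen times never
feed the coordination polynomials directly. The simplified three-value *w*ᵐ
variant is a configuration switch on any scenario, not a fourth scenario.
Sub-12-mm organs are emitted as constant-length curves at their final value,
flagged, and excluded from error scoring. Predicted curves are exposed both
as parameter triples and as evaluated series on caller-supplied grids.

Leave-one-out evaluation re-estimates all crop-level components (the six
profiles and the coordination coefficients) from the n − 1 training plants
in every fold; per-plant components (organ fits, appearance fits, observed
finals) depend only on the plant's own data and are computed once and
cached. MSEP per organ averages squared error over the plateau-truncated
observations: every observation at or below 0.97 × final length is kept,
plus the first four beyond it in chronological order ("first four" being the
natural reading of keeping four plateau values). RMSEP aggregates as
√(mean MSEP) over organ records — per rounded rank, pooled per kind, and as
a percentage of the kind's mean observed final length (the denominator is a
documented choice; an alternative would be per-organ normalisation before
averaging). Organ-level pooling is used throughout rather than plant-level
first.

## Synthetic crops

The generator emulates the study conditions, not an idealised model: 30
plants by default, phytomer counts uniform on 10–16, per-plant appearance
parameters drawn around α = 15 ± 6 °Cd, fast-phase phyllochron 6 ± 2 and
slow-phase 35 ± 7 °Cd/leaf (the measured slow-phase spread), breakpoint
0.45 ± 0.07. Per organ, final length is the calibrated profile value with
independent multiplicative noise (CV 10 % — size deviations are organ-local,
matching the observation that a plant long at one phytomer is not
systematically long at the next), timing is the coordination prediction plus
18 °Cd of noise (back-solved so that refitting the coordination on synthetic
leaflets returns adjusted R² near the calibration's ≈ 0.97), and *w*ᵐ is the
profile value exactly (durations are the stable component). Observations lie
on a visit grid of 7/6 days at 18.1 °Cd/day (a constant-rate thermal clock —
the 20.2 °C glasshouse mean above base; a weather-series mode is available
through the thermal-time utilities), start only at appearance + 15 °Cd
(left-censoring, as in the field), extend past every organ's 99.9 % point,
and carry 0.8 mm Gaussian noise rounded to 1 mm.

What the generator does *not* emulate: environmental responses (light,
density, humidity), between-crop mean shifts, secondary shoots, and any
correlation structure between neighbouring organs beyond the shared
appearance model. Passing tests therefore demonstrate internal consistency
of the pipeline under realistic noise, not transferability of the shipped
calibration to new glasshouse conditions. One visible consequence: the
internode coordination refitted on synthetic crops shows lower adjusted R²
(≈ 0.8) than the calibrated value, because small basal internodes carry
proportionally more fitting error at ruler resolution.

Problem sizes used in the shipped analyses and tests — a 30-plant crop for
cross-validation (≈ 25 000 length observations, ≈ 560 fitted organs), a
10-plant noise-free crop for closure checks, 201 leaves for the allometry —
keep every stage comfortably within desk-scale runtimes while matching the
study's sampling density per organ.

## Leaf-area allometry

Whole-leaf area is *A* = a·*L*²·*N*ₗ^b with shipped a = 0.287, b = 0.746.
"Maximise R²" is implemented as nonlinear least squares on the raw area
scale (equivalent for this model, and consistent with the multiplicative
error structure: residuals grouped by leaflet count stay centred on zero).
The exponent is unidentifiable from a single leaflet count, which is an
error; even leaflet counts warn but compute. The dimensionality-reduction
argument that one leaflet dimension suffices motivates the interface and is
not re-derived.

## Numerical notes and limitations

- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical config + seed reproduces byte-identical CSVs.
- Logistic exponents are clipped at ±500 before `exp` to avoid overflow at
  extreme evaluation times.
- The breakpoint search space for the appearance fit is the interior of the
  observed rank range; *c* is constrained to the open interval (0, 1).
- Profile JSON round-trips store *w* × 10³ (as tabulated); re-reading
  reproduces *t*⁰/*L*ᵐ knots bit-exactly and *w* to relative 1e-12 (one
  multiplication each way).
- The shipped profiles are used verbatim as the calibrated defaults; they
  are never re-derived from raw data in this package (the original crops are
  not distributed). Cross-validation on synthetic crops re-estimates
  profiles per fold from synthetic organs only.
- Minimum observations per logistic fit defaults to 5 (three parameters plus
  slack; the study averaged 16–19 per curve) and is configurable.
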