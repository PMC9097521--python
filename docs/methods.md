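# Methods

## The reaction-layer model

The analysis assumes adsorption under kinetic control: forced
convection in the flow cell removes diffusion limitation, so the
initial rate of peak-2 suppression reflects the surface reaction step
alone. A particle of hydrodynamic radius *R* interacts with the DOPC
monolayer through the band of its surface lying within the reaction
layer of thickness *h* above the lipid plane. Every geometric
quantity follows in closed form from *R*, *h* and the bulk properties
of amorphous silica:

| symbol | meaning | expression | units |
|---|---|---|---|
| a(R) | per-particle reactive area | π(2Rh + h²) | cm² |
| N(R) | particles per mmol SiO₂ | (M/1000)/((4/3)πR³ρ) | mmol⁻¹ |
| A(R) | specific reactive area | a·N | cm² mmol⁻¹ |
| C_tr(R) | molecules per particle | N_A(4/3)πR³ρ/M | — |
| SA(R) | close-packed footprint per mmol particles | N_mmol·2√3R² | cm² mmol⁻¹ |
| ΔI_max(R) | max peak depression | 32.1·min(1, a/(2√3R²)) | μA |
| v(R) | conversion factor | ΔI_max·SA (model form uncapped) | μA cm² mmol⁻¹ |

Fixed parameters (all configurable through the `constants:` config
block): h = 3.23 × 10⁻⁷ cm, ρ = 2.196 g cm⁻³, M = 60.08 g mol⁻¹,
full-suppression current 32.1 μA, and Avogadro-scale counts held at
three significant figures (6.02 × 10²⁰ mmol⁻¹ / 6.02 × 10²³ mol⁻¹) so
that worked examples reproduce at their printed precision; a
full-precision N_A can be supplied instead. h is a constant of the
model, never fitted. Lengths are cm internally; manifests accept nm
and convert once at ingestion.

The min(1, ·) cap on ΔI_max encodes saturation: below the crossover
radius (the positive root of 2√3R² = π(2Rh + h²), ≈7.18 × 10⁻⁷ cm)
close-packed particles have confluent reactive areas and suppression
is total. The model v deliberately uses the *uncapped* product
32.1·a(R)·N_mmol so that the v/SA quotient remains the uncapped
depression at every radius; consequently the identity
v = ΔI_max·SA holds exactly only above the crossover, and the
experimental-v and model-v top-down constants coincide there whenever
the measured maximum depression equals the model value.

## Rate extraction

Initial rates are ordinary least-squares slopes of peak height versus
time restricted to a window, default 0–50 s and configurable; OLS
rather than a two-point difference for noise robustness. Peak heights
are assumed baseline-corrected on input — the package does not locate
peaks in raw voltammograms. The V-versus-C_np fit uses a free
intercept (reported as a diagnostic, expected ≈ 0) rather than a
forced origin: conservative, and it makes a violated origin visible
instead of absorbing it into the slope. k′ uncertainty is the OLS
slope standard error from that fit. The k′-versus-A fit across sizes
is unweighted by default; a 1/SD² weighted variant is available but
off, since nothing in the data model makes the per-size variances
reliably known.

## Rate constants and uncertainty

k₁ = 1000·s/32.1 from the k′-vs-A slope s; per-size
k₂ = k′·1000·C_tr/v with either v variant; k₂cor substitutes
k′_cor = s·A(R). The bottom-up/top-down equivalence
(k₂ at k′ = s·A(R) with model v equals k₁ for every R) is asserted in
the test suite to a relative 10⁻¹⁰ over a 50-point grid spanning
5–100 nm, as are the per-size identities k′/k′_cor = k₂/k₂cor.

Error propagation is first order with independence assumed: relative
variances of multiplicative factors add in quadrature. The
capacitance-peak measurement error entering the experimental-v k₂ is
a config input, default 0 (k′-only propagation). Reports carry full
precision in machine output; human tables are formatted views.

## Synthetic studies

The generator emulates the statistical structure the analysis
assumes, with a known ground-truth rate constant (default
4.22 × 10⁻⁴ cm s⁻¹) so recovery is testable end to end. Per size,
k′ is derived by inverting the top-down conversion
(k′ = k_het·v_model/(1000·C_tr), which makes k′ exactly proportional
to A). Each noise-free trace declines at exactly k′·C until the
depression reaches a set fraction (default 0.5) of ΔI_max(R), then
relaxes exponentially to the plateau with continuous value and slope
— the linear-then-saturating shape the windowed-OLS extraction
assumes. A pure exponential transient was rejected because its
in-window secant is a biased estimate of the initial slope, which
would contaminate recovery with a deterministic artefact of the
transient's functional form rather than testing the estimator. Noise
is additive, homoscedastic Gaussian on current (default SD 0.1 μA);
no noise model beyond that is implied.

Doses are range-found per size, as an experimentalist would: the top
concentration is the largest for which the linear phase outlasts the
50 s window (C_max = 0.5·ΔI_max/(k′·50 s)), capped at the study
ceiling of 12 mmol dm⁻³, with six equal fractions of C_max per size.
Small particles, whose k′ is orders of magnitude larger per mmol,
therefore get sub-mmol doses — a fixed high-mmol grid would fully
suppress their peak within seconds and no windowed estimator could
recover the rate. Radii default to {6.75, 15, 25, 46, 66, 86} nm,
spanning the studied range; sampling is 1 s steps over 300 s. Every
trace draws noise from a sub-seed derived from the master seed and
its grid indices, so studies are bit-reproducible and single traces
regenerable in isolation.

What passing recovery tests do show: the extraction chain is unbiased
and correctly propagates a known rate constant through geometry,
fitting and unit conversions at realistic noise. What they do not
show: robustness to baseline drift, heteroscedastic or correlated
noise, polydispersity or agglomeration (a single effective radius per
dispersion), partial-coverage plateaus, or the recovery/flushing
phase — none of which the generator emulates.

## Dissolved silica

The solubility percentage is interpreted as % w/v (g per 100 cm³),
the only reading under which 0.012% and M = 60.08 give
0.002 mol dm⁻³. The dissolved-species footprint is the flat
equilateral base of the SiO₄ tetrahedron, (√3/4)·d² with
d = 0.26 nm ≈ 0.0293 nm²; no hydration-shell inflation. The
competition ratio is the plain quotient of particulate and dissolved
reactive areas, flagged particulate-dominated above 1. With defaults
the ratio evaluates to ≈2.3 — the particulate area more than double
the dissolved one.

## Numerical choices and degenerate inputs

Fits with a constant response return a zero slope with zero standard
error (no scatter, exact fit); two-point windows fit exactly and
report zero slope error. Fewer than two in-window samples, fewer than
three concentrations or sizes, and zero concentration span raise
typed errors (`InsufficientDataError`, `DegenerateDesignError`).
Radii above 10⁻⁴ cm in rate-constant tables raise a unit-sanity error
(nm mistakenly passed as cm); `Particle.in_bounds` exposes the same
check non-fatally. Zero-dose traces are flat by construction and
contribute a (0, V≈0) point to the k′ fit. The pipeline writes
nothing until the whole analysis has succeeded, and identical inputs
produce byte-identical reports.

The per-size experimental maximum depression is taken from the data
when a trace's late-time tail has flattened (last tenth of samples,
tail drift < 5% of the total depression), else the model value is
used; the provenance is recorded per row.

## Problem sizes

Default test and acceptance runs use 6 × 6 × 1 trace grids, 301
samples per trace, 50-point identity grids and 100–200 seeded
replications for the stochastic recovery checks — sizes chosen to
characterise estimator behaviour well while keeping a full run in the
order of seconds.

## Known limitations

The reactive-area form of Eq-style geometry is exact only for a
sphere touching a plane; surface roughness and particle–particle
interactions are out of scope. The model cannot separate the roles of
dissolved and particulate species in a mixed exposure — it quantifies
their competing capacities only. The printed per-size experimental
k′ and maximum-depression values behind the published top-down
constants are not available, so those specific numbers are validated
through the algebraic identities and synthetic recovery rather than
re-derived from data.
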