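# Methods

This note documents the models, conventions and numerical choices behind
`tramplerisk`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Season calendar and telemetry

Weeks are half-open 7-day blocks anchored at 14 April (week 1 of the
redshank nesting season, which spans weeks 1–12, mid-April to mid-July); a
28-week season therefore ends on 26 October. Calendar weeks are *not* used —
the block convention keeps week lengths exactly equal, which the AR(1)
trend models assume. Fixes are validated on ingestion: timestamps must be
strictly increasing per collar; identical (collar, timestamp) pairs are
treated as hardware duplicates and collapsed to the first occurrence with a
logged count; no interpolation of missed fixes is ever performed — activity
is defined on recorded positions only. Cattle days are the per-collar count
of distinct calendar days with at least one fix, summed over collars.

GPX support encodes the planar metre coordinates through a local
equirectangular mapping (origin 52.8° N, 0.2° E, near the Wash estuary);
the mapping is linear, so CSV and GPX round-trip to sub-millimetre
agreement. It is a coordinate *encoding*, not a geodetic transform; real
GPS data should be projected to planar metres before ingestion.

## Grid and cattle activity

The analysis grid is 50 × 50 m, half-open cells anchored at the boundary
bounding-box minimum (the anchor is configurable; results are reproducible
given the anchor). A cell's marsh area is its intersection with the usable
marsh — boundary minus creeks — and a cell is included iff that area
exceeds 6.25 m² (strictly), the threshold implied by the 2.5-m GPS chipset
accuracy. Fixes on a cell edge belong to the cell by the half-open
convention.

Activity is `H · (n/N) / area_ha`. The denominator `N` counts only fixes
landing in included cells over the same evaluation window as the numerator
(per-week for weekly surfaces, the first 24 days of grazing for risk maps);
fixes in excluded slivers are logged and dropped from both numerator and
denominator, so the conservation identity Σ activity × area = H holds
exactly whenever nothing is excluded. Weeks with no within-marsh fixes are
*missing*, never zero.

Habitat zones (non-saltmarsh, mid-marsh redshank, *Elytrigia* redshank,
non-redshank — in order of proximity to the seawall) label each included
cell by largest intersected area; exact ties go to the zone nearer the
seawall in that fixed order. Stocking summaries use SCD = herd/area and a
0.8 livestock-unit coefficient for young cattle; reported values are
rounded to 2 decimals, half-up, with unrounded values retained internally.

## Range metrics

CA₁₀₀ uses included cells as its denominator (the "available marsh").
Because activity is proportional to raw fix counts, the unique minimal cell
set containing all of a week's activity is exactly the visited set, so
CA₁₀₀ is the visited-cell percentage. The 95th-percentile distance to the
seawall pools fixes over collars and uses linear interpolation between
order statistics (the type-7 definition); weeks with fewer than 20 fixes
are flagged low-precision. Weeks before grazing starts are absent, not
zero.

## Trend models

The global model for a weekly response is
`g(y) ~ marsh + week + week² + marsh:week + marsh:week²` with g one of
log₁₀, log₁₀(x+1), √ or identity, and AR(1) errors within marsh ordered by
week (gap-aware: a missing week contributes φ^gap). φ is estimated by
profile *REML* rather than ML: at 28 weeks per group, profile-ML φ is
biased low by roughly (1+3φ)/T (≈ −0.1 at φ = 0.6), and REML removes most
of that bias (simulation: mean estimate 0.59 vs 0.50 at truth 0.6). Term
tests are F tests computed on the whitened fit — not likelihood-ratio
tests — so the usual argument for ML when comparing fixed-effect
structures does not apply; `method="ml"` remains available.

Term F tables are sequential (type I), in the order marsh, week, week²,
interactions, matching the conventional presentation of such tables.
Backward selection repeatedly deletes the single removable term with the
largest deletion-test p ≥ α (default 0.05), respecting marginality: a main
effect is never dropped while any of its interactions remains, and week is
retained while week² is present. Stopping occurs when every removable term
tests significant — which means a stop retains *all* remaining terms;
consequently the per-replicate probability of keeping at least one
pure-noise term exceeds α (≈ 25 % with ~6 sequential tests), while the
per-deletion-test retention rate is controlled at α (simulated 0.051).
Degenerate inputs (an exactly constant response) yield NA F tests rather
than numerical noise. The residual-ACF diagnostic reports per-group
autocorrelations to lag 10 against ±1.96/√n white-noise bands.

Per-zone models are Gaussian linear models of the zone's weekly mean
cattle density (zone fix share scaled by herd size over zone area);
interactions enter the global model and only they are eliminated, so the
reported table always shows the marsh, week and week² rows. Zones absent
from a marsh are skipped with a log entry.

## Trampling probabilities and the dose–response

Disc outcomes convert exactly as the exposure-period algebra dictates:
p_period = broken/9 per 14-day period, d = 1 − (1 − p_period)^(1/14),
d̄ = (d₁ + d₂)/2, p₂₄ = 1 − (1 − d̄)^24. The two functions are algebraic
inverses at equal day counts (verified to 1e-12).

The dose–response is a binomial penalized spline on the logit scale: cubic
B-splines (6 basis functions over the observed activity range) with a
second-difference penalty, fitted by penalized IRLS; the smoothing
parameter minimises AIC = deviance + 2·edf over a log-spaced grid. The
second-difference penalty shrinks toward a straight line in the logit —
i.e. toward a logistic curve — so a logistic truth drives the selected
effective df toward 2, consistent with a near-linear smooth on this scale.
Each plot enters as nine weighted Bernoulli trials at its observed p₂₄,
preserving the binomial error structure while modelling the
incubation-length response; a period-level variant (two binomial counts per
plot, converted to the 24-day scale after fitting) is available behind
`period_level=True`. Plot-local activity is the activity of the 50-m cell
containing the plot centre over the exposure window; plots straddling
cells use the centre cell only. Confidence bands use the Bayesian
posterior covariance of the spline coefficients on the logit scale.
Predictions outside the fitted activity range are clamped to the boundary
with a warning, never extrapolated; all-identical outcomes flag the fit as
degenerate (complete separation). A Moran's-I screen with inverse-distance
weights on plot-level residuals is reported, not auto-corrected.

Risk maps apply the fitted curve to per-cell activity pooled over the first
24 days of grazing (single-window normalisation, not weekly); zero-activity
cells receive the model's zero-activity prediction, and zone labels ride
along for overlap summaries such as the redshank-zone vs non-redshank-zone
mean-risk ratio.

## Synthetic generator

The generator's defaults describe the study system on which the dummy-nest
experiment runs: a 126-ha usable marsh along an 1,800-m seawall, grazed by
39 young cattle (4 collared, one fix per 20 min) from week 6 to week 28,
with four habitat zone bands of 100/250/150/200 m and ~5 % of the area in
creeks. `marsh_area_ha` is interpreted as *usable* (creek-free) area: the
rectangular boundary is inflated by 1/(1−creek_density) so the usable area
matches the configured value whether or not creeks are present. Zone bands
are laid seaward in the canonical order; the configuration is
over-determined (area, seawall length and band widths), resolved by
deriving depth from area/length, requiring the bands to fit (a
configuration error names the first band that does not), and extending the
outermost non-redshank band to the seaward edge.

Movement is a biased correlated random walk: velocity mixes persistence
(0.6), attraction (0.06) toward a herd centre whose distance from the wall
follows a Gaussian hump peaking at `expansion_peak_week` (baseline 120 m,
peak 75 % of marsh depth, width 5.5 weeks), cohesion toward the herd
centroid (0.05), and Gaussian step noise whose s.d. grows with the range
profile (8–45 m per 20-min step) — cattle ranging farther also wander
more. Walkers reflect off the boundary and are nudged out of creeks, never
discarded. This reproduces the qualitative field phenomena the pipeline
must detect — early-season concentration within a few hundred metres of
the wall, hump-shaped CA₁₀₀ and 95th-percentile-distance trajectories, a
majority-never-visited grid — but it is *not* calibrated to any real herd:
no forage depletion, tidal forcing (an optional periodic attraction pulse
exists, off by default), weather, or behavioural state switching. Passing
tests therefore demonstrate that the pipeline recovers the structure the
generator encodes, not that the walk is a faithful movement model. Collar
dropout (battery failure) is an optional per-collar truncation date,
default none.

Disc trials are Bernoulli per disc per 14-day period with
logit(p) = β₀ + β₁·activity (defaults −4.0, 2.9: p₂₄ ≈ 0.03 with no
cattle, > 0.99 above ~3 cattle/ha, emulating a saturating curve), with
broken discs replaced after period 1. Plot layouts are stratified across
zones with a 50-m minimum spacing, mirroring the 30-plot field design. A
single seeded generator (numpy `default_rng` with per-stage streams) makes
every stochastic stage reproducible; the seed and a scientific-settings
hash are recorded in every output header, and reruns are byte-identical.

## Problem sizes and tolerances

The test suite runs the full default season (4 collars × 23 weeks ×
20-min fixes ≈ 46k fixes, 540 cells) once as a shared fixture; recovery
studies use 200 replicates (dose–response, backward selection) and 500
replicates (AR(1) φ), sizes at which Monte-Carlo error is well below the
asserted bands. Conservation and probability-algebra identities are
asserted at 1e-9–1e-12; geometry oracles at 1e-6 relative (area sums) and
1e-9 absolute (distances). The whole suite completes in well under a
minute per module on one CPU.

## Known limitations

Herd-representativeness (3–10 % of animals collared) is assumed, as in the
field design. The dose–response is fitted on dummy nests at plot scale and
carries their caveats (random placement, unknown footfall bias). The
simulator's movement parameters are illustrative; quantitative field
values (absolute CA₁₀₀ percentages, distances, GAM χ²) depend on real GPS
data and are reproduced in qualitative structure only. Predictions of the
dose–response outside the observed activity range are clamped, so risk
maps saturate rather than extrapolate.
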