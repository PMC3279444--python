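# Methods

## Scope and design

`walkrisk` implements a descriptive (cross-sectional) comparative risk
assessment: given a cohort with home locations, one-day activity diaries,
a pollutant monitor network, and built-environment layers, it estimates
attributable ischemic heart disease (IHD) mortality for physical
inactivity and for three pollutants (PM2.5, NOx, O3), overall and within
high- and low-walkability neighborhoods. The assessment makes no causal
claim: neighborhood walkability is an exposure classifier, not an
intervention.

The computation is organized as a statsmodels-style pair: a
`ComparativeRiskModel` built from the joined tables, whose `fit()` returns
a `RiskAssessmentResults` holding the group × factor PAF table,
between-neighborhood differences, the tier-based multi-level PAF, and
`summary()` / `plot()` / `stratified()` views. The upstream stages
(synthetic city, exposure assignment, built environment, activity) are
deterministic data transformations and stay plain functions.

## Exposure assignment

Monitor daily series are collapsed to an annual metric: the arithmetic
mean of daily values, where for O3 the dailies are daily 1-hr maxima by
input contract (so the metric is the annual mean of 1-hr maxima, matching
the epidemiological studies the dose–response coefficients come from).
The annual metrics — not the daily values — are interpolated to homes; for
a fixed monitor set the two orders commute, and interpolating the metric
is ~365× cheaper.

Interpolation is inverse-distance weighting over the k = 3 nearest
monitors. The distance exponent is 1 (plain inverse distance) by default
and configurable; a home within ε = 1 m of a monitor takes that monitor's
value directly, which avoids the 1/d singularity at a physically
negligible threshold. Ties in distance are broken by monitor id so runs
are deterministic. The result is a convex combination of the used monitor
values, exact at monitor sites and continuous elsewhere.

Referent levels are the per-pollutant 10th percentile of the cohort
exposure distribution, computed with linear-interpolation quantiles (the
numpy default). The percentile, k, and power are all logged at INFO so a
run is auditable.

## Built environment and walkability

* **Population density** — tract population ÷ tract area (km²), joined by
  point-in-polygon; a home on a shared boundary goes to the
  lowest-tract-id match, deterministically.
* **Network buffer** — the home is snapped to the nearest point of the
  nearest non-freeway edge (homes >500 m from any such edge get an empty,
  flagged buffer); the buffer is every node whose shortest-path distance
  from the snapped point is ≤1,000 m, computed by truncated Dijkstra from
  the two edge endpoints. Dijkstra trees and per-location results are
  cached (offsets quantized to 25 m), so households on the same block
  share the computation.
* **Intersection density** — the count of buffer nodes with degree ≥3 in
  the non-freeway graph.
* **Land-use mix** — with aⱼ the area of primary class j (residential,
  commercial, retail, institutional) inside the buffer footprint and
  pⱼ = aⱼ/Σa, the index is −Σ pⱼ ln pⱼ / ln 4. It is 1 at an equal
  four-way mixture, 0 for a single use, permutation- and scale-invariant,
  and a zero-area footprint scores 0 with a flag rather than being
  dropped, so cohort accounting stays explicit.
* **Footprint** — converting a network buffer (a set of network points) to
  an area is underdetermined; the package implements both a convex hull of
  the reached points (default: cheap, and close in spirit to "the area
  within the buffer") and a union of 50 m half-width corridors around the
  reached edges (configurable) for users who want a street-hugging
  footprint.

Classification uses cohort-level tertile cut points per variable
(linear-interpolation quantiles; values equal to a cut point go to the
lower bin, deterministically). High walkability = upper tertile on all
three variables; low = lower tertile on all three; the rule therefore
depends only on ranks and is invariant to monotone transforms of any
variable. A decile mode supports finer gradient reporting.

## Activity and the Monte Carlo sensitivity analysis

One weekday diary per participant is scaled by 7 to weekly minutes
(assuming activity is constant across the week) and split into active
transport vs recreation. Tiers: inactive = 0 min/week, insufficiently
active = (0, 150], active = >150.

The day-redistribution Monte Carlo relaxes the constant-by-day
assumption: within strata of age (0–25, 26–50, >50) × sex × ethnicity, the
stratum's pooled nonsedentary minutes are conserved exactly while a new
nonsedentary set of size min(stratum size, k × current count) is drawn
uniformly without replacement (k = 2 for active-every-other-day, 3 for
every-third-day) and the pool is split equally within it. The
transport/recreation split follows the stratum's original transport
share. Consequences, both tested: stratum person-minutes are conserved
exactly in every replicate, and the inactive share never increases. The
cap at stratum size is applied (and logged) since a stratum cannot contain
more nonsedentary people than members.

## Risk model conventions

* The dichotomous PAF uses the **mean individual RR over all group
  members** — the unexposed contribute RR = 1 and dilute the mean. With
  observed tier prevalences (83.5/5.6/10.9%) this reproduces the
  51/100,000 cohort inactivity figure; the standard mean-over-exposed
  variant (which yields ≈56) is selectable via `rr_convention`. The
  multi-level PAF Σpᵢ(RRᵢ−1)/(1+Σpᵢ(RRᵢ−1)) over the activity tiers is
  always reported alongside; algebraically it dominates the
  mean-over-all dichotomous form, with equality only at p ∈ {0,1} or all
  RR = 1.
* Exposed means strictly above the pollutant referent (≈90% of the cohort
  at a 10th-percentile referent by construction) or at/below 150 min/week
  for activity.
* Pollutant RR is clamped to 1 below the referent rather than allowed to
  dip below 1: the referent represents a clean-neighborhood baseline, not
  a protective threshold.
* Linear activity dose–response variants decline from RR(0) = 1.47
  (medium; low/high use 1.31/1.63) to 1.00 at 150 min/week. These
  bracketing slopes are this package's reconstruction of a plausible
  low/medium/high family, not a literature triplet.
* Base rates: 191.2 IHD deaths/100,000/yr for everything except NOx,
  which uses 81.9 (the male 45–54 subgroup rate, because the NOx
  coefficient comes from a male-cohort study). Reported rates are rounded
  to the nearest integer death.
* Attributable rates are reported per factor and never summed.

## The synthetic city

The generator produces the statistical structure the assessment assumes,
on planar meters with Euclidean distances (the method uses only relative
distances, so no geodesy):

* **Pollutant fields** — linear radial gradients from the core
  (PM2.5 25.5 − 0.50/km, NOx 115 − 2.6/km, O3 82 + 1.4/km μg/m³) plus an
  exponential near-freeway increment for PM2.5/NOx and Gaussian daily
  noise. These are the simplest forms giving core-peaking PM2.5/NOx and
  periphery-peaking O3 with cohort means near 22/85/99 μg/m³.
* **Streets** — a coarse uniform grid (500 m default) everywhere plus
  half-spacing lattice nodes kept with probability rising toward the
  core, so intersection density within a fixed buffer varies continuously
  from periphery to core while the graph stays connected and planar. One
  straight east-west line is flagged freeway.
* **Tracts and parcels** — a square tract grid with population density
  declining exponentially from ~57,000 to ~2,000 people/km²; parcels are
  tract subcells whose land-use class mixture shifts from
  residential-dominated at the edge to a balanced four-way mix at the
  core.
* **Cohort** — homes sampled ∝ tract population, uniform within tract;
  weekly activity is zero-inflated log-normal with P(nonsedentary) rising
  linearly from 0.10 to 0.27 in central-ness and nonsedentary means
  declining 543 → 410 min/week, so the cohort is ~83% inactive, activity
  prevalence roughly doubles core vs edge, and nonsedentary people at the
  edge do more minutes each; the active-transport share rises 0.18 → 0.55
  with central-ness. Demographics come from fixed vocabularies with mild
  central-ness gradients. One weekday diary per participant; no weekend
  supplement is simulated.

Everything is driven by one seed; identical config + seed reproduces
byte-identical fixture files.

What the generator does **not** emulate: realistic street topology or
travel demand, multi-day or seasonal activity patterns, geocoding error,
spatially correlated daily pollution noise, or survey trip undercounting.
Passing tests therefore demonstrate that the pipeline recovers the
structure it is pointed at, not that real-survey magnitudes would be
reproduced. The between-neighborhood checks are accordingly sign/ordering
properties, not magnitude matches.

## Problem sizes and numerics

Cohort-level calibration checks run at n = 30,000 participants (matching
the study cohort's order of magnitude); the full spatial
pipeline property checks run at n = 6,000 participants on a 30-km domain,
which gives the same sign pattern with comfortable margins while keeping
the suite quick. The calibrated exposure distribution used for the PM2.5
cohort rate is the log-normal fitted to a mean of 22 μg/m³ and a 10th
percentile of 13.6 μg/m³ (σ ≈ 0.332, μ ≈ 3.036).

Degenerate inputs are defined rather than special-cased: empty buffers
score 0 intersections and 0 mix (flagged); constant variables make
tertiles undefined and raise; an all-active cohort at referent exposures
yields all-zero attributable rates. Quantiles everywhere use linear
interpolation between order statistics; ties at bin edges go to the lower
bin; monitor-distance ties break by monitor id.

## Limitations

Cross-sectional design; constant background IHD rate (no age-specific
integration); no uncertainty propagation of the dose–response confidence
intervals (they are carried in config only); single-pollutant models (no
two-pollutant O3 adjustment); IDW exposure (no dispersion or land-use
regression modeling); self-report activity taken at face value.
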