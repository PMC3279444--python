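# walkrisk

Within-urban comparative risk assessment of the built environment: how do
**physical inactivity** and **outdoor air pollution exposure** (PM2.5, NOx,
O3) trade off across neighborhoods of different *walkability*, measured as
attributable ischemic heart disease (IHD) mortality?

Dense, walkable urban cores tend to raise physical activity — but they also
sit where PM2.5 and NOx concentrations peak, while O3 is typically higher in
outlying areas. `walkrisk` quantifies this trade-off for a travel-diary
cohort: it interpolates home-based annual pollutant exposures from a monitor
network, derives weekly activity minutes from one-day diaries, classifies
neighborhoods by walkability, and converts both risk factors into
attributable IHD mortality rates per neighborhood type. A fully seeded
synthetic-city generator makes the whole pipeline runnable and testable
without any restricted survey or GIS data.

## The model

Each participant *i* receives a relative risk per risk factor:

* **Pollutants** — linear dose–response above a cohort referent
  concentration *c*₀ (the 10th percentile of cohort exposure):
  RR*ᵢ* = 1 + (RR₁₀ − 1)·max(0, *cᵢ* − *c*₀)/10, with RR₁₀ = 1.25 (PM2.5),
  1.08 (NOx), 1.008 (O3) per 10 μg/m³; RR is clamped to 1 below the
  referent. Exposure *cᵢ* is the inverse-distance-weighted average of the
  annual metrics of the 3 monitors nearest the home.
* **Physical inactivity** — the WHO three-tier scheme on weekly minutes
  (one weekday diary × 7): inactive (0 min/week) RR = 1.47, insufficiently
  active (1–150) RR = 1.31, active (>150) RR = 1.00. Linear dose–response
  variants are available as a sensitivity analysis.

Each group *g* (cohort, high-, low-walkability) is summarized by the
population-attributable fraction

  PAF*g* = *p*(R̄R − 1) / (*p*(R̄R − 1) + 1),

where R̄R is the mean individual RR in the group (averaged over **all**
members, so the unexposed contribute 1 — a `mean_over_exposed` variant is
selectable) and *p* the proportion exposed relative to the referent.
Attributable mortality is PAF × the background IHD rate (191.2
deaths/100,000/yr; 81.9 for the NOx male 45–54 subgroup). A multi-level PAF
over the activity tiers is reported alongside. Rates for different risk
factors are never summed: the factors confound one another and the at-risk
populations overlap.

**Walkability** is the joint-tertile rule over three household variables:
tract population density, intersection count (nodes with ≥3 non-freeway
segments) within a 1-km network buffer, and land-use mix — the normalized
entropy −Σ pⱼ ln pⱼ / ln 4 of the four primary land-use area shares inside
the buffer footprint. Upper tertile on all three ⇒ high walkability; lower
tertile on all three ⇒ low.

## Worked example

```python
from walkrisk import RunConfig, SyntheticCityConfig, MonteCarloScheme
from walkrisk.pipeline import run_pipeline

cfg = RunConfig(
    synthetic_city=SyntheticCityConfig(n_participants=2000, seed=1),
    monte_carlo=MonteCarloScheme(n_reps=20),
    seed=1,
)
out = run_pipeline(cfg, "results/demo")
print(out["results"].summary())
```

prints (abridged):

```
Comparative risk assessment: attributable IHD mortality
RR convention: mean_over_all; activity dose-response: stepwise
Referent levels (ug/m3): NOx=79.2, O3=86.1, PM2.5=18.7

group    risk factor               n  p_exp  meanRR     PAF  rate
cohort   physical_inactivity    2000  0.870  1.3993  0.2577    49
cohort   PM2.5                  2000  0.900  1.0605  0.0516    10
high     PM2.5                   285  1.000  1.1123  0.1009    19
high     physical_inactivity     285  0.856  1.3861  0.2484    48
low      PM2.5                   448  0.723  1.0170  0.0121     2
low      physical_inactivity     448  0.902  1.4174  0.2735    52

Multi-level (tier-based) cohort PAF for physical inactivity:
0.2854 -> 55 deaths/100,000/yr
```

Reading this: 87% of the synthetic cohort is below the 150 min/week
activity referent; their diluted mean RR of 1.40 yields a PAF of 0.258,
i.e. **49** of the 191.2 background IHD deaths/100,000/yr are attributable
to physical inactivity. PM2.5-attributable mortality is *higher* in the
high-walkability core (19 vs 2) while inactivity-attributable mortality is
*lower* there (48 vs 52) — the central trade-off the assessment measures.
`out["results"].differences` tabulates the high-minus-low contrasts, and
`out["results"].plot()` draws the grouped bar chart. The same run is
available from a shell:

```bash
walkrisk all --config run.yaml --out results/
```

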