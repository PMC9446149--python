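# Methods

## Scope and intent

`activesim` simulates daily recreation-center class participation and its
long-run effect on body weight in a synthetic population of adult women, with
and without a place-tailored app that surfaces free classes. It is built for
scenario analysis — sweeping the baseline propensity to exercise and the
app-engagement cascade — not for forecasting any particular real city: the
spatial layout, demographic marginals and behavioral gate probabilities are
parametric stand-ins, configurable per scenario.

## The synthetic city and population

The city is a 4×2 mosaic of square wards, 4 km on a side, on a planar km
grid with Euclidean distances. This is deliberately abstract: every
mechanism in the model needs only distances (walk/drive reach, a 0.5-mile
geofence), not real geography. Recreation centers are placed uniformly at
random within their ward's rectangle; the default counts per ward
(4, 3, 4, 4, 3, 8, 1, 3) are invented placeholders that make ward 6 the best
served and ward 7 the worst, reproducing the qualitative access gradient the
model is meant to explore. Centers hold 50-minute classes at 6.5 METs on
weekdays by default.

Agents number 167,356 by default (10,000 at desk scale; every prevalence
metric is population-size-free). Ward shares use the two published ward
denominators (ward 6: 20,739; ward 7: 32,729 of 167,356) and split the rest
evenly. Age is uniform on 18–65; height normal (1.63 ± 0.07 m, clipped);
initial BMI lognormal with median 30.2 kg/m² and sdlog 0.23, clipped to
[16, 55] — chosen so that initial obesity prevalence is ≈51% and overweight
≈28%, plausible for the modelled population; initial prevalence is
explicitly a user-set initial condition, not an estimated quantity. Income
and work location are carried on each agent but have no behavioral mechanism
attached by default. Smartphone ownership is Bernoulli(0.80); car ownership
is per-ward (0.45 in ward 7 to 0.68 in ward 6).

Body composition splits the BMI-implied weight with the Deurenberg equation
for women, BF% = 1.2·BMI + 0.23·age − 5.4, clamped to [5%, 60%]. The lower
clamp is defensive — it is unreachable for BMI > 10 and age ≥ 18 — while the
upper clamp engages at extreme BMI/age.

## Behavior

Participation each day is the conjunction of five gates (baseline
propensity; objective access with a class scheduled today; perceived
access; class awareness; preparedness), drawn independently each agent-day.
Independence across days is the simplest joint law consistent with a
per-factor description and keeps the closed form: P(attend) = p₀ ·
P(access∧class) · p₃·p₄·p₅.

Gate defaults (p₃ = 0.60, p₄ = p₅ = 0.50; app-modified 0.85/0.80/0.80) were
calibrated analytically, before any simulation, to the published ~2% daily
participation at a 25% baseline: 0.25 × 0.78 (access) × 5/7 (class days) ×
0.15 ≈ 0.021. The app uplifts are invented (their published values are in
supplementary material not available here) and are config-exposed.

Two consequences of independent daily gates are worth knowing. First, the
monthly participation rate implied by an independent 2.1% daily rate is
1 − (1 − 0.021)³⁰ ≈ 47%, far above the ~19% a population of habitual
repeaters would show; validation against participation therefore uses the
structural ordering daily < monthly < ever, not the monthly level. An
optional per-agent habit multiplier (`GateParams.habit_sd`, a lognormal
factor on the preparedness gate, off by default) introduces repeat-attender
heterogeneity for users who want it. Second, over a 5-year horizon every
agent with access almost surely attends at least once, so the
ever-participated share equals the objective-access share — the
participation ceiling is exact here, not just an upper bound.

## Energy balance and weight

Each agent's state is (fat mass F, lean mass L). Daily:

- maintenance expenditure TEE = PAL · (19.7·L + 413) kcal/day (Cunningham-
  type RMR linear in lean mass — chosen because L is a state variable —
  times a physical-activity level, default 1.5);
- class energy = (MET − 1) · weight · minutes/60, net of resting
  expenditure since rest is already inside TEE (gross mode by flag);
- the imbalance ΔE = intake − TEE − exercise is partitioned by the Forbes
  rule, lean share c/(c+F) with c = 10.4 kg, and converted to mass with
  ρ_lean = 1807 and ρ_fat = 9440 kcal/kg;
- masses are floored at L ≥ 25 kg, F ≥ 2 kg (residual deficit discarded).

Intake is calibrated once to the initial TEE, making weight exactly
stationary without classes, and never adjusted (no compensatory eating).
This yields exact energy bookkeeping (ρ-weighted mass change equals
cumulative net kcal to 1e−6 relative while floors are inactive, verified
over 5 simulated years) and a well-defined steady state under sustained
exercise: a BMI-30 agent attending daily converges to |intake − TEE −
exercise| < 1 kcal/day within 5 years. Because exercise doses here are
small (~7–9 min/week population average), 5-year BMI shifts are small;
effects accrue over years, and year-1 changes are smaller than year-5
changes in any effective scenario.

## The app

Adoption is a three-stage cascade (aware → download → notifications), with
download restricted to smartphone owners in sampled mode. Expected-mode
counts round half away from zero, reproducing the published chains
(167,356 → 41,839 → 10,460 → 2,615 at 25%; → 125,517 → 94,138 at 75%).
Attrition: each adopter is retained forever with probability r∞ (default
0.3) or churns at a uniform time in the first 90 days; no churn later, no
re-adoption. The uniform-churn shape is a modelling choice — only the
3-month window and the existence of attrition are given — and r∞ is
config-exposed. Notified, still-active users get (a) an evening prompt when
a reachable center has a class tomorrow, raising the awareness and
preparedness gates the next day, and (b) a geofence notification when a
center lies within 0.5 miles (0.804672 km) of home, raising the
perceived-access gate that day. The geofence is evaluated at the home
location once daily; there is no within-day movement model, and work-based
access is deliberately not modelled (home access is the proxy).

## Experiments, common random numbers, and inference

Replicates share the generated city and differ in behavioral/app streams.
Stream layout enforces common random numbers across scenarios: the behavior
stream consumes exactly n×4 uniforms per day and the app stream a fixed
number of per-agent uniforms regardless of the engagement triple. Hence a
zero-awareness app is bit-identical to no app; adoption sets grow
monotonically in each cascade component; and participation is monotone in
every gate probability, pathwise, replicate by replicate.

Every population metric (percent ever exercised, PA min/week, overweight and
obesity prevalence — disjoint categories, [25,30) and ≥30 — mean BMI, mean
BMI among the obese, daily/monthly participation) is reported as a
mean with a 95% t CI (df = replicates − 1) across replicates; ward-level
summaries are the same statistics within ward. App-vs-no-app contrasts use
per-replicate paired differences.

A caveat on significance: with paired common random numbers the delta CIs
are extremely tight, so even a practically negligible effect (e.g. +0.06
min/week at 25% engagement) is statistically nonzero. `compare()` reports
the flag, but magnitude is the meaningful summary of an intervention
effect under this design; the acceptance script reports magnitudes.

Calendar: 364-day years (52 exact weeks), so minutes/week aggregation is
exact and weekday schedules tile the year; the default horizon is 5 years
(1,820 days), replicates default to 10.

## Problem sizes and numerical choices

Desk-scale runs use 10,000 agents; one 5-year replicate takes well under a
second, and the full four-scenario engagement ladder with 10 replicates
runs in about half a minute. The full 167,356-agent population is supported
with the same code path. All distance thresholds are closed (≤); cascade
rounding is half-away-from-zero; all randomness flows from
`numpy.random.SeedSequence(seed, spawn_key)` so every result is exactly
reproducible from (config, replicate index).

## Limitations

- The city, gate probabilities and app uplifts are parametric stand-ins;
  absolute outcome levels (e.g. year-5 obesity prevalence) track the chosen
  initial BMI distribution and are not calibrated to any real city.
- No social-network influence, habit formation (beyond the optional
  multiplier), capacity limits, travel-time or transit modelling, adaptive
  thermogenesis, or dietary response.
- Ever-participation saturates at the access ceiling under homogeneous
  gates; real populations show persistent never-attenders even with access.
- Attrition's uniform-churn shape and the retained-core fraction are
  assumptions, not estimates.
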