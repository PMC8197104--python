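# Methods

This note documents the models implemented in `comfortrisk`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real registry data.

## 1. Thermal comfort: PMV

The PMV kernel (`comfortrisk.comfort`) is the steady-state single-node heat
balance in its standard ISO 7730 form.  For a subject with metabolic rate
M (W/m² of body surface), mechanical work W, clothing insulation
I_cl = clo × 0.155 m²·K/W and clothing area factor

    f_cl = 1.00 + 1.290 I_cl   (I_cl ≤ 0.078, boundary inclusive)
         = 1.05 + 0.645 I_cl   (I_cl > 0.078),

the thermal load is

    L = (M−W)
        − 3.05·10⁻³ (5733 − 6.99(M−W) − P_a)        (skin vapour diffusion)
        − max(0, 0.42 ((M−W) − 58.15))               (sweat evaporation)
        − 1.7·10⁻⁵ M (5867 − P_a)                    (latent respiration)
        − 0.0014 M (34 − t_a)                        (sensible respiration)
        − 3.96·10⁻⁸ f_cl ((t_cl+273)⁴ − (T_mrt+273)⁴)  (radiation)
        − f_cl h_c (t_cl − t_a)                      (convection)

and PMV = (0.303 e^(−0.036M) + 0.028) · L.  The sweat term is clamped at
zero below the resting rate; at the fixed reference subject used throughout
(80 W over 1.80 m² ⇒ M = 44.4 W/m²) the clamp is always active.

The water vapour partial pressure is the Magnus form
P_a = (RH/100) · 611.2 · exp(17.62 t_a / (243.12 + t_a)) Pa, used as a
single continuous expression above and below 0 °C so no solver ever crosses
a freezing-point discontinuity.

t_cl appears on both sides of its balance equation and is solved by a
damped fixed-point iteration (damping 0.5, start (t_sk + t_a)/2 with
t_sk = 35.7 − 0.028(M−W), tolerance 10⁻⁴ °C, 500 iterations).  At high wind
the fixed-point map is expansive; elements that fail to contract are
re-solved by bisection on the residual t − rhs(t), which is strictly
increasing in t, so termination is guaranteed.  h_c is recomputed at every
iterate as max(2.38 |t_cl − t_a|^0.25, 12.1 √v) — the printed two-branch
form is exactly "take the larger".  All kernels broadcast over numpy
arrays; a year of station-hours is solved in one vectorised pass.

The implementation agrees with ISO 7730 validation cases to ~0.01 PMV units
and with an independent brute-force bisection oracle to 10⁻³ PMV units on
200 random states spanning t_a ∈ [−20, 40], T_mrt ∈ [t_a−20, t_a+30],
v ∈ [0, 10], RH ∈ [0, 100] (tests/test_acceptance.py).

## 2. Thermal comfort: PET by load equivalence

PET is defined as the air temperature of a standardized reference
environment — T_mrt = t_a,ref, v = 0.1 m/s, vapour pressure 1200 Pa — in
which the reference subject's heat budget matches the actual environment.
`comfortrisk` evaluates both budgets with the PMV body model above and
bisects t_a,ref over [−60, 70] °C until the loads match (reported to
0.01 °C; the reference load is strictly increasing in t_a,ref, so the
bracket test is exact).  The reference vapour pressure is held at 1200 Pa
by convention even where that exceeds saturation at cold reference
temperatures, which is why `EnvironmentState` accepts an explicit `pa`
without the saturation cap that applies when `pa` is derived from RH.

**Known limitation.**  Dedicated PET software rests on a two-node
(core/skin) physiology in which skin temperature falls under cold, windy
exposure, damping the dry heat loss.  The single-node equivalence here
keeps skin temperature fixed at 35.7 − 0.028(M−W) °C, so wind chill is
amplified: on the six published worked-example rows (winter conditions,
station winds 1.9–7.6 m/s) this PET runs 8–12 °C colder than the published
reference-tool values, the deviation growing with wind speed.  Sensitivity
probes over the metabolic-rate interpretation (44–115 W/m²) and wind
height-reduction exponents do not close that gap, so the corresponding
soft acceptance check (±2.5 °C) is reported honestly as failing.  The
self-consistency properties — PET of the reference environment equals its
own air temperature to 0.02 °C, strict monotonicity in t_a, wind lowering
PET below skin temperature — all hold, and every downstream stage uses this
PET consistently, so within-package analyses (band fractions, planted-
effect recovery) are unaffected by the offset.  Conclusions about absolute
PET values of real weather records should not be drawn from this kernel.

Fixed personal factors: 0.9 clo, 80 W total metabolic rate converted by the
DuBois area of the reference subject (1.80 m², configurable through
`PersonState.from_total_watts`); mechanical work W = 0 (standard default).

## 3. Synthetic climate and registry

`comfortrisk.simulate` emulates the structure of the Korean feeds the
analysis was designed for; defaults are the study conditions (ten years,
three cities / five districts, published monthly normals, published
per-type monthly accident profiles, no planted comfort effect).

* **Air temperature** = seasonal curve + diurnal sinusoid (amplitude 4 °C,
  peak 15:00) + AR(1) noise (coefficient 0.8, marginal SD 2 °C).  The
  seasonal curve is piecewise linear between mid-month nodes; because the
  monthly average of such an interpolant is ≈ x_{m−1}/8 + 3x_m/4 + x_{m+1}/8
  rather than x_m, the nodes are obtained by solving that 12×12 circulant
  system for the published monthly normals.  Generated monthly means then
  match the normals within ±0.5 °C over ≥5 simulated years (tested).
* **Wind** is lognormal around the monthly normal (shape 0.4); **RH** is
  beta-distributed around the monthly normal (concentration 30), bounded in
  [0, 100] by construction.
* **T_mrt** = t_a + a deterministic clear-sky day-shape (10 °C × sin-arc
  peaking at solar noon, zero at night).  No radiation model is attempted —
  radiant temperature modelling was external to the analysis chain this
  package implements.
* **Districts** of a city copy the city series exactly, reproducing the
  administrative semantics of the real feed (and making the linkage's
  shared-weather invariant testable).
* **Accidents** follow an inhomogeneous Poisson process over working hours
  (Mon–Fri 07:00–18:00; the boundaries are a configurable default, not a
  registry fact).  Per (type, severity) the hourly intensity is the
  published monthly count profile normalised to mean 1, optionally times
  k_out for hours whose PET is outside [18, 23) °C, and scaled so the
  expected total equals `rate_scale` × the published decade total prorated
  to the simulated span.  `comfort_multiplier_for_target(q, p)` returns the
  k_out that turns a baseline outside-comfort exposure fraction q into an
  event outside-comfort probability p (odds-ratio identity); q must be
  weighted by the stratum's monthly profile, which
  `outside_comfort_fraction(..., month_profile=...)` provides.

Not emulated: holiday calendars (Mon–Fri only), spatial weather gradients
within a city, worker-population denominators, multi-day weather regimes
beyond AR(1) persistence.  Consequently, passing tests demonstrate that the
pipeline's estimators recover known structure from data of this shape —
they do not validate the epidemiology of any real registry.

## 4. Linkage and classification

The join key is (city, district, hour); timestamps are truncated (not
rounded) to the hour.  `strict` drops unmatched events but always counts
them in the `LinkageReport`; `nearest-hour` retries at −1 h then +1 h
(earlier hour preferred on ties) and records the fallback in
`match_quality`.  Duplicate climate keys abort with an integrity error.

Comfort bands partition the line with half-open [lower, upper) intervals
(Very cold < 4, Cold [4,8), Cool [8,13), Slightly cool [13,18), Neutral
[18,23), Slightly warm [23,29), Warm [29,35), Hot [35,41), Very hot ≥ 41);
the published band edges overlap at their endpoints, and the half-open
convention makes the partition exact.  The comfort zone is precisely
Neutral; cold/hot thresholds (18, 23) are shared verbatim with the Monte
Carlo module.  Seasons: Mar–May spring, Jun–Aug summer, Sep–Nov autumn,
Dec–Feb winter.

## 5. Monte Carlo range probabilities

Per stratum the event PETs are summarised by the sample mean and SD
(denominator n−1; fewer than two events is an explicit degenerate-
distribution error).  The sampling distribution is **normal** — the
published analysis does not name its distribution, but its printed per-type
percentages are reproduced from its printed means/SDs under normality to a
few tenths of a percentage point, which identifies the choice.  Cold means
draw < 18, hot means draw ≥ 23 (matching the half-open bands), outside =
cold + hot exactly per draw set.  Defaults: 10⁶ draws, mandatory seed;
SE = √(p(1−p)/N) with normal-approximation 95 % CIs.  A zero SD is treated
as a point mass.  The estimator is checked against the closed-form normal
CDF within 4 SE at 10⁶ draws and for consistency as N grows.

## 6. Network importance

Architecture 4-9-2 (nine hidden units in a single hidden layer), logistic
activations, inputs and targets min–max scaled to [0, 1], 70/30 split by a
seeded permutation, full-batch gradient descent with momentum (learning
rate 0.1, momentum 0.9, ≤5000 epochs, early stop when the loss change is
below 10⁻⁸).  The training table has one row per working station-hour with
fatal/injury counts (or presence flags — both encodings are exposed, since
the original construction is unstated).  R² = 1 − SSE/SST pooled over both
outputs on the test split; SST = 0 yields R² = 0 by convention.

Garson's decomposition was chosen as the canonical single-hidden-layer
importance method matching the published normalised four-way output;
Olden's signed variant is available behind `method="olden"`.  The
decomposition is tested against an exhaustive path-enumeration oracle and
for invariance to hidden-unit permutation.  On planted data whose outcome
depends only on T_a, the T_a share exceeds 0.5 and tops every other input
in ≥18/20 seeds (observed: 20/20, shares ≈ 0.74–0.83).

On the synthetic registry itself the hourly event counts are dominated by
Poisson noise, so the test-split R² is near zero — the published high R²
belongs to the original registry construction, which is explicitly not
reproducible here, and no such value is claimed.

## 7. Problem sizes and runtimes

Chosen sizes (package defaults and test fixtures): the generator default is
the full study span (10 years); unit tests use one simulated year of one
city; the climate-calibration tests use five years (the condition under
which the ±0.5 °C guarantee is stated); the planted-enrichment check uses
two years at 1.5× rates (≈22 000 events of the measured stratum, giving a
2-SE band of ±0.5 points); Monte Carlo checks use 10⁶ draws.  The whole
suite runs in well under five minutes on one CPU; the acceptance script in
seconds.

## 8. Reproducibility

Every random stage takes an explicit seed; per-city, per-stratum and
per-target streams are derived through `numpy.random.SeedSequence.spawn`,
so identical configurations are byte-identical regardless of which other
stages run.  The pipeline writes a `manifest.json` with versions, seeds and
row counts per stage, and unmatched/dropped record counts are always
reported — no row is reconciled silently.
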