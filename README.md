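# comfortrisk

Outdoor thermal comfort and construction-accident risk analysis.

Construction work happens outdoors in all four seasons, and injury and
fatality rates vary with the weather the workers are exposed to.  This
package implements, as a tested and reusable pipeline, an analysis of that
relationship built on the **physiological equivalent temperature (PET)**:
it links accident records to hourly district-level weather, computes each
event's PET, classifies events into thermal comfort bands, estimates by
Monte Carlo simulation the probability that each accident type occurs in
cold / hot / outside-comfort conditions, and ranks the four environmental
inputs of PET (air temperature T_a, mean radiant temperature T_mrt, wind
speed v, relative humidity RH) with a neural-network connection-weight
decomposition.  Because the underlying Korean registry and weather feeds
are not public, a first-class synthetic generator reproduces their
statistical structure (monsoon seasonal cycle, district-shared station
weather, an 18-type accident taxonomy with seasonal rate profiles) so that
every stage is testable end to end.

It is aimed at occupational-safety researchers and epidemiologists who want
a transparent, scriptable implementation of this analysis chain.

## The model

**PMV** (predicted mean vote) is Fanger's steady-state heat-balance index:
the thermal load *L* on the body is metabolic heat production *M − W* minus
six loss pathways (skin vapour diffusion, sweat evaporation, latent and
sensible respiration, radiation through the clothing surface, convection),
and PMV = (0.303 e^(−0.036M) + 0.028) · L.  The clothing surface
temperature t_cl is implicit (it feeds the radiative and convective losses
and the convective coefficient h_c = max(2.38 |t_cl − t_a|^0.25,
12.1 √v)) and is solved iteratively.

**PET** is the air temperature of a standardized reference environment
(T_mrt = T_a, v = 0.1 m/s, vapour pressure 1200 Pa) in which a reference
subject (0.9 clo, 80 W) experiences the same thermal load as in the actual
outdoor environment; here it is found by bisection on the reference air
temperature using the PMV body model for the load on both sides.  This is a
deliberate single-node approximation to the two-node physiological models
behind dedicated PET software; its behaviour and limits are quantified in
[docs/methods.md](docs/methods.md).

PET in **[18, 23) °C** is the comfort range; below 18 °C is the cold range,
at or above 23 °C the hot range.  Per accident type, the PET at event time
is summarised by its mean μ and standard deviation σ, and the probability
of an event occurring in each range is estimated from N normal draws as
E(X) ≈ (1/N) Σ x_n with x_n the range indicator.

Relative importance uses a 4-9-2 logistic network (inputs T_a, T_mrt, v,
RH; outputs fatal and injury counts per working station-hour; 70/30
train/test split) and Garson's decomposition
Q_i = Σ_h Σ_o (|w_ih| / Σ_k |w_kh|) · |v_ho|, normalised to Σ_i Q_i = 1.

## Worked example

Estimate the range probabilities for the most frequent accident type,
"fall", from its published PET parameters (mean 16.45 °C, SD 13.71 °C):

```sh
$ printf 'accident_type,severity,mean,std\nfall,fatal,16.45,13.71\n' > params.csv
$ comfortrisk mcs --params params.csv --n 1000000 --seed 5 --out mcs.csv
accident_type severity  mean   std  p_cold_pct  p_hot_pct  p_outside_pct ...
         fall    fatal 16.45 13.71     54.4787     31.648        86.1267 ...
```

Reading: a fall-type accident has a 54.5 % probability of occurring in the
cold range, 31.6 % in the hot range, hence 86.1 % outside the 18–23 °C
comfort range — accidents of this type overwhelmingly happen in thermally
uncomfortable conditions.

The full synthetic study is the numbered scripts under `analysis/`
(simulate → link → classify → Monte Carlo → importance), each a thin driver
over the library that prints what it found and writes its tables under
`results/analysis/`:

```sh
python analysis/01_simulate_registry.py
python analysis/02_link_events.py
...
```

The same stages are available as `comfortrisk simulate|pet|link|analyze|
mcs|importance|run` subcommands (CSV schemas in
[docs/formats.md](docs/formats.md)).

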