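# File formats

All files are UTF-8 CSV with a header row and `.` as the decimal mark.
Timestamps are ISO-8601 at hourly resolution (`YYYY-MM-DD HH:00:00`).

## climate.csv  (simulate → link, importance)

| column    | type  | meaning                                   |
|-----------|-------|-------------------------------------------|
| city      | str   | administrative city                       |
| district  | str   | district within the city                  |
| timestamp | datetime | station-hour                           |
| ta        | float | air temperature, °C                       |
| tmrt      | float | mean radiant temperature, °C              |
| v         | float | wind speed, m/s                           |
| rh        | float | relative humidity, % (0–100)              |

One row per (city, district, hour); districts of a city carry identical
weather at the same hour.

## accidents.csv  (simulate → link)

| column        | type  | meaning                               |
|---------------|-------|----------------------------------------|
| city          | str   |                                        |
| district      | str   |                                        |
| timestamp     | datetime | event hour                          |
| accident_type | str   | one of the 18 taxonomy labels          |
| severity      | str   | `fatal` or `injury`                    |

## linked.csv  (link → analyze, mcs, importance)

All accident columns, the matched climate fields (`ta,tmrt,v,rh`), plus:

| column        | type  | meaning                                    |
|---------------|-------|---------------------------------------------|
| match_quality | str   | `exact` or `nearest-hour`                   |
| pet           | float | physiological equivalent temperature, °C    |
| comfort_band  | str   | one of the nine thermal-perception bands    |
| zone          | str   | `cold` / `comfort` / `hot`                  |
| season        | str   | `winter` / `spring` / `summer` / `autumn`   |

## PET batch mode (`comfortrisk pet`)

Input columns `ta,tmrt,v,rh`; output adds `pa` (Pa), `pmv`, `tcl` (°C),
`pet` (°C).

## params CSV (`comfortrisk mcs --params`)

Columns `accident_type,severity,mean,std` — per-stratum PET mean and
standard deviation in °C, letting the Monte Carlo stage run without any
registry.

## mcs output

`accident_type, severity, mean, std, p_cold_pct, p_hot_pct, p_outside_pct,
se_outside_pct, n_draws, seed` — percentages on 0–100.

## importance output

`variable, importance` (Garson shares summing to 1), with a sidecar JSON
carrying the network weights, R², epochs and spec for audit.

## run.yaml (`comfortrisk run --config`)

```yaml
generator:            # GeneratorConfig fields
  years: 10
  seed: 1
  rate_scale: 1.0
  layout: {Seoul: [Jung-gu, Gangbuk-gu]}
linkage_policy: strict   # or nearest-hour
mcs_draws: 1000000
mcs_seed: 1
network:              # NetworkSpec fields
  seed: 1
params_file: null     # optional params CSV for the MCS stage
```

Thermal-comfort constants (body surface area, total metabolic watts, clo,
the PET reference environment `v` and `pa`, solver tolerances) are exposed
through `PersonState.from_total_watts(...)` and `PETConfig(...)` and can be
passed to `GeneratorConfig(person=..., pet_config=...)`.
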