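"""Synthetic climate feed and accident registry generator.

Emulates the statistical structure of the data the analysis pipeline
consumes: an hourly district-level weather feed with the monsoon seasonal
cycle of South Korea, and an accident registry whose event rate varies by
accident type, season, and (optionally) by whether the hour's PET falls
outside the 18-23 degC comfort range.

Climate model
-------------
Air temperature is a mean-preserving piecewise-linear seasonal curve through
the published monthly normals, plus a diurnal sinusoid (default amplitude
4 degC, warmest at 15:00) and AR(1) noise (coefficient 0.8).  Monthly means
of the generated series match the published normals within the stated
+/-0.5 degC over five or more simulated years.  Wind is lognormal around the
monthly normal, relative humidity is beta-distributed around the monthly
normal, and the mean radiant temperature is air temperature plus a
deterministic clear-sky daytime offset (default +10 degC at solar noon,
zero at night).  All districts of a city share the city's series, matching
the administrative semantics of the real feed.

Accident model
--------------
Events are drawn from an inhomogeneous Poisson process over working hours
(default 07:00-18:00, Monday-Friday).  Per (type, severity) the hourly
intensity is proportional to the published monthly count profile of that
stratum, optionally multiplied by ``comfort_multiplier`` (k_out) in hours
whose PET lies outside the comfort range; intensities are normalised so the
expected event total equals ``rate_scale`` times the published decade total
prorated to the simulated span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .comfort import PETConfig, PersonState, REFERENCE_PERSON, pet_from_values

COMFORT_LO = 18.0
COMFORT_HI = 23.0


class ValidationError(ValueError):
    pass


def _default_layout() -> dict[str, tuple[str, ...]]:
    return {
        "Seoul": ("Gangbuk-gu", "Jung-gu", "Gangseo-gu"),
        "Incheon": ("Nam-gu",),
        "Cheongju": ("Sangdang-gu",),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic registry; defaults are the study
    conditions (ten years, published monthly climate normals and per-type
    accident counts, no planted comfort effect)."""

    start_year: int = 2007
    years: int = 10
    layout: dict[str, tuple[str, ...]] = field(default_factory=_default_layout)
    seed: int = 0
    monthly_ta: np.ndarray = field(default_factory=lambda: reference.MONTHLY_TA.copy())
    monthly_wind: np.ndarray = field(default_factory=lambda: reference.MONTHLY_WIND.copy())
    monthly_rh: np.ndarray = field(default_factory=lambda: reference.MONTHLY_RH.copy())
    diurnal_amplitude: float = 4.0   # degC
    ar1_coeff: float = 0.8
    noise_sd: float = 2.0            # degC, marginal sd of the AR(1) noise
    wind_sigma: float = 0.4          # lognormal shape
    rh_concentration: float = 30.0   # beta concentration
    radiant_offset: float = 10.0     # degC added to ta at solar noon
    rate_scale: float = 1.0
    comfort_multiplier: float = 1.0  # k_out: intensity factor outside comfort
    working_hours: tuple[int, int] = (7, 18)  # [start, end) local hours
    person: PersonState = REFERENCE_PERSON
    pet_config: PETConfig = field(default_factory=PETConfig)

    def __post_init__(self):
        if not self.layout:
            raise ValidationError("layout must contain at least one city")
        if self.years < 1:
            raise ValidationError("years must be >= 1")
        if self.rate_scale < 0 or self.comfort_multiplier < 0:
            raise ValidationError("rates must be non-negative")


def _seasonal_nodes(monthly_means: np.ndarray) -> np.ndarray:
    """Mid-month node values whose piecewise-linear interpolant has the
    given monthly means.

    Averaging a linear interpolant of mid-month nodes over month m yields
    approximately x_{m-1}/8 + 3 x_m/4 + x_{m+1}/8 (equal month lengths), so
    the nodes solve the corresponding circulant system.
    """
    a = np.zeros((12, 12))
    for m in range(12):
        a[m, (m - 1) % 12] = 1 / 8
        a[m, m] = 3 / 4
        a[m, (m + 1) % 12] = 1 / 8
    return np.linalg.solve(a, np.asarray(monthly_means, dtype=float))


def _seasonal_curve(ts: pd.DatetimeIndex, monthly_means: np.ndarray) -> np.ndarray:
    """Evaluate the mean-preserving seasonal interpolant at each timestamp."""
    nodes = _seasonal_nodes(monthly_means)
    years = range(ts[0].year - 1, ts[-1].year + 2)
    node_times = pd.DatetimeIndex(
        [pd.Timestamp(year=y, month=m + 1, day=15, hour=12) for y in years
         for m in range(12)]
    )
    node_vals = np.tile(nodes, len(list(years)))
    return np.interp(ts.asi8, node_times.asi8, node_vals)


def _city_weather(ts: pd.DatetimeIndex, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    n = len(ts)
    hour = ts.hour.to_numpy()
    month = ts.month.to_numpy() - 1

    base = _seasonal_curve(ts, cfg.monthly_ta)
    diurnal = cfg.diurnal_amplitude * np.cos(2 * np.pi * (hour - 15) / 24.0)
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar1_coeff**2)
    innov = rng.normal(0.0, innov_sd, size=n)
    from scipy.signal import lfilter
    noise = lfilter([1.0], [1.0, -cfg.ar1_coeff], innov)
    ta = base + diurnal + noise

    wind_mean = cfg.monthly_wind[month]
    mu = np.log(wind_mean) - cfg.wind_sigma**2 / 2.0
    v = rng.lognormal(mean=mu, sigma=cfg.wind_sigma)

    rh_mean = np.clip(cfg.monthly_rh[month] / 100.0, 1e-3, 1 - 1e-3)
    alpha = rh_mean * cfg.rh_concentration
    beta = (1.0 - rh_mean) * cfg.rh_concentration
    rh = np.clip(100.0 * rng.beta(alpha, beta, size=n), 0.0, 100.0)

    solar = np.maximum(0.0, np.sin(np.pi * (hour - 6) / 12.0))
    solar[(hour < 6) | (hour > 18)] = 0.0
    tmrt = ta + cfg.radiant_offset * solar

    return pd.DataFrame(
        {"timestamp": ts, "ta": ta, "tmrt": tmrt, "v": v, "rh": rh}
    )


def generate_climate(config: GeneratorConfig) -> pd.DataFrame:
    """Hourly ClimateRecord frame: columns city, district, timestamp, ta,
    tmrt, v, rh; one row per (city, district, hour), districts of a city
    sharing the city series."""
    ts = pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.years}-01-01",
        freq="h",
        inclusive="left",
    )
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.layout))
    frames = []
    for (city, districts), child in zip(sorted(config.layout.items()), children):
        wx = _city_weather(ts, config, np.random.default_rng(child))
        for district in districts:
            f = wx.copy()
            f.insert(0, "district", district)
            f.insert(0, "city", city)
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


def working_hour_mask(ts: pd.DatetimeIndex,
                      working_hours: tuple[int, int] = (7, 18)) -> np.ndarray:
    """True for Monday-Friday hours in [start, end)."""
    lo, hi = working_hours
    return np.asarray((ts.dayofweek < 5) & (ts.hour >= lo) & (ts.hour < hi))


def _city_hours(climate: pd.DataFrame) -> pd.DataFrame:
    """One row per (city, hour) with the shared weather fields."""
    return (
        climate.drop_duplicates(subset=["city", "timestamp"])
        .loc[:, ["city", "timestamp", "ta", "tmrt", "v", "rh"]]
        .reset_index(drop=True)
    )


def hourly_pet(climate: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """PET per (city, hour); computed once per city series, not per district."""
    hours = _city_hours(climate)
    hours["pet"] = pet_from_values(
        hours["ta"].to_numpy(), hours["tmrt"].to_numpy(),
        hours["v"].to_numpy(), hours["rh"].to_numpy(),
        person=config.person, config=config.pet_config,
    )
    return hours


def outside_comfort_fraction(
    climate: pd.DataFrame,
    config: GeneratorConfig,
    month_profile: np.ndarray | None = None,
) -> float:
    """Fraction of working station-hours whose PET lies outside 18-23 degC.

    With ``month_profile`` (12 weights) the fraction is weighted by the
    hour's month — the baseline exposure seen by an accident stratum with
    that seasonal intensity profile.
    """
    hours = hourly_pet(climate, config)
    ts = pd.DatetimeIndex(hours["timestamp"])
    mask = working_hour_mask(ts, config.working_hours)
    p = hours.loc[mask, "pet"].to_numpy()
    outside = (p < COMFORT_LO) | (p >= COMFORT_HI)
    if month_profile is None:
        return float(outside.mean())
    w = np.asarray(month_profile, dtype=float)[ts.month.to_numpy()[mask] - 1]
    return float(np.sum(outside * w) / np.sum(w))


def comfort_multiplier_for_target(q: float, p: float) -> float:
    """k_out that turns a baseline outside-comfort hour fraction q into an
    event outside-comfort probability p: k = p(1-q) / (q(1-p))."""
    if not 0 < q < 1 or not 0 < p < 1:
        raise ValidationError("q and p must lie strictly inside (0, 1)")
    return p * (1.0 - q) / (q * (1.0 - p))


def generate_accidents(climate: pd.DataFrame,
                       config: GeneratorConfig) -> pd.DataFrame:
    """AccidentRecord frame: columns city, district, timestamp,
    accident_type, severity; inhomogeneous Poisson over working hours."""
    hours = _city_hours(climate)
    ts = pd.DatetimeIndex(hours["timestamp"])
    mask = working_hour_mask(ts, config.working_hours)
    work = hours.loc[mask].reset_index(drop=True)
    if len(work) == 0:
        raise ValidationError("climate coverage contains no working hours")
    month = pd.DatetimeIndex(work["timestamp"]).month.to_numpy() - 1

    if config.comfort_multiplier != 1.0:
        petv = pet_from_values(
            work["ta"].to_numpy(), work["tmrt"].to_numpy(),
            work["v"].to_numpy(), work["rh"].to_numpy(),
            person=config.person, config=config.pet_config,
        )
        outside = (petv < COMFORT_LO) | (petv >= COMFORT_HI)
        comfort_w = np.where(outside, config.comfort_multiplier, 1.0)
    else:
        comfort_w = np.ones(len(work))

    districts = {c: list(d) for c, d in config.layout.items()}
    cities = work["city"].to_numpy()

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
        len(config.layout) + 1)[-1])
    span_years = config.years
    frames = []
    for atype in reference.ACCIDENT_TYPES:
        for severity in reference.SEVERITIES:
            counts = np.asarray(reference.MONTHLY_COUNTS[atype][severity],
                                dtype=float)
            expected_total = (
                config.rate_scale * counts.sum() * span_years / 10.0
            )
            if expected_total == 0:
                continue
            month_profile = counts / counts.mean() if counts.sum() > 0 else counts
            w = month_profile[month] * comfort_w
            if w.sum() == 0:
                continue
            lam = expected_total * w / w.sum()
            n = rng.poisson(lam)
            idx = np.repeat(np.arange(len(work)), n)
            if len(idx) == 0:
                continue
            ev = pd.DataFrame(
                {
                    "city": cities[idx],
                    "timestamp": work["timestamp"].to_numpy()[idx],
                    "accident_type": atype,
                    "severity": severity,
                }
            )
            ev["district"] = [
                districts[c][k] for c, k in zip(
                    ev["city"],
                    rng.integers(0, [len(districts[c]) for c in ev["city"]]),
                )
            ]
            frames.append(ev)

    if not frames:
        return pd.DataFrame(
            columns=["city", "district", "timestamp", "accident_type", "severity"]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.loc[:, ["city", "district", "timestamp", "accident_type", "severity"]]
    return out.sort_values(["timestamp", "city", "district", "accident_type",
                            "severity"], kind="mergesort").reset_index(drop=True)


def scaled_config(config: GeneratorConfig, **overrides) -> GeneratorConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
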