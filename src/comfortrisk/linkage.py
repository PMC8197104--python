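"""Administrative record linkage of accident events to station-hour weather.

Each accident is joined to the climate record of its (city, district, hour);
districts of a city share the city's weather at a given hour, so the join is
purely administrative (no geodesic search).  Timestamps are truncated, not
rounded, to the hour.  Under the ``nearest-hour`` policy an unmatched event
may fall back to the record one hour earlier, then one hour later (the
earlier hour wins ties); under ``strict`` unmatched events are dropped from
the linked output but always counted and reported — the pipeline never drops
rows silently.

Linked events carry the computed PET, comfort band, zone and season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import classify_pet, season_of, zone_of
from .comfort import PETConfig, PersonState, REFERENCE_PERSON, pet_from_values

KEY = ["city", "district", "timestamp"]
CLIMATE_FIELDS = ["ta", "tmrt", "v", "rh"]


class IntegrityError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class LinkageReport:
    n_accidents: int
    n_linked: int
    n_exact: int
    n_nearest: int
    n_unmatched: int
    unmatched: pd.DataFrame

    def __post_init__(self):
        assert self.n_linked + self.n_unmatched == self.n_accidents


def _check_schema(frame: pd.DataFrame, required: list[str], name: str):
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{name} is missing columns {missing}")


def link(
    accidents: pd.DataFrame,
    climate: pd.DataFrame,
    policy: str = "strict",
    person: PersonState = REFERENCE_PERSON,
    pet_config: PETConfig = PETConfig(),
) -> tuple[pd.DataFrame, LinkageReport]:
    """Join accidents to climate on (city, district, hour) and compute PET.

    Returns ``(linked, report)``; ``linked`` holds one row per matched
    accident with the weather fields, ``pet``, ``comfort_band``, ``zone``,
    ``season`` and ``match_quality`` (exact | nearest-hour).
    """
    if policy not in ("strict", "nearest-hour"):
        raise ValidationError(f"unknown policy {policy!r}")
    _check_schema(accidents, KEY + ["accident_type", "severity"], "accidents")
    _check_schema(climate, KEY + CLIMATE_FIELDS, "climate")

    acc = accidents.copy()
    acc["timestamp"] = pd.DatetimeIndex(acc["timestamp"]).floor("h")
    clim = climate.loc[:, KEY + CLIMATE_FIELDS].copy()
    clim["timestamp"] = pd.DatetimeIndex(clim["timestamp"])

    dup = clim.duplicated(subset=KEY)
    if dup.any():
        raise IntegrityError(
            f"{int(dup.sum())} duplicate climate keys (city, district, hour)"
        )

    merged = acc.merge(clim, on=KEY, how="left", sort=False)
    matched = merged[CLIMATE_FIELDS[0]].notna().to_numpy()
    merged["match_quality"] = np.where(matched, "exact", "unmatched")

    if policy == "nearest-hour":
        for offset, _pref in ((-1, "earlier"), (1, "later")):
            todo = merged["match_quality"].to_numpy() == "unmatched"
            if not todo.any():
                break
            shifted = merged.loc[todo, KEY + ["accident_type", "severity"]].copy()
            shifted["timestamp"] = shifted["timestamp"] + pd.Timedelta(hours=offset)
            refill = shifted.loc[:, KEY].merge(clim, on=KEY, how="left",
                                               sort=False)
            hit = refill[CLIMATE_FIELDS[0]].notna().to_numpy()
            rows = np.flatnonzero(todo)[hit]
            merged.loc[rows, CLIMATE_FIELDS] = refill.loc[hit,
                                                          CLIMATE_FIELDS].to_numpy()
            merged.loc[rows, "match_quality"] = "nearest-hour"

    is_linked = merged["match_quality"].to_numpy() != "unmatched"
    unmatched = merged.loc[~is_linked, acc.columns].reset_index(drop=True)
    linked = merged.loc[is_linked].reset_index(drop=True)

    if len(linked):
        linked["pet"] = pet_from_values(
            linked["ta"].to_numpy(), linked["tmrt"].to_numpy(),
            linked["v"].to_numpy(), linked["rh"].to_numpy(),
            person=person, config=pet_config,
        )
        linked["comfort_band"] = classify_pet(linked["pet"].to_numpy())
        linked["zone"] = zone_of(linked["pet"].to_numpy())
        linked["season"] = season_of(
            pd.DatetimeIndex(linked["timestamp"]).month.to_numpy()
        )
    else:
        for col in ("pet", "comfort_band", "zone", "season"):
            linked[col] = pd.Series(dtype=float if col == "pet" else object)

    n_exact = int((linked["match_quality"] == "exact").sum())
    n_nearest = int((linked["match_quality"] == "nearest-hour").sum())
    report = LinkageReport(
        n_accidents=len(acc),
        n_linked=len(linked),
        n_exact=n_exact,
        n_nearest=n_nearest,
        n_unmatched=len(unmatched),
        unmatched=unmatched,
    )
    return linked, report
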