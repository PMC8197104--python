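"""Season and PET comfort-band classification, and event cross-tabulation.

The nine thermal-perception bands partition the real line with half-open
``[lower, upper)`` intervals (the published band edges overlap at their
endpoints; the half-open convention makes the partition exact).  The
comfort zone is exactly PET in [18, 23); everything below is the cold zone
and everything at or above 23 the hot zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import ACCIDENT_TYPES, SEVERITIES


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ComfortBand:
    label: str
    lower: float  # inclusive, degC
    upper: float  # exclusive, degC
    zone: str     # cold | comfort | hot


COMFORT_BANDS: tuple[ComfortBand, ...] = (
    ComfortBand("Very cold", -np.inf, 4.0, "cold"),
    ComfortBand("Cold", 4.0, 8.0, "cold"),
    ComfortBand("Cool", 8.0, 13.0, "cold"),
    ComfortBand("Slightly cool", 13.0, 18.0, "cold"),
    ComfortBand("Neutral", 18.0, 23.0, "comfort"),
    ComfortBand("Slightly warm", 23.0, 29.0, "hot"),
    ComfortBand("Warm", 29.0, 35.0, "hot"),
    ComfortBand("Hot", 35.0, 41.0, "hot"),
    ComfortBand("Very hot", 41.0, np.inf, "hot"),
)

_EDGES = np.array([b.lower for b in COMFORT_BANDS[1:]])  # interior edges

SEASONS = ("winter", "spring", "summer", "autumn")
_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def classify_pet(pet_value):
    """ComfortBand for a scalar PET, or band-label array for array input."""
    arr = np.asarray(pet_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("PET must be finite")
    idx = np.searchsorted(_EDGES, arr, side="right")
    if arr.ndim == 0:
        return COMFORT_BANDS[int(idx)]
    labels = np.array([b.label for b in COMFORT_BANDS])
    return labels[idx]


def zone_of(pet_value):
    """cold / comfort / hot zone label(s) for PET value(s)."""
    arr = np.asarray(pet_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("PET must be finite")
    zones = np.where(arr < 18.0, "cold", np.where(arr < 23.0, "comfort", "hot"))
    return str(zones) if arr.ndim == 0 else zones


def season_of(month):
    """Meteorological season of a calendar month (1-12); array-capable."""
    arr = np.asarray(month)
    if np.any((arr < 1) | (arr > 12)):
        raise ValidationError("month must lie in 1..12")
    if arr.ndim == 0:
        return _MONTH_SEASON[int(arr)]
    lut = np.array([_MONTH_SEASON[m] for m in range(1, 13)])
    return lut[arr - 1]


@dataclass(frozen=True)
class CrossTab:
    """Integer contingency table of classified events."""

    axes: tuple[str, ...]
    table: pd.DataFrame  # long form: axis columns + 'count'

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def pivot(self) -> pd.DataFrame:
        if len(self.axes) == 1:
            return self.table.set_index(self.axes[0])["count"]
        return self.table.pivot_table(
            index=list(self.axes[:-1]), columns=self.axes[-1],
            values="count", fill_value=0, aggfunc="sum",
        )


def crosstab(events: pd.DataFrame, axes: tuple[str, ...]) -> CrossTab:
    """Exact counts of events per cell of the requested axes.

    Recognised axes are any event columns plus the derived ``month``,
    ``season``, ``comfort_band`` and ``zone`` (the latter two require a
    ``pet`` column).  Unknown accident-type labels raise with the offending
    values listed.
    """
    if "accident_type" in events.columns and len(events):
        bad = sorted(set(events["accident_type"]) - set(ACCIDENT_TYPES))
        if bad:
            raise ValidationError(f"unknown accident types: {bad}")
    if "severity" in events.columns and len(events):
        bad = sorted(set(events["severity"]) - set(SEVERITIES))
        if bad:
            raise ValidationError(f"unknown severities: {bad}")

    df = events.copy()
    if len(df):
        ts = pd.DatetimeIndex(df["timestamp"]) if "timestamp" in df else None
        if "month" in axes and "month" not in df:
            df["month"] = ts.month
        if "season" in axes and "season" not in df:
            df["season"] = season_of(ts.month.to_numpy())
        if "comfort_band" in axes and "comfort_band" not in df:
            df["comfort_band"] = classify_pet(df["pet"].to_numpy())
        if "zone" in axes and "zone" not in df:
            df["zone"] = zone_of(df["pet"].to_numpy())
    else:
        for ax in axes:
            if ax not in df.columns:
                df[ax] = pd.Series(dtype=object)

    counts = (
        df.groupby(list(axes), observed=False).size().rename("count").reset_index()
        if len(df)
        else pd.DataFrame({ax: pd.Series(dtype=object) for ax in axes}
                          | {"count": pd.Series(dtype=int)})
    )
    return CrossTab(axes=tuple(axes), table=counts)
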