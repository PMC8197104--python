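#!/usr/bin/env python
"""Cross-tabulate linked events by month, season and PET comfort band.

Produces the monthly type-by-severity table and the comfort-band
type-by-severity table, plus simple bar charts of the monthly and band-wise
event totals.
"""

import sys
from pathlib import Path

import pandas as pd

from comfortrisk.classification import COMFORT_BANDS, crosstab

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> int:
    linked = pd.read_csv(SCRATCH / "linked.csv")
    monthly = crosstab(linked, ("month", "accident_type", "severity"))
    bands = crosstab(linked, ("comfort_band", "accident_type", "severity"))
    seasons = crosstab(linked, ("season", "severity"))
    monthly.table.to_csv(RESULTS / "03_monthly_counts.csv", index=False)
    bands.table.to_csv(RESULTS / "03_band_counts.csv", index=False)
    seasons.table.to_csv(RESULTS / "03_season_counts.csv", index=False)

    top = (monthly.table.groupby("accident_type")["count"].sum()
           .sort_values(ascending=False))
    month_totals = monthly.table.groupby("month")["count"].sum()
    print(f"classified {monthly.total:,} events")
    print(f"most frequent accident type: {top.index[0]} ({top.iloc[0]:,})")
    print(f"busiest month: {int(month_totals.idxmax())} "
          f"({month_totals.max():,} events)")
    band_totals = (bands.table.groupby("comfort_band")["count"].sum()
                   .reindex([b.label for b in COMFORT_BANDS], fill_value=0))
    print("events per comfort band:")
    print(band_totals.to_string())

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = RESULTS / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        month_totals.plot.bar(ax=axes[0], color="#1f77b4")
        axes[0].set_title("Events per month")
        band_totals.plot.bar(ax=axes[1], color="#d62728")
        axes[1].set_title("Events per PET comfort band")
        for ax in axes:
            ax.tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(figdir / "03_counts.png", dpi=120)
        print(f"figure: {figdir / '03_counts.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped figures")
    return 0


if __name__ == "__main__":
    sys.exit(main())
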