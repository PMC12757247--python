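#!/usr/bin/env python
"""Synthesize the trial-period weather series.

Generates a seeded daily external weather season (May-August) from the
pooled monthly statistics of the Wanju site, plus direct in-greenhouse
series for both temperature regimes, and writes them under results/
together with the monthly-statistics table used.
"""

import argparse
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from ghtomato.weather_synth import (external_to_frame, generate_external_series,
                                    greenhouse_monthly_stats,
                                    greenhouse_series_from_stats,
                                    outside_monthly_stats, stats_to_frame)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

stats = outside_monthly_stats()
stats_to_frame(stats).to_csv(args.out / "monthly_stats_external.csv", index=False)

ext = generate_external_series(stats, date(2022, 5, 1), date(2022, 8, 31),
                               seed=args.seed)
external_to_frame(ext).to_csv(args.out / "weather_external.csv", index=False)
print(f"external season: {len(ext)} days, "
      f"mean tmax {np.mean([d.tmax for d in ext]):.2f} C, "
      f"mean sr {np.mean([d.sr for d in ext]):.2f}")

for regime in ("control", "heat"):
    gh = greenhouse_series_from_stats(greenhouse_monthly_stats(regime),
                                      date(2022, 5, 1), date(2022, 8, 31),
                                      seed=args.seed, regime=regime)
    df = pd.DataFrame([dict(date=d.date.isoformat(), sr=d.sr, rh=d.rh,
                            tmax=d.tmax, tmin=d.tmin) for d in gh])
    df.to_csv(args.out / f"weather_greenhouse_{regime}.csv", index=False)
    over40 = sum(d.tmax > 40 for d in gh)
    print(f"{regime} house: mean tmax {df.tmax.mean():.2f} C, "
          f"{over40} days above 40 C")
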