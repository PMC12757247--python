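"""Synthetic daily weather matching the Wanju trial statistics.

The greenhouse trials (Wanju, Republic of Korea; May-August of 2022 and
2023) published only *summary* weather: monthly means of the six external
variables, and season-level means +/- SD of greenhouse maximum/minimum
temperature and humidity per treatment. This module turns those summaries
into daily series:

* each day's value for each variable is drawn independently from a normal
  distribution truncated at physical bounds (rh in [0,1]; radiation,
  precipitation and wind nonnegative), centred on that month's mean;
* where a printed SD exists (temperatures, humidity) it is used; otherwise
  a coefficient of variation of 0.25 supplies realistic day-to-day spread;
* tmax/tmin draws that cross are swapped so tmax >= tmin always holds;
* one global seed fans out into an independent substream per variable, so
  adding a variable never perturbs the others.

No autocorrelation or cross-correlation is modelled: the printed statistics
constrain only the marginals, and the downstream crop model consumes days
independently. Scenario warming is applied as per-month additive offsets to
tmax/tmin via :func:`apply_scenario`.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, replace
from datetime import date as Date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gh_climate import SR_TRANSMISSION, GreenhouseWeatherDay

log = logging.getLogger(__name__)

VARIABLES = ("sr", "rh", "tmax", "tmin", "precip", "wind")

#: Physical truncation bounds per variable.
BOUNDS: Mapping[str, tuple[float, float]] = {
    "sr": (0.0, math.inf),
    "rh": (0.0, 1.0),
    "tmax": (-math.inf, math.inf),
    "tmin": (-math.inf, math.inf),
    "precip": (0.0, math.inf),
    "wind": (0.0, math.inf),
}

#: Day-to-day coefficient of variation used where no SD was published.
DEFAULT_CV = 0.25

SEASON_MONTHS = (5, 6, 7, 8)


@dataclass(frozen=True)
class ExternalWeatherDay:
    """One day of weather outside the greenhouse.

    ``sr`` is daily solar radiation in the units of the published monthly
    table (numerically MJ m-2 day-1 scale; see docs/methods.md on the
    printed unit label), ``rh`` a fraction in [0, 1], temperatures in deg C,
    ``precip`` in mm and ``wind`` in m/s.
    """

    date: Date
    sr: float
    rh: float
    tmax: float
    tmin: float
    precip: float
    wind: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"tmax {self.tmax} < tmin {self.tmin} on {self.date}")
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(f"rh {self.rh} outside [0, 1] on {self.date}")
        for name in ("sr", "precip", "wind"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} on {self.date}")


@dataclass(frozen=True)
class MonthlyWeatherStats:
    """Mean and SD per variable for one calendar month.

    ``mean`` and ``sd`` are mappings from variable name to value; only the
    variables present in ``mean`` are generated. Missing SDs default to
    ``DEFAULT_CV * |mean|``.
    """

    month: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month index {self.month} out of range")
        for var, s in self.sd.items():
            if s < 0:
                raise ValueError(f"negative SD for {var} in month {self.month}")
        if "rh" in self.mean and not 0.0 <= self.mean["rh"] <= 1.0:
            raise ValueError(f"rh mean {self.mean['rh']} outside [0, 1]")

    def sd_for(self, var: str) -> float:
        if var in self.sd:
            return self.sd[var]
        return DEFAULT_CV * abs(self.mean[var])


@dataclass(frozen=True)
class ScenarioOffsets:
    """Per-month additive warming offsets (deg C) for tmax and tmin."""

    tmax: Mapping[int, float]
    tmin: Mapping[int, float]

    def __post_init__(self) -> None:
        for m in (self.tmax, self.tmin):
            for month, v in m.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite offset for month {month}")

    @classmethod
    def zero(cls, months: Iterable[int] = SEASON_MONTHS) -> "ScenarioOffsets":
        months = tuple(months)
        return cls({m: 0.0 for m in months}, {m: 0.0 for m in months})

    def negated(self) -> "ScenarioOffsets":
        return ScenarioOffsets({m: -v for m, v in self.tmax.items()},
                               {m: -v for m, v in self.tmin.items()})


# ---------------------------------------------------------------------------
# Published summary statistics (Wanju site, May-August 2022-2023)

# External monthly means: sr, rh (fraction), tmax, tmin, precip (mm), wind (m/s)
OUTSIDE_MONTHLY_MEANS: Mapping[int, Mapping[int, Mapping[str, float]]] = {
    2022: {
        5: dict(sr=23.76, rh=0.59, tmax=27.36, tmin=15.12, precip=0.52, wind=1.68),
        6: dict(sr=17.68, rh=0.73, tmax=28.82, tmin=19.79, precip=5.47, wind=1.63),
        7: dict(sr=16.46, rh=0.78, tmax=31.11, tmin=23.72, precip=5.94, wind=1.56),
        8: dict(sr=18.13, rh=0.79, tmax=33.04, tmin=26.01, precip=1.39, wind=1.66),
    },
    2023: {
        5: dict(sr=16.05, rh=0.71, tmax=25.51, tmin=16.64, precip=11.30, wind=1.40),
        6: dict(sr=19.95, rh=0.70, tmax=28.86, tmin=19.18, precip=5.66, wind=1.56),
        7: dict(sr=14.59, rh=0.81, tmax=30.52, tmin=23.41, precip=23.71, wind=1.45),
        8: dict(sr=17.43, rh=0.76, tmax=32.63, tmin=24.49, precip=10.83, wind=1.37),
    },
}

# Season-level SDs measured outside (per year): used as the default
# day-to-day spread for temperatures and humidity in every month.
OUTSIDE_SEASON_SD: Mapping[int, Mapping[str, float]] = {
    2022: dict(tmax=3.21, tmin=4.04, rh=0.108),
    2023: dict(tmax=3.42, tmin=3.42, rh=0.096),
}

# In-greenhouse season-level mean +/- SD per (regime, year):
# tmax, tmin (deg C) and rh (fraction).
GREENHOUSE_SEASON_STATS: Mapping[tuple[str, int], Mapping[str, tuple[float, float]]] = {
    ("control", 2022): dict(tmax=(37.36, 4.71), tmin=(21.50, 4.35), rh=(0.68, 0.0831)),
    ("control", 2023): dict(tmax=(36.56, 5.45), tmin=(21.62, 3.65), rh=(0.73, 0.0996)),
    ("heat", 2022): dict(tmax=(40.65, 3.39), tmin=(22.20, 4.23), rh=(0.68, 0.0784)),
    ("heat", 2023): dict(tmax=(38.63, 4.47), tmin=(22.35, 3.67), rh=(0.7194, 0.0907)),
}


def outside_monthly_stats(year: int | None = None) -> list[MonthlyWeatherStats]:
    """Monthly statistics of external weather for one year, or pooled.

    With ``year=None`` the two trial years are pooled: monthly means are
    averaged and the published season SDs averaged. SDs for radiation,
    precipitation and wind fall back to the default CV.
    """
    years = [year] if year is not None else sorted(OUTSIDE_MONTHLY_MEANS)
    for y in years:
        if y not in OUTSIDE_MONTHLY_MEANS:
            raise ValueError(f"no published external weather for year {y}")
    out = []
    for month in SEASON_MONTHS:
        mean = {v: float(np.mean([OUTSIDE_MONTHLY_MEANS[y][month][v] for y in years]))
                for v in VARIABLES}
        sd = {v: float(np.mean([OUTSIDE_SEASON_SD[y][v] for y in years]))
              for v in ("tmax", "tmin", "rh")}
        out.append(MonthlyWeatherStats(month=month, mean=mean, sd=sd))
    return out


def greenhouse_monthly_stats(regime: str, year: int | None = None,
                             months: Sequence[int] = SEASON_MONTHS,
                             sr_transmission: float = SR_TRANSMISSION,
                             ) -> list[MonthlyWeatherStats]:
    """Monthly statistics for direct in-greenhouse weather synthesis.

    Temperatures and humidity come from the season-level greenhouse
    summaries for ``regime`` (pooled over the two trial years when ``year``
    is None) and are applied to each month. In-greenhouse radiation is the
    pooled external monthly mean scaled by the envelope transmission.
    """
    if regime not in ("control", "heat"):
        raise ValueError(f"regime must be 'control' or 'heat', got {regime!r}")
    years = [year] if year is not None else sorted({y for (_, y) in GREENHOUSE_SEASON_STATS})
    for y in years:
        if (regime, y) not in GREENHOUSE_SEASON_STATS:
            raise ValueError(f"no greenhouse statistics for ({regime}, {y})")
    pooled = {v: (float(np.mean([GREENHOUSE_SEASON_STATS[(regime, y)][v][0] for y in years])),
                  float(np.mean([GREENHOUSE_SEASON_STATS[(regime, y)][v][1] for y in years])))
              for v in ("tmax", "tmin", "rh")}
    outside = {s.month: s for s in outside_monthly_stats(year if year in OUTSIDE_MONTHLY_MEANS else None)}
    out = []
    for month in months:
        sr_mean = sr_transmission * outside[month].mean["sr"]
        mean = dict(sr=sr_mean, **{v: pooled[v][0] for v in ("rh", "tmax", "tmin")})
        sd = {v: pooled[v][1] for v in ("rh", "tmax", "tmin")}
        out.append(MonthlyWeatherStats(month=month, mean=mean, sd=sd))
    return out


# ---------------------------------------------------------------------------
# Sampling machinery


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator keyed by (seed, variable name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


def _sample_variable(var: str, means: np.ndarray, sds: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws, one per day; SD 0 collapses to the clipped mean."""
    lo, hi = BOUNDS[var]
    out = np.clip(means.astype(float), lo, hi)
    live = sds > 0
    if live.any():
        m, s = means[live], sds[live]
        a, b = (lo - m) / s, (hi - m) / s
        out[live] = sps.truncnorm.rvs(a, b, loc=m, scale=s,
                                      size=int(live.sum()), random_state=rng)
    return out


def _dates(start: Date, end: Date) -> list[Date]:
    if end < start:
        raise ValueError(f"end date {end} before start date {start}")
    return [start + timedelta(days=i) for i in range((end - start).days + 1)]


def _stats_by_month(stats: Iterable[MonthlyWeatherStats],
                    dates: Sequence[Date]) -> dict[int, MonthlyWeatherStats]:
    by_month = {s.month: s for s in stats}
    for month in sorted({d.month for d in dates}):
        if month not in by_month:
            raise ValueError(f"no monthly statistics provided for month {month}")
    return by_month


def _sample_table(stats: Iterable[MonthlyWeatherStats], start: Date, end: Date,
                  seed: int, variables: Sequence[str], stream_prefix: str,
                  ) -> tuple[list[Date], dict[str, np.ndarray]]:
    dates = _dates(start, end)
    by_month = _stats_by_month(stats, dates)
    cols: dict[str, np.ndarray] = {}
    for var in variables:
        means = np.array([by_month[d.month].mean[var] for d in dates])
        sds = np.array([by_month[d.month].sd_for(var) for d in dates])
        rng = _substream(seed, f"{stream_prefix}:{var}")
        cols[var] = _sample_variable(var, means, sds, rng)
    # resolve tmax/tmin crossings by swapping
    if "tmax" in cols and "tmin" in cols:
        crossed = cols["tmax"] < cols["tmin"]
        if crossed.any():
            tmax = np.where(crossed, cols["tmin"], cols["tmax"])
            tmin = np.where(crossed, cols["tmax"], cols["tmin"])
            cols["tmax"], cols["tmin"] = tmax, tmin
    return dates, cols


def generate_external_series(stats: Iterable[MonthlyWeatherStats],
                             start: Date, end: Date, seed: int,
                             ) -> list[ExternalWeatherDay]:
    """Generate a daily external weather series between two dates inclusive.

    Deterministic given ``seed``. Every month in the range must appear in
    ``stats``.
    """
    dates, cols = _sample_table(stats, start, end, seed, VARIABLES, "external")
    return [ExternalWeatherDay(date=d, **{v: float(cols[v][i]) for v in VARIABLES})
            for i, d in enumerate(dates)]


def greenhouse_series_from_stats(stats: Iterable[MonthlyWeatherStats],
                                 start: Date, end: Date, seed: int,
                                 regime: str) -> list[GreenhouseWeatherDay]:
    """Generate in-greenhouse daily weather directly from summary statistics.

    Used to drive the crop engine when the external->greenhouse regression
    pipeline is not exercised. Same sampling rules as
    :func:`generate_external_series`.
    """
    if regime not in ("control", "heat"):
        raise ValueError(f"regime must be 'control' or 'heat', got {regime!r}")
    variables = ("sr", "rh", "tmax", "tmin")
    dates, cols = _sample_table(stats, start, end, seed, variables, f"greenhouse:{regime}")
    return [GreenhouseWeatherDay(date=d, tmax=float(cols["tmax"][i]),
                                 tmin=float(cols["tmin"][i]),
                                 rh=float(cols["rh"][i]), regime=regime,
                                 sr=float(cols["sr"][i]))
            for i, d in enumerate(dates)]


def apply_scenario(series: Sequence[ExternalWeatherDay],
                   offsets: ScenarioOffsets) -> list[ExternalWeatherDay]:
    """Shift tmax/tmin by their monthly offsets; all other fields unchanged.

    Offsets must cover every month present. If shifted tmin exceeds shifted
    tmax (possible with asymmetric offsets), tmin is clamped to tmax and a
    warning is logged.
    """
    months = sorted({d.date.month for d in series})
    for m in months:
        if m not in offsets.tmax or m not in offsets.tmin:
            raise ValueError(f"scenario offsets missing month {m}")
    out: list[ExternalWeatherDay] = []
    clamped = 0
    for day in series:
        tmax = day.tmax + offsets.tmax[day.date.month]
        tmin = day.tmin + offsets.tmin[day.date.month]
        if tmin > tmax:
            clamped += 1
            tmin = tmax
        out.append(replace(day, tmax=tmax, tmin=tmin))
    if clamped:
        log.warning("scenario offsets forced tmin->tmax clamping on %d day(s)", clamped)
    return out


# ---------------------------------------------------------------------------
# Tabular interchange (one row per day; ISO dates; rh as fraction)


def external_to_frame(series: Sequence[ExternalWeatherDay]) -> pd.DataFrame:
    return pd.DataFrame([{"date": d.date.isoformat(), "sr": d.sr, "rh": d.rh,
                          "tmax": d.tmax, "tmin": d.tmin, "precip": d.precip,
                          "wind": d.wind} for d in series])


def frame_to_external(df: pd.DataFrame) -> list[ExternalWeatherDay]:
    return [ExternalWeatherDay(date=Date.fromisoformat(str(r.date)), sr=r.sr,
                               rh=r.rh, tmax=r.tmax, tmin=r.tmin,
                               precip=r.precip, wind=r.wind)
            for r in df.itertuples(index=False)]


def stats_to_frame(stats: Iterable[MonthlyWeatherStats]) -> pd.DataFrame:
    rows = [{"month": s.month, "var": v, "mean": s.mean[v], "sd": s.sd_for(v)}
            for s in stats for v in s.mean]
    return pd.DataFrame(rows)


def frame_to_stats(df: pd.DataFrame) -> list[MonthlyWeatherStats]:
    out = []
    for month, grp in df.groupby("month"):
        mean = dict(zip(grp["var"], grp["mean"].astype(float)))
        sd = dict(zip(grp["var"], grp["sd"].astype(float)))
        out.append(MonthlyWeatherStats(month=int(month), mean=mean, sd=sd))
    return sorted(out, key=lambda s: s.month)
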