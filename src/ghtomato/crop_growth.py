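"""Daily-timestep crop growth engine (EPIC-family, greenhouse subset).

A from-scratch reimplementation of the process subset that governs
greenhouse tomato growth in EPIC/APEX-style models:

* **phenology** -- a heat-unit clock: daily growing degrees above the base
  temperature TG accumulate toward the potential heat units PHU, giving the
  heat-unit index HUI in [0, ~1];
* **canopy** -- leaf area index follows the standard EPIC sigmoid
  ``f(x) = x / (x + exp(l1 - l2*x))`` of HUI, anchored through two encoded
  calibration points (DLAP1/DLAP2), scaled by the maximum potential LAI
  (DMLA), with a mild late-season decline (exponent RLAD);
* **growth** -- intercepted photosynthetically active radiation (Beer's law,
  extinction 0.65, PAR fraction 0.5) times the radiation-use-efficiency
  parameter WA gives potential daily biomass, down-regulated by the most
  limiting of temperature stress and water stress;
* **water** -- a single-layer soil bucket with Hargreaves-type potential
  evapotranspiration and automatic irrigation (optionally capped);
* **yield** -- dry fruit yield is the harvest index HI times final dry
  biomass.

Nutrient cycling, erosion, multi-layer soil hydrology, CO2 response and
fruit-set physiology are deliberately out of scope: the greenhouse trials
this engine reproduces controlled fertigation and CO2, and the published
parameter sets exercise only the processes above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canopy light-extinction coefficient (Beer's law) -- also used for the
#: ground-cover fraction in the evapotranspiration split.
K_EXTINCTION = 0.65
#: Photosynthetically active fraction of shortwave radiation.
PAR_FRACTION = 0.5
#: Conversion from the weather tables' radiation unit to MJ m-2 day-1.
#: The table values (14-24) are on the MJ scale, so the default is 1.0;
#: set 3.6 if a source really reports kWh m-2 day-1.
SR_TO_MJ = 1.0
#: HUI at which late-season LAI and radiation-use-efficiency decline begins.
DECLINE_START = 0.9
#: Latent heat of vaporization, MJ kg-1 (Hargreaves-type PET).
LAMBDA_ET = 2.45


def decode_dlap(code: float) -> tuple[float, float]:
    """Decode a DLAP point: 15.05 -> (0.15, 0.05).

    Integer part is the percent of the growing season elapsed; the two
    fractional digits are the fraction of maximum LAI attained.
    """
    cents = round(code * 100)
    whole, frac = divmod(cents, 100)
    if not 0 < whole < 100:
        raise ValueError(f"DLAP integer part must be in (0, 100): {code}")
    if frac == 0:
        raise ValueError(f"degenerate DLAP code {code}: no fractional digits")
    return whole / 100.0, frac / 100.0


def encode_dlap(season_fraction: float, lai_fraction: float) -> float:
    """Inverse of :func:`decode_dlap`, rounded to the two-digit convention."""
    whole = round(season_fraction * 100)
    frac = round(lai_fraction * 100)
    if not 0 < whole < 100:
        raise ValueError(f"season fraction {season_fraction} out of range")
    if not 0 < frac < 100:
        raise ValueError(f"LAI fraction {lai_fraction} not encodable in two digits")
    return whole + frac / 100.0


@dataclass(frozen=True)
class CropParams:
    """Cultivar parameter set (EPIC/APEX naming).

    wa
        biomass-energy ratio, (kg/ha) per (MJ/m^2) of intercepted PAR.
    hi
        harvest index, dry fruit / dry biomass.
    tb, tg
        optimum and base temperature for growth (deg C). Growth stops at or
        below tg; temperature stress is 1 at tb.
    dmla
        maximum potential leaf area index.
    dlap1, dlap2
        encoded points of the optimal LAI development curve: integer part =
        percent of the season elapsed, two fractional digits = fraction of
        DMLA attained (15.05 -> 5% of DMLA at 15% of the season).
    rlad, rbmd
        late-season decline exponents for LAI and for WA.
    phu
        potential heat units for the growing period (deg C day).
    density
        plants per m^2 (per-area traits conversion; the engine itself works
        per hectare).
    """

    wa: float
    hi: float
    tb: float
    tg: float
    dmla: float
    dlap1: float
    dlap2: float
    rlad: float
    rbmd: float
    phu: float
    density: float = 4.7

    def __post_init__(self) -> None:
        if not 0.0 < self.hi <= 1.0:
            raise ValueError(f"harvest index {self.hi} outside (0, 1]")
        if self.tb <= self.tg:
            raise ValueError(f"optimum temperature {self.tb} must exceed base {self.tg}")
        if self.phu <= 0 or self.dmla <= 0 or self.wa <= 0:
            raise ValueError("wa, dmla and phu must be positive")
        s1, _ = decode_dlap(self.dlap1)
        s2, _ = decode_dlap(self.dlap2)
        if not s1 < s2:
            raise ValueError("dlap1 season fraction must precede dlap2")


#: Published parameter sets for the two accessions under each temperature
#: regime (HR17: moderately heat-tolerant; HR24: heat-tolerant commercial
#: cultivar). PHU was 2000 for all four cases in the trials.
PRESETS: Mapping[str, CropParams] = {
    "HR17-con": CropParams(wa=48, hi=0.8, tb=28, tg=10, dmla=7, dlap1=15.05,
                           dlap2=45.38, rlad=0.1, rbmd=0.1, phu=2000),
    "HR17-heat": CropParams(wa=40, hi=0.62, tb=28, tg=10, dmla=3.82, dlap1=15.05,
                            dlap2=45.35, rlad=0.1, rbmd=0.1, phu=2000),
    "HR24-cont": CropParams(wa=50, hi=0.7, tb=30, tg=10, dmla=12, dlap1=15.05,
                            dlap2=45.41, rlad=0.1, rbmd=0.1, phu=2000),
    "HR24-heat": CropParams(wa=45, hi=0.4, tb=30, tg=10, dmla=7, dlap1=15.05,
                            dlap2=45.29, rlad=0.1, rbmd=0.1, phu=2000),
}

#: Preset name for each (accession, regime) pair.
PRESET_BY_CASE: Mapping[tuple[str, str], str] = {
    ("HR17", "control"): "HR17-con",
    ("HR17", "heat"): "HR17-heat",
    ("HR24", "control"): "HR24-cont",
    ("HR24", "heat"): "HR24-heat",
}


@dataclass(frozen=True)
class LaiCurve:
    """EPIC sigmoid ``f(x) = x / (x + exp(l1 - l2*x))`` on x = HUI."""

    l1: float
    l2: float

    def __call__(self, x):
        x = np.asarray(x, float)
        out = x / (x + np.exp(self.l1 - self.l2 * x))
        return float(out) if out.ndim == 0 else out


def solve_lai_curve(p1: tuple[float, float], p2: tuple[float, float]) -> LaiCurve:
    """Solve (l1, l2) so the sigmoid passes through two (x, f) points.

    Each point gives the linear relation ``l1 - l2*x = log(x*(1-f)/f)``;
    two distinct points determine the 2x2 system exactly.
    """
    (x1, f1), (x2, f2) = p1, p2
    if p1 == p2 or x1 == x2:
        raise ValueError("LAI curve needs two distinct season fractions")
    for x, f in (p1, p2):
        if not 0 < f < 1 or x <= 0:
            raise ValueError(f"LAI curve point ({x}, {f}) outside (0,1) range")
    c1 = math.log(x1 * (1 - f1) / f1)
    c2 = math.log(x2 * (1 - f2) / f2)
    l2 = (c1 - c2) / (x2 - x1)
    l1 = c1 + l2 * x1
    curve = LaiCurve(l1=l1, l2=l2)
    resid = max(abs(curve(x1) - f1), abs(curve(x2) - f2))
    if not resid < 1e-9:
        raise ValueError(f"LAI curve solve failed: residual {resid:.3e}")
    return curve


def lai_curve_for(params: CropParams) -> LaiCurve:
    return solve_lai_curve(decode_dlap(params.dlap1), decode_dlap(params.dlap2))


def daily_hui_increment(tmax: float, tmin: float, tg: float, phu: float) -> float:
    """Daily heat-unit index increment: max(0, tavg - tg) / phu."""
    if phu <= 0:
        raise ValueError("phu must be positive")
    return max(0.0, (tmax + tmin) / 2.0 - tg) / phu


def potential_lai(hui: float, curve: LaiCurve, dmla: float,
                  rlad: float = 0.1, decline_start: float = DECLINE_START) -> float:
    """Potential LAI at heat-unit index ``hui``.

    Follows ``dmla * f(hui)`` up to ``decline_start``, then declines as
    ``((1 - hui) / (1 - decline_start)) ** rlad``, floored at zero (so LAI
    is zero once the heat-unit clock passes 1).
    """
    if hui < 0:
        raise ValueError("hui must be nonnegative")
    if hui <= decline_start:
        return dmla * curve(hui)
    factor = max(0.0, (1.0 - hui) / (1.0 - decline_start)) ** rlad
    return dmla * curve(decline_start) * factor


def temperature_stress(tavg: float, tb: float, tg: float) -> float:
    """EPIC temperature stress: sin(pi/2 * x) on x = (tavg-tg)/(tb-tg).

    1 at the optimum tb, 0 at or below the base tg, and 0 again at tb +
    (tb - tg) (symmetric decline beyond the optimum); clamped to [0, 1].
    """
    if tb <= tg:
        raise ValueError("tb must exceed tg")
    x = (tavg - tg) / (tb - tg)
    if x <= 0.0 or x >= 2.0:
        return 0.0
    return min(1.0, max(0.0, math.sin(math.pi * x / 2.0)))


def intercepted_par(sr_mj: float, lai: float) -> float:
    """Intercepted PAR, MJ m-2: 0.5 * sr * (1 - exp(-0.65 * LAI))."""
    if sr_mj < 0 or lai < 0:
        raise ValueError("radiation and LAI must be nonnegative")
    return PAR_FRACTION * sr_mj * (1.0 - math.exp(-K_EXTINCTION * lai))


def daily_biomass_delta(wa: float, par_i: float, reg: float, hui: float,
                        decline_start: float = DECLINE_START,
                        rbmd: float = 0.1) -> float:
    """Daily dry-biomass increment, Mg/ha.

    ``0.001 * wa_eff * par_i * reg`` with wa in (kg/ha)/(MJ/m^2); wa_eff
    declines after ``decline_start`` with exponent ``rbmd`` (floored at 0).
    """
    if min(wa, par_i, hui) < 0 or not 0.0 <= reg <= 1.0:
        raise ValueError("inputs must be nonnegative with reg in [0, 1]")
    wa_eff = wa
    if hui > decline_start:
        wa_eff = wa * max(0.0, (1.0 - hui) / (1.0 - decline_start)) ** rbmd
    return 0.001 * wa_eff * par_i * reg


def hargreaves_pet(tmax: float, tmin: float, sr_mj: float) -> float:
    """Radiation-based potential evapotranspiration, mm/day.

    ``0.0135 * (tavg + 17.8) * sr / 2.45``, floored at zero.
    """
    tavg = (tmax + tmin) / 2.0
    return max(0.0, 0.0135 * (tavg + 17.8) * sr_mj / LAMBDA_ET)


@dataclass(frozen=True)
class SoilConfig:
    """Single-layer soil water bucket (loam-scale defaults)."""

    capacity_mm: float = 150.0
    initial_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.capacity_mm <= 0 or not 0.0 <= self.initial_fraction <= 1.0:
            raise ValueError("invalid soil configuration")


@dataclass
class SeasonResult:
    """Aggregate output of one simulated season."""

    biomass: float          # final dry biomass, Mg/ha
    fruit_yield: float      # dry fruit yield = hi * biomass, Mg/ha
    max_lai: float
    irrigation: float       # total, mm
    aet: float              # total actual evapotranspiration, mm
    days: int
    daily: pd.DataFrame | None = field(default=None, repr=False)


def simulate_season(params: CropParams,
                    weather: Sequence,
                    irrigation_cap_mm: float | None = None,
                    soil: SoilConfig = SoilConfig(),
                    sr_to_mj: float = SR_TO_MJ,
                    decline_start: float = DECLINE_START,
                    harvest_day: int | None = None,
                    return_daily: bool = False) -> SeasonResult:
    """Run the daily engine over an in-greenhouse weather series.

    ``weather`` is a gap-free sequence of daily records with ``date``,
    ``tmax``, ``tmin`` and ``sr`` attributes (``GreenhouseWeatherDay``
    works). ``harvest_day`` truncates the run to the first N days.

    Each day: the heat-unit clock advances; potential LAI and temperature
    stress follow from it; Hargreaves PET times canopy cover gives the
    transpiration demand, met from the soil bucket (AET = min(demand,
    available water)); automatic irrigation refills the bucket after each
    day, limited by the remaining seasonal cap if one is set; growth is
    scaled by the most limiting of temperature and water stress.

    With unlimited irrigation and a full initial bucket, water stress is 1
    on every day and total irrigation equals total AET.
    """
    if len(weather) == 0:
        raise ValueError("weather series is empty")
    days = list(weather[:harvest_day] if harvest_day is not None else weather)
    for prev, cur in zip(days, days[1:]):
        if (cur.date - prev.date) != timedelta(days=1):
            raise ValueError(f"weather gap between {prev.date} and {cur.date}")

    curve = lai_curve_for(params)
    water = soil.capacity_mm * soil.initial_fraction
    cap_left = math.inf if irrigation_cap_mm is None else float(irrigation_cap_mm)
    hui = 0.0
    biomass = 0.0
    max_lai = 0.0
    tot_irr = 0.0
    tot_aet = 0.0
    rows = [] if return_daily else None

    for i, day in enumerate(days):
        hui += daily_hui_increment(day.tmax, day.tmin, params.tg, params.phu)
        lai = potential_lai(hui, curve, params.dmla, params.rlad, decline_start)
        max_lai = max(max_lai, lai)
        tavg = (day.tmax + day.tmin) / 2.0
        ts = temperature_stress(tavg, params.tb, params.tg)

        sr_mj = day.sr * sr_to_mj
        pet = hargreaves_pet(day.tmax, day.tmin, sr_mj)
        cover = 1.0 - math.exp(-K_EXTINCTION * lai)
        demand = pet * cover
        aet = min(demand, water)
        water -= aet
        irr = min(soil.capacity_mm - water, cap_left)
        water += irr
        cap_left -= irr
        tot_irr += irr
        tot_aet += aet
        ws = 1.0 if demand <= 1e-12 else aet / demand

        reg = min(ts, ws)
        par_i = intercepted_par(sr_mj, lai)
        biomass += daily_biomass_delta(params.wa, par_i, reg, hui,
                                       decline_start, params.rbmd)
        if rows is not None:
            rows.append(dict(date=day.date, day=i + 1, hui=hui, lai=lai, ts=ts,
                             ws=ws, pet=pet, aet=aet, irrigation=irr,
                             biomass=biomass))

    daily = pd.DataFrame(rows) if rows is not None else None
    return SeasonResult(biomass=biomass, fruit_yield=params.hi * biomass,
                        max_lai=max_lai, irrigation=tot_irr, aet=tot_aet,
                        days=len(days), daily=daily)


def fit_dlap_from_lai(hui: Sequence[float], lai: Sequence[float], dmla: float,
                      anchors: tuple[float, float] = (0.15, 0.45),
                      ) -> tuple[float, float]:
    """Re-derive DLAP codes from an LAI trajectory on a HUI axis.

    Reads the LAI fraction (of ``dmla``) at the two anchor season fractions
    by linear interpolation and re-encodes them with the two-digit
    convention. The series must cover both anchors and give fractions
    strictly inside (0, 1).
    """
    hui = np.asarray(hui, float)
    lai = np.asarray(lai, float)
    if hui.ndim != 1 or hui.shape != lai.shape or len(hui) < 2:
        raise ValueError("hui and lai must be matching 1-D series")
    order = np.argsort(hui)
    hui, lai = hui[order], lai[order]
    codes = []
    for a in anchors:
        if not hui[0] <= a <= hui[-1]:
            raise ValueError(f"LAI series does not cover anchor HUI {a}")
        frac = float(np.interp(a, hui, lai)) / dmla
        if not 0.005 <= frac < 0.995:
            raise ValueError(f"degenerate LAI fraction {frac:.3f} at HUI {a}")
        codes.append(encode_dlap(a, frac))
    return tuple(codes)


def params_to_dict(params: CropParams) -> dict:
    """Table-style field names (WA, HI, ..., DENSITY) for interchange."""
    return {"WA": params.wa, "HI": params.hi, "TB": params.tb, "TG": params.tg,
            "DMLA": params.dmla, "DLAP1": params.dlap1, "DLAP2": params.dlap2,
            "RLAD": params.rlad, "RBMD": params.rbmd, "PHU": params.phu,
            "DENSITY": params.density}


def params_from_dict(d: Mapping) -> CropParams:
    return CropParams(wa=d["WA"], hi=d["HI"], tb=d["TB"], tg=d["TG"],
                      dmla=d["DMLA"], dlap1=d["DLAP1"], dlap2=d["DLAP2"],
                      rlad=d["RLAD"], rbmd=d["RBMD"], phu=d["PHU"],
                      density=d.get("DENSITY", 4.7))
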