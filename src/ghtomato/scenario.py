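"""Multi-year climate-change scenario projection.

Shared-socioeconomic-pathway warming (SSP245 "middle of the road", SSP585
high forcing) is *emulated* rather than ingested from GCM output: per-month
additive offsets are applied to synthetic external weather so that, after
the external weather passes through the greenhouse regressions, the
in-greenhouse monthly mean temperatures move from the historical values
toward the published scenario values. Each scenario year then drives the
crop engine with a scenario potential-heat-unit override (the hotter season
accumulates more heat units) and a capped automatic irrigation supply.

CO2 is carried in the configuration for the record but has no growth
effect: the greenhouses regulate CO2, and the projections held it at the
historical 360 ppm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .calibration import percent_bias
from .crop_growth import CropParams, SeasonResult, simulate_season
from .gh_climate import PRModel, PUBLISHED_MODELS, eval_pr, predict_greenhouse_series
from .weather_synth import (MonthlyWeatherStats, ScenarioOffsets,
                            apply_scenario, generate_external_series,
                            outside_monthly_stats)

log = logging.getLogger(__name__)

#: Published in-greenhouse monthly mean (tmax, tmin) targets, deg C, for the
#: May-August season: historical (2022-2023) and the two projections
#: (2030-2039), heat-treatment house.
GREENHOUSE_MONTHLY_TARGETS: Mapping[str, Mapping[int, tuple[float, float]]] = {
    "historical": {5: (29.58, 13.88), 6: (38.68, 20.56),
                   7: (40.45, 24.92), 8: (35.18, 24.19)},
    "SSP245": {5: (37.10, 14.36), 6: (40.10, 20.87),
               7: (42.03, 25.44), 8: (42.61, 26.02)},
    "SSP585": {5: (36.59, 14.51), 6: (40.07, 20.78),
               7: (41.37, 25.07), 8: (42.34, 25.60)},
}

#: Scenario potential-heat-unit overrides (deg C day).
SCENARIO_PHU = {"historical": 2000.0, "SSP245": 2600.0, "SSP585": 2800.0}

#: Annual irrigation caps (mm) assumed per accession under the projections.
IRRIGATION_CAP_MM = {"HR17": 4000.0, "HR24": 6000.0}

#: Crop simulation window: the heat-treatment period of the trials
#: (treatment started 18 May; total yield summed through the 77th day).
SIM_START = (5, 18)
HARVEST_DAYS = 77
SEASON_SPAN = ((5, 1), (8, 31))


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: warming offsets + PHU override + irrigation cap."""

    name: str
    offsets: ScenarioOffsets
    phu: float
    irrigation_cap_mm: float | None
    years: int = 10
    co2_ppm: float = 360.0  # recorded, inert

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.phu <= 0:
            raise ValueError("phu override must be positive")
        if self.irrigation_cap_mm is not None and self.irrigation_cap_mm <= 0:
            raise ValueError("irrigation cap must be positive")


@dataclass
class ScenarioReport:
    """Multi-year scenario output for one accession/parameter set."""

    name: str
    results: list[SeasonResult]
    mean_yield: float
    mean_irrigation: float
    mean_aet: float
    mean_wue: float

    @property
    def years(self) -> int:
        return len(self.results)


def water_use_efficiency(dry_yield_mg_ha: float, irrigation_mm: float) -> float:
    """WUE, kg/mm: dry yield (kg/ha) per mm of seasonal irrigation."""
    if irrigation_mm <= 0:
        raise ValueError("water use efficiency undefined without irrigation")
    return dry_yield_mg_ha * 1000.0 / irrigation_mm


def offsets_for_greenhouse_targets(
        targets: Mapping[int, tuple[float, float]],
        external_stats: Sequence[MonthlyWeatherStats],
        regime: str = "heat",
        models: Mapping[str, PRModel] | None = None) -> ScenarioOffsets:
    """Solve the external warming offsets that move predicted in-greenhouse
    monthly mean (tmax, tmin) onto ``targets``.

    For each month the greenhouse regressions are evaluated at the monthly
    mean external conditions, and a 2x2 root solve finds the additive shifts
    of external tmax/tmin that make the predicted pair equal the target
    pair. (Mean-day evaluation ignores the small Jensen term from the
    squared-tmin term of the tmax model; the residual is well under the
    weather generator's sampling noise.)
    """
    models = PUBLISHED_MODELS if models is None else models
    m_tmax, m_tmin = models[f"Tmax_{regime}"], models[f"Tmin_{regime}"]
    d_tmax: dict[int, float] = {}
    d_tmin: dict[int, float] = {}
    for s in external_stats:
        if s.month not in targets:
            continue
        base = dict(X1=s.mean["sr"], X2=s.mean["rh"], X3=s.mean["tmax"],
                    X4=s.mean["tmin"], X5=s.mean["precip"], X6=s.mean["wind"])
        want = np.asarray(targets[s.month], float)

        def gap(d, base=base, want=want):
            x = dict(base, X3=base["X3"] + d[0], X4=base["X4"] + d[1])
            return [eval_pr(m_tmax, x) - want[0], eval_pr(m_tmin, x) - want[1]]

        sol, info, ok, msg = optimize.fsolve(gap, x0=[0.0, 0.0], full_output=True)
        if ok != 1:
            raise RuntimeError(f"offset solve failed for month {s.month}: {msg}")
        d_tmax[s.month], d_tmin[s.month] = float(sol[0]), float(sol[1])
    missing = set(targets) - set(d_tmax)
    if missing:
        raise ValueError(f"external stats missing months {sorted(missing)}")
    return ScenarioOffsets(tmax=d_tmax, tmin=d_tmin)


def scenario_config(name: str, accession: str,
                    external_stats: Sequence[MonthlyWeatherStats] | None = None,
                    years: int = 10) -> ScenarioConfig:
    """Build a preset configuration ("historical", "SSP245" or "SSP585").

    The historical configuration has zero offsets, the trial PHU and
    unlimited irrigation (the trials irrigated to demand); the projections
    target the published scenario greenhouse temperatures and cap annual
    irrigation per accession.
    """
    if name not in GREENHOUSE_MONTHLY_TARGETS:
        raise ValueError(f"unknown scenario {name!r}")
    external_stats = outside_monthly_stats() if external_stats is None else external_stats
    if name == "historical":
        offsets = ScenarioOffsets.zero(s.month for s in external_stats)
        cap = None
    else:
        hist = offsets_for_greenhouse_targets(
            GREENHOUSE_MONTHLY_TARGETS["historical"], external_stats)
        want = offsets_for_greenhouse_targets(
            GREENHOUSE_MONTHLY_TARGETS[name], external_stats)
        # warming relative to the emulated historical greenhouse state
        offsets = ScenarioOffsets(
            tmax={m: want.tmax[m] - hist.tmax[m] for m in want.tmax},
            tmin={m: want.tmin[m] - hist.tmin[m] for m in want.tmin})
        cap = IRRIGATION_CAP_MM[accession]
    return ScenarioConfig(name=name, offsets=offsets, phu=SCENARIO_PHU[name],
                          irrigation_cap_mm=cap, years=years)


def _year_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_scenario(params: CropParams, config: ScenarioConfig,
                 external_stats: Sequence[MonthlyWeatherStats] | None = None,
                 regime: str = "heat", seed: int = 0,
                 first_year: int = 2030) -> ScenarioReport:
    """Run ``config.years`` seeded season simulations.

    Per year: synthesize external weather for the May-August season, apply
    the warming offsets, predict in-greenhouse weather with the ``regime``
    regressions, override PHU, and run the crop engine over the treatment
    window (18 May + 77 days) with capped automatic irrigation. Reports are
    reproducible bit-for-bit given (config, seed).
    """
    external_stats = outside_monthly_stats() if external_stats is None else external_stats
    results: list[SeasonResult] = []
    (m0, d0), (m1, d1) = SEASON_SPAN
    for i in range(config.years):
        year = first_year + i
        series = generate_external_series(external_stats, Date(year, m0, d0),
                                          Date(year, m1, d1), _year_seed(seed, i))
        warmed = apply_scenario(series, config.offsets)
        gh = predict_greenhouse_series(warmed, regime)
        start = Date(year, *SIM_START)
        window = [d for d in gh if d.date >= start]
        params_y = replace(params, phu=config.phu)
        results.append(simulate_season(params_y, window,
                                       irrigation_cap_mm=config.irrigation_cap_mm,
                                       harvest_day=HARVEST_DAYS))
    yields = [r.fruit_yield for r in results]
    irrs = [r.irrigation for r in results]
    wues = [water_use_efficiency(y, irr) for y, irr in zip(yields, irrs)]
    return ScenarioReport(name=config.name, results=results,
                          mean_yield=float(np.mean(yields)),
                          mean_irrigation=float(np.mean(irrs)),
                          mean_aet=float(np.mean([r.aet for r in results])),
                          mean_wue=float(np.mean(wues)))


def compare_accessions(report_a: ScenarioReport, report_b: ScenarioReport,
                       baseline_a: ScenarioReport, baseline_b: ScenarioReport
                       ) -> dict[str, float]:
    """Yield deltas of two accessions' scenario runs vs their baselines.

    Returns absolute deltas (Mg/ha) and relative changes (fractions of the
    baseline mean) for each accession.
    """
    if report_a.years != report_b.years:
        raise ValueError("reports cover different numbers of years")
    delta_a = report_a.mean_yield - baseline_a.mean_yield
    delta_b = report_b.mean_yield - baseline_b.mean_yield
    return {
        "delta_a": delta_a,
        "delta_b": delta_b,
        "relative_a": delta_a / baseline_a.mean_yield,
        "relative_b": delta_b / baseline_b.mean_yield,
    }
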