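"""Derived plant traits from the greenhouse harvest measurements.

Harvest index (fruit fresh weight / total fresh weight), heat-induced
percent reductions, moisture content relative to fresh weight, and the
per-plant -> per-area dry-yield conversion at the trial planting density.

Report rounding follows the published convention (harvest index to two
decimals, reductions to whole percent); full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Trial planting density, plants per m^2.
DEFAULT_DENSITY = 4.7


@dataclass(frozen=True)
class PlantRecord:
    """Per-plant harvest record for one accession x regime case."""

    accession: str
    regime: str
    total_fresh_kg: float
    fruit_fresh_kg: float
    lai: float | None = None
    height_m: float | None = None
    stem_mm: float | None = None
    dry_kg: float | None = None

    def __post_init__(self) -> None:
        if self.total_fresh_kg < 0 or self.fruit_fresh_kg < 0:
            raise ValueError("weights must be nonnegative")
        if self.fruit_fresh_kg > self.total_fresh_kg:
            raise ValueError("fruit weight exceeds total fresh weight")


def measured_trait_table() -> pd.DataFrame:
    """The published per-plant harvest measurements (77th treatment day,
    Wanju trials): fresh weights (kg/plant), moisture (%), LAI, harvest
    index as printed, height (m) and stem thickness (mm)."""
    rows = [
        ("HR17", "control", 2.50, 1.63, 91, 3.24, 0.65, 1.90, 15.8),
        ("HR24", "control", 3.16, 1.50, 89, 5.93, 0.48, 2.33, 19.2),
        ("HR17", "heat", 1.89, 1.17, 90, 2.77, 0.62, 2.12, 16.3),
        ("HR24", "heat", 2.34, 0.83, 87, 4.80, 0.35, 2.27, 17.2),
    ]
    return pd.DataFrame(rows, columns=[
        "accession", "regime", "total_fresh_kg", "fruit_fresh_kg",
        "moisture_pct", "lai", "harvest_index", "height_m", "stem_mm"])


def harvest_index(total_fresh: float, fruit_fresh: float) -> float:
    """Fruit fresh weight over total fresh weight (fraction)."""
    if total_fresh <= 0:
        raise ValueError("total fresh weight must be positive")
    if fruit_fresh > total_fresh:
        raise ValueError("fruit weight exceeds total fresh weight")
    if fruit_fresh < 0:
        raise ValueError("fruit weight must be nonnegative")
    return fruit_fresh / total_fresh


def percent_reduction(control_value: float, heat_value: float) -> float:
    """Heat-induced reduction, %: 100 * (control - heat) / control."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * (control_value - heat_value) / control_value


def moisture_content(fresh: float, dry: float) -> float:
    """Moisture relative to fresh weight, %: 100 * (fresh - dry) / fresh."""
    if fresh <= 0:
        raise ValueError("fresh weight must be positive")
    if not 0 <= dry <= fresh:
        raise ValueError("dry weight must lie in [0, fresh]")
    return 100.0 * (fresh - dry) / fresh


def area_yield(dry_per_plant_kg: float, density_per_m2: float = DEFAULT_DENSITY) -> float:
    """Per-area dry yield, Mg/ha, from kg/plant at a planting density.

    kg/plant * plants/m^2 = kg/m^2; x10 converts to Mg/ha.
    """
    if dry_per_plant_kg < 0 or density_per_m2 < 0:
        raise ValueError("inputs must be nonnegative")
    return dry_per_plant_kg * density_per_m2 * 10.0


def derive_trait_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add computed harvest index (full precision and 2-dp report value)."""
    out = df.copy()
    out["hi_computed"] = [
        harvest_index(t, f)
        for t, f in zip(out["total_fresh_kg"], out["fruit_fresh_kg"])]
    out["hi_report"] = out["hi_computed"].round(2)
    return out


def heat_reduction_table(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percent reductions of fresh weight and fruit yield under heat, per
    accession, with whole-percent report rounding."""
    df = measured_trait_table() if df is None else df
    rows = []
    for acc, grp in df.groupby("accession", sort=True):
        con = grp[grp.regime == "control"].iloc[0]
        heat = grp[grp.regime == "heat"].iloc[0]
        for trait in ("total_fresh_kg", "fruit_fresh_kg"):
            red = percent_reduction(con[trait], heat[trait])
            rows.append(dict(accession=acc, trait=trait,
                             reduction_pct=red, reduction_report=round(red)))
    return pd.DataFrame(rows)
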