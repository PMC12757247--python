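from datetime import date

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from ghtomato.weather_synth import (MonthlyWeatherStats, greenhouse_monthly_stats,
                                    greenhouse_series_from_stats)


def zero_sd(stats):
    """Strip the day-to-day spread so every day equals the monthly mean."""
    return [MonthlyWeatherStats(s.month, s.mean, {v: 0.0 for v in s.mean})
            for s in stats]


@pytest.fixture(scope="session")
def mean_greenhouse_series():
    """Deterministic (SD=0) in-greenhouse season per regime, 18 May-31 Aug."""
    def make(regime, year=None):
        stats = zero_sd(greenhouse_monthly_stats(regime, year=year))
        return greenhouse_series_from_stats(stats, date(2022, 5, 18),
                                            date(2022, 8, 31), seed=0,
                                            regime=regime)
    return make
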