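"""Greenhouse microclimate models.

Daily maximum/minimum temperature and relative humidity inside a
temperature-controlled greenhouse are predicted from external weather with
additive polynomial regressions: the response is a sum of per-variable
polynomials ``f_j(X_j) = b_j1*X_j + b_j2*X_j^2 + ...`` plus an intercept.
Candidate predictors are the six external variables measured at the Wanju
trial site:

========  =========================================
``X1``    daily solar radiation (table units)
``X2``    relative humidity (fraction)
``X3``    daily maximum temperature (deg C)
``X4``    daily minimum temperature (deg C)
``X5``    precipitation (mm)
``X6``    wind speed (m/s)
========  =========================================

Six published regressions (one per response x regime) ship as immutable
constants in :data:`PUBLISHED_MODELS`; :func:`fit_pr` refits new models from
data using the same selection procedure (Pearson-significance screening,
collinearity exclusion, OLS on polynomial terms, k-fold cross-validation).
Refitting never mutates the published constants.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

if TYPE_CHECKING:  # only for annotations; weather_synth imports this module
    from .weather_synth import ExternalWeatherDay

log = logging.getLogger(__name__)

#: Effective shortwave transmission of the greenhouse envelope (cover film,
#: structure shading, seasonal screening). Multiplies outside solar radiation
#: to give the radiation reaching the canopy. Set during model construction by
#: matching the simulated dry-mass scale to the harvest observations (see
#: docs/methods.md); plausible range for plastic multi-span houses in a Korean
#: summer is roughly 0.5-0.7.
SR_TRANSMISSION = 0.65

X_VARIABLES = ("X1", "X2", "X3", "X4", "X5", "X6")

RESPONSES = (
    "RH_control", "RH_heat",
    "Tmax_control", "Tmax_heat",
    "Tmin_control", "Tmin_heat",
)


@dataclass(frozen=True)
class PolyTerm:
    """One polynomial term ``coef * var**power`` of a regression."""

    var: str
    power: int
    coef: float

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError(f"term power must be >= 1, got {self.power}")
        if not np.isfinite(self.coef):
            raise ValueError(f"non-finite coefficient for {self.var}^{self.power}")


@dataclass(frozen=True)
class PRModel:
    """Additive polynomial regression with fit diagnostics.

    ``sigma`` is the residual standard deviation, used when simulating noisy
    responses from a model. Diagnostics are ``None`` for hand-specified
    models and populated by :func:`fit_pr`.
    """

    response: str
    intercept: float
    terms: tuple[PolyTerm, ...]
    r2: float | None = None
    cv_rmse: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            key = (t.var, t.power)
            if key in seen:
                raise ValueError(f"duplicate term {t.var}^{t.power}")
            seen.add(key)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t.var for t in self.terms))


@dataclass(frozen=True)
class GreenhouseWeatherDay:
    """One day of in-greenhouse weather.

    ``sr`` is the solar radiation reaching the canopy *inside* the house
    (outside radiation scaled by the envelope transmission), in the same
    units as the external tables. ``regime`` is the temperature treatment of
    the house ("control" or "heat").
    """

    date: Date
    tmax: float
    tmin: float
    rh: float
    regime: str
    sr: float = 0.0

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise ValueError(f"tmin {self.tmin} > tmax {self.tmax} on {self.date}")
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError(f"rh {self.rh} outside [0, 1] on {self.date}")
        if self.sr < 0:
            raise ValueError(f"negative solar radiation on {self.date}")
        if self.regime not in ("control", "heat"):
            raise ValueError(f"unknown regime {self.regime!r}")


def _model(response: str, intercept: float,
           terms: Sequence[tuple[str, int, float]], r2: float) -> PRModel:
    return PRModel(response=response, intercept=intercept,
                   terms=tuple(PolyTerm(v, p, c) for v, p, c in terms), r2=r2)


#: The six published greenhouse-climate regressions for the Wanju site
#: (fitted there on 175 days of 2022-2023 data; the attached r2 values are
#: the published ones and are metadata only -- the underlying daily dataset
#: is not public, so they cannot be recomputed here).
PUBLISHED_MODELS: Mapping[str, PRModel] = {
    "RH_control": _model("RH_control", 0.539429,
                         [("X1", 1, -0.009796), ("X1", 2, 0.000204),
                          ("X2", 1, 0.475429)], 0.90),
    "RH_heat": _model("RH_heat", 0.698088,
                      [("X1", 1, -0.012741), ("X1", 2, 0.000199),
                       ("X2", 1, 0.277417)], 0.89),
    "Tmax_control": _model("Tmax_control", 1.78009,
                           [("X1", 1, 0.80236), ("X1", 2, -0.01807),
                            ("X3", 1, 0.79777), ("X4", 2, 0.00825)], 0.84),
    "Tmax_heat": _model("Tmax_heat", 13.19313,
                        [("X1", 1, 0.82980), ("X1", 2, -0.01929),
                         ("X3", 1, 0.54994), ("X4", 2, 0.00511)], 0.78),
    "Tmin_control": _model("Tmin_control", -4.8907,
                           [("X1", 1, -0.0277), ("X2", 1, 5.6565),
                            ("X3", 1, 0.0939), ("X4", 1, 0.9181),
                            ("X6", 1, 0.3364)], 0.98),
    "Tmin_heat": _model("Tmin_heat", -4.0764,
                        [("X1", 1, -0.0339), ("X2", 1, 6.2056),
                         ("X3", 1, 0.1138), ("X4", 1, 0.8767),
                         ("X6", 1, 0.2621)], 0.97),
}


def eval_pr(model: PRModel, x: Mapping[str, float]):
    """Evaluate ``intercept + sum coef * x[var]**power``.

    Values in ``x`` may be scalars or numpy arrays (broadcast). No clamping
    is applied at this level. Raises ``ValueError`` naming the first missing
    variable.
    """
    out = model.intercept
    for t in model.terms:
        if t.var not in x:
            raise ValueError(
                f"model {model.response} needs variable {t.var!r}, "
                f"not present in input")
        out = out + t.coef * np.asarray(x[t.var]) ** t.power
    return out


def external_day_to_x(day: "ExternalWeatherDay") -> dict[str, float]:
    """Map an external weather day onto the X1..X6 predictor convention."""
    return {"X1": day.sr, "X2": day.rh, "X3": day.tmax,
            "X4": day.tmin, "X5": day.precip, "X6": day.wind}


def predict_greenhouse_day(day: "ExternalWeatherDay", regime: str,
                           models: Mapping[str, PRModel] | None = None,
                           sr_transmission: float = SR_TRANSMISSION,
                           ) -> GreenhouseWeatherDay:
    """Predict one in-greenhouse day from an external day.

    Humidity is clamped to [0, 1]; if the predicted minimum temperature
    exceeds the predicted maximum (possible for adversarial inputs, the two
    responses being independent regressions), tmin is clamped down to tmax
    and a warning is logged.
    """
    if regime not in ("control", "heat"):
        raise ValueError(f"regime must be 'control' or 'heat', got {regime!r}")
    models = PUBLISHED_MODELS if models is None else models
    x = external_day_to_x(day)
    rh = float(np.clip(eval_pr(models[f"RH_{regime}"], x), 0.0, 1.0))
    tmax = float(eval_pr(models[f"Tmax_{regime}"], x))
    tmin = float(eval_pr(models[f"Tmin_{regime}"], x))
    if tmin > tmax:
        log.warning("predicted tmin %.2f > tmax %.2f on %s (%s); clamping",
                    tmin, tmax, day.date, regime)
        tmin = tmax
    return GreenhouseWeatherDay(date=day.date, tmax=tmax, tmin=tmin, rh=rh,
                                regime=regime, sr=day.sr * sr_transmission)


def predict_greenhouse_series(series: Sequence["ExternalWeatherDay"],
                              regime: str, **kw) -> list[GreenhouseWeatherDay]:
    return [predict_greenhouse_day(d, regime, **kw) for d in series]


# ---------------------------------------------------------------------------
# Refitting


def _screen_candidates(data: pd.DataFrame, y: pd.Series,
                       candidates: Sequence[str], alpha: float,
                       collinearity_threshold: float) -> list[str]:
    """Variable screening: Pearson-significance filter, then drop the weaker
    member of any surviving pair whose mutual |r| reaches the threshold."""
    strength: dict[str, float] = {}
    for var in candidates:
        r, p = sps.pearsonr(data[var], y)
        if p < alpha:
            strength[var] = abs(r)
        else:
            log.debug("screening: %s dropped (r=%.3f, p=%.3f)", var, r, p)
    survivors = sorted(strength, key=strength.get, reverse=True)
    kept: list[str] = []
    for var in survivors:  # strongest first; greedy exclusion
        r_pair = [abs(sps.pearsonr(data[var], data[u])[0]) for u in kept]
        if any(r >= collinearity_threshold for r in r_pair):
            log.debug("screening: %s dropped (collinear with kept variable)", var)
            continue
        kept.append(var)
    return kept


def fit_pr(data: pd.DataFrame, response: str, max_order: int = 2,
           alpha: float = 0.05, collinearity_threshold: float = 0.5,
           k: int = 5, seed: int | None = None,
           term_spec: Mapping[str, Sequence[int]] | None = None,
           cv: str = "blocks") -> PRModel:
    """Fit a polynomial regression with the published selection procedure.

    1. Drop candidate variables whose Pearson correlation with the response
       is not significant at ``alpha`` (two-sided t test on r).
    2. Among survivors, when two variables correlate at |r| >=
       ``collinearity_threshold``, keep the one more strongly correlated
       with the response.
    3. Fit, by OLS, all powers 1..``max_order`` of each retained variable
       (or exactly the powers listed in ``term_spec`` for variables named
       there -- the published models keep e.g. only the square of X4, and
       that per-term choice is an explicit override, not automated).
    4. Report in-sample R^2 and k-fold cross-validated RMSE. Folds are
       contiguous-in-time blocks by default (``cv="random"`` shuffles with
       ``seed``).

    Requires at least twice as many rows as fitted terms.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    y = data[response]
    candidates = [c for c in data.columns
                  if c != response and np.issubdtype(data[c].dtype, np.number)]
    kept = _screen_candidates(data, y, candidates, alpha, collinearity_threshold)
    if not kept:
        raise ValueError(
            f"no candidate variable is significantly correlated with "
            f"{response} at alpha={alpha}; consider relaxing alpha")

    term_keys: list[tuple[str, int]] = []
    for var in kept:
        powers = (term_spec.get(var, range(1, max_order + 1))
                  if term_spec else range(1, max_order + 1))
        term_keys.extend((var, int(p)) for p in powers)

    n = len(data)
    if n < 2 * (len(term_keys) + 1):
        raise ValueError(
            f"need at least {2 * (len(term_keys) + 1)} rows to fit "
            f"{len(term_keys)} terms, got {n}")

    X = np.column_stack([data[v].to_numpy(float) ** p for v, p in term_keys])
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear terms)")
    res = sm.OLS(y.to_numpy(float), Xc).fit()

    # k-fold CV on the final term set
    idx = np.arange(n)
    if cv == "random":
        idx = np.random.default_rng(seed).permutation(n)
    elif cv != "blocks":
        raise ValueError(f"cv must be 'blocks' or 'random', got {cv!r}")
    folds = np.array_split(idx, k)
    sq_errs: list[float] = []
    yv = y.to_numpy(float)
    for test_idx in folds:
        train = np.setdiff1d(idx, test_idx)
        beta, *_ = np.linalg.lstsq(Xc[train], yv[train], rcond=None)
        pred = Xc[test_idx] @ beta
        sq_errs.extend((yv[test_idx] - pred) ** 2)
    cv_rmse = float(np.sqrt(np.mean(sq_errs)))

    terms = tuple(PolyTerm(v, p, float(c))
                  for (v, p), c in zip(term_keys, res.params[1:]))
    return PRModel(response=response, intercept=float(res.params[0]),
                   terms=terms, r2=float(res.rsquared), cv_rmse=cv_rmse,
                   sigma=float(np.sqrt(res.mse_resid)))


def simulate_response(model: PRModel, data: pd.DataFrame,
                      seed: int | None = None, sigma: float | None = None
                      ) -> np.ndarray:
    """Draw a noisy response from ``model`` over predictor rows in ``data``.

    ``sigma`` defaults to the model's stored residual SD (0 if unset).
    """
    x = {v: data[v].to_numpy(float) for v in model.variables}
    mean = eval_pr(model, x)
    s = model.sigma if sigma is None else sigma
    if not s:
        return np.asarray(mean, float)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed or 0, zlib.crc32(model.response.encode())]))
    return np.asarray(mean, float) + rng.normal(0.0, s, size=len(data))


# ---------------------------------------------------------------------------
# JSON round-trip


def model_to_dict(model: PRModel) -> dict:
    return {"response": model.response, "intercept": model.intercept,
            "terms": [{"var": t.var, "power": t.power, "coef": t.coef}
                      for t in model.terms],
            "r2": model.r2, "cv_rmse": model.cv_rmse, "sigma": model.sigma}


def model_from_dict(d: Mapping) -> PRModel:
    return PRModel(response=d["response"], intercept=d["intercept"],
                   terms=tuple(PolyTerm(t["var"], t["power"], t["coef"])
                               for t in d["terms"]),
                   r2=d.get("r2"), cv_rmse=d.get("cv_rmse"), sigma=d.get("sigma"))


def model_to_json(model: PRModel) -> str:
    return json.dumps(model_to_dict(model), indent=2)


def model_from_json(text: str) -> PRModel:
    return model_from_dict(json.loads(text))
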