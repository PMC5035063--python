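"""Water productivity, photothermal quotient and treatment summaries.

Water productivity is reported with respect to evapotranspiration
(WP_ET = grain yield / seasonal ET) and to irrigation
(WP_I = grain yield / irrigation applied), both in kg ha-1 mm-1.  The
photothermal quotient (PTQ, MJ m-2 d-1 degC-1) indexes growth per unit
development time over the maximum-tillering-to-anthesis window:

    T >= 10        PTQ = radiation / (T - 4.5)
    4.5 <= T <= 10 PTQ = radiation x [(T - 4.5)/5.5] / 5.5
    T <= 4.5       PTQ = 0

with T the daily mean temperature.  The piecewise form is intentionally
discontinuous at T = 10 and is implemented exactly as published practice
uses it.  Scenario summaries give per-treatment means over years, paired
mulch-minus-bare differences, and empirical exceedance curves of those
differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .weather import WeatherSeries

__all__ = [
    "wp_et",
    "wp_i",
    "ptq_daily",
    "ptq_period",
    "count_hot_grainfill_days",
    "summarize_scenario",
    "mulch_difference_table",
    "exceedance_curve",
    "yield_decline_rate",
]

SUMMARY_FIELDS = [
    "yield_kg_ha", "irrigation_n", "irrigation_mm", "es_mm",
    "transpiration_mm", "et_mm", "drainage_mm", "runoff_mm", "dswc_mm",
    "wp_et", "wp_i", "mean_stress_index", "hot_grainfill_days",
]
GROUP_KEYS = ["soil", "mulch", "sowing", "policy"]


def wp_et(yield_kg_ha: float, et_mm: float) -> float:
    """Grain yield per mm of seasonal evapotranspiration."""
    if et_mm <= 0:
        raise ValueError("ET must be positive")
    return yield_kg_ha / et_mm


def wp_i(yield_kg_ha: float, irrigation_mm: float) -> float:
    """Grain yield per mm of irrigation; undefined (NaN) for rainfed."""
    if irrigation_mm <= 0:
        raise ValueError("irrigation must be positive; rainfed WP_I is undefined")
    return yield_kg_ha / irrigation_mm


def ptq_daily(radn: float, tmean: float) -> float:
    """Daily photothermal quotient, piecewise in mean temperature."""
    if radn < 0:
        raise ValueError("radiation must be non-negative")
    if tmean >= 10.0:
        return radn / (tmean - 4.5)
    if tmean >= 4.5:
        return radn * ((tmean - 4.5) / 5.5) / 5.5
    return 0.0


def ptq_period(weather: WeatherSeries, start, end) -> float:
    """Mean daily PTQ over [start, end], with T = (Tmax + Tmin)/2."""
    f = weather.slice(start, end).frame
    if len(f) == 0:
        raise ValueError("empty PTQ window")
    tmean = (f["tmax"] + f["tmin"]) / 2.0
    vals = [ptq_daily(r, t) for r, t in zip(f["radn"], tmean)]
    return float(np.mean(vals))


def count_hot_grainfill_days(weather: WeatherSeries, start, end,
                             threshold: float = 34.0) -> int:
    """Days in the grain-fill window with Tmax above the threshold."""
    f = weather.slice(start, end).frame
    return int((f["tmax"] > threshold).sum())


def summarize_scenario(results: pd.DataFrame,
                       group_keys: list[str] | None = None) -> pd.DataFrame:
    """Per-treatment means over years of yield, water balance and WP.

    WP is reported both as the mean of per-year ratios (``wp_et``/``wp_i``
    columns, NaN-skipping so rainfed years do not poison WP_I) and as the
    ratio of the group means (``wp_et_rm``/``wp_i_rm``), since both
    conventions are in field use.
    """
    keys = group_keys or [k for k in GROUP_KEYS if k in results.columns]
    fields = [f for f in SUMMARY_FIELDS if f in results.columns]
    out = results.groupby(keys, dropna=False)[fields].mean(numeric_only=False)
    grp = results.groupby(keys, dropna=False)
    out["wp_et_rm"] = grp["yield_kg_ha"].mean() / grp["et_mm"].mean()
    irr = grp["irrigation_mm"].mean()
    out["wp_i_rm"] = (grp["yield_kg_ha"].mean() / irr).where(irr > 0)
    return out.reset_index()


def mulch_difference_table(results: pd.DataFrame,
                           value: str = "yield_kg_ha") -> pd.DataFrame:
    """Paired (same year/soil/date/policy) mulch-minus-bare differences."""
    keys = [k for k in ("soil", "sowing", "policy", "year")
            if k in results.columns]
    piv = results.pivot_table(index=keys, columns="mulch", values=value,
                              aggfunc="first")
    if True not in piv.columns or False not in piv.columns:
        raise ValueError("need both mulched and bare seasons for differences")
    if piv[True].isna().any() or piv[False].isna().any():
        raise ValueError("unpaired mulch/bare seasons")
    out = piv.reset_index()
    out["difference"] = out[True] - out[False]
    return out.drop(columns=[True, False])


def exceedance_curve(differences) -> pd.DataFrame:
    """Empirical exceedance: sorted differences vs probability of exceeding.

    Probability uses the (i - 0.5)/n plotting position on descending values.
    """
    vals = np.sort(np.asarray(differences, dtype=float))[::-1]
    n = len(vals)
    if n == 0:
        raise ValueError("no differences supplied")
    prob = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"difference": vals, "exceedance_probability": prob})


def yield_decline_rate(mean_a: float, mean_b: float, days_between: float) -> float:
    """(mean at date A - mean at date B) / days between, same units per day."""
    if days_between <= 0:
        raise ValueError("days_between must be positive")
    return (mean_a - mean_b) / days_between
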