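"""Daily weather series: file I/O, validation and stochastic generation.

The simulations are driven by daily maximum/minimum temperature (degC),
solar radiation (MJ m-2 d-1) and rainfall (mm).  Because no long weather
record ships with the package, :func:`generate_synthetic_weather` produces
multi-year series whose monthly statistics match a set of
:class:`ClimateNormals` (mean Tmax/Tmin/radiation per month, mean monthly
rainfall total with an observed range).  Rainfall is event-based — most
days are dry and the monthly total falls in a handful of skewed events —
which is the dominant feature of the semi-arid NW-Indian wheat season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MonthNormal",
    "ClimateNormals",
    "WeatherSeries",
    "WeatherFormatError",
    "read_weather_table",
    "write_weather_table",
    "generate_synthetic_weather",
    "monthly_summary",
    "monthly_climatology",
]

WEATHER_COLUMNS = ["date", "tmax", "tmin", "radn", "rain"]

#: Days a rainfall event's radiation is scaled by (cloud cover on wet days).
WET_DAY_RADN_FACTOR = 0.6

#: Shape of the gamma distribution for monthly rain totals (strongly skewed).
RAIN_GAMMA_SHAPE = 0.75


class WeatherFormatError(ValueError):
    """Raised when a weather table violates the format or its invariants."""


@dataclass(frozen=True)
class MonthNormal:
    """Climate normals for one calendar month."""

    tmax: float
    tmin: float
    radn: float
    rain_mean: float
    rain_min: float
    rain_max: float
    observed: bool = True

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError("mean tmax below mean tmin")
        if self.radn < 0 or self.rain_mean < 0:
            raise ValueError("negative radiation or rainfall normal")
        if not (self.rain_min <= self.rain_mean <= self.rain_max):
            raise ValueError("rainfall range does not contain the mean")


@dataclass(frozen=True)
class ClimateNormals:
    """Twelve :class:`MonthNormal` entries keyed by calendar month (1-12)."""

    months: dict[int, MonthNormal]
    latitude: float = 30.9

    def __post_init__(self) -> None:
        if sorted(self.months) != list(range(1, 13)):
            raise ValueError("normals must cover months 1..12 exactly")

    def array(self, attr: str) -> np.ndarray:
        """Values of one attribute as a 12-vector ordered Jan..Dec."""
        return np.array([getattr(self.months[m], attr) for m in range(1, 13)])


@dataclass
class WeatherSeries:
    """An ordered run of daily weather records plus the site latitude.

    ``frame`` holds columns ``date`` (datetime64), ``tmax``, ``tmin``,
    ``radn`` and ``rain``.  Dates must be strictly increasing with no gaps.
    """

    frame: pd.DataFrame
    latitude: float = 30.9

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        validate_weather_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def slice(self, start, end) -> "WeatherSeries":
        """Sub-series covering ``start`` .. ``end`` inclusive."""
        f = self.frame
        mask = (f["date"] >= pd.Timestamp(start)) & (f["date"] <= pd.Timestamp(end))
        return WeatherSeries(f.loc[mask].copy(), self.latitude)


def validate_weather_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise WeatherFormatError(f"missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        return
    dates = frame["date"]
    if not pd.api.types.is_datetime64_any_dtype(dates):
        raise WeatherFormatError("date column is not parsed as dates")
    deltas = dates.diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        row = int(deltas.index[deltas <= pd.Timedelta(0)][0])
        raise WeatherFormatError(f"dates not strictly increasing at row {row}")
    if (deltas > pd.Timedelta(days=1)).any():
        row = int(deltas.index[deltas > pd.Timedelta(days=1)][0])
        raise WeatherFormatError(f"gap in daily dates at row {row}")
    for cond, msg in [
        (frame["tmax"] < frame["tmin"], "tmax < tmin"),
        (frame["radn"] < 0, "negative radiation"),
        (frame["rain"] < 0, "negative rainfall"),
    ]:
        if cond.any():
            row = int(np.flatnonzero(cond.to_numpy())[0])
            raise WeatherFormatError(f"{msg} at row {row}")


def read_weather_table(path, latitude: float = 30.9) -> WeatherSeries:
    """Read a daily weather table from delimited text.

    Accepts the CSV dialect (``date,tmax,tmin,radn,rain`` header, ISO dates)
    or a whitespace-separated table with the same header (".met"-style).
    Rejects malformed files with the offending row number.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "," if "," in header else r"\s+"
    frame = pd.read_csv(path, sep=sep, comment="!")
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise WeatherFormatError(f"missing column(s): {', '.join(missing)}")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherFormatError(f"unparseable date: {exc}") from exc
    return WeatherSeries(frame[WEATHER_COLUMNS], latitude)


def write_weather_table(series: WeatherSeries, path) -> None:
    """Write a series as CSV (ISO dates) readable by :func:`read_weather_table`."""
    out = series.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _mean_preserving_knots(normals: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Knot values at month midpoints whose piecewise-linear daily curve has
    monthly means equal to ``normals`` (fixed-point correction)."""
    knots = normals.astype(float).copy()
    doy = np.arange(365)
    month_len = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    mid = np.cumsum(month_len) - month_len / 2.0
    month_of_day = np.repeat(np.arange(12), month_len)
    for _ in range(n_iter):
        daily = _interp_periodic(doy, mid, knots)
        means = np.array([daily[month_of_day == m].mean() for m in range(12)])
        knots += normals - means
    return knots


def _interp_periodic(doy: np.ndarray, mid: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation over a 365-day year."""
    xp = np.concatenate([[mid[-1] - 365.0], mid, [mid[0] + 365.0]])
    fp = np.concatenate([[knots[-1]], knots, [knots[0]]])
    return np.interp(doy, xp, fp)


@lru_cache(maxsize=64)
def _gamma_mean_for_truncated_target(target: float, lo: float, hi: float) -> float:
    """Underlying gamma mean whose [lo, hi]-truncated expectation equals
    ``target`` (bisection; truncation to the printed range would otherwise
    bias wet months low)."""
    k = RAIN_GAMMA_SHAPE

    def trunc_mean(m: float) -> float:
        sc = m / k
        p = stats.gamma.cdf(hi, k, scale=sc) - stats.gamma.cdf(lo, k, scale=sc)
        if p <= 0:
            return hi
        partial = stats.gamma.cdf(hi, k + 1, scale=sc) - stats.gamma.cdf(lo, k + 1, scale=sc)
        return m * partial / p

    a, b = target, 10.0 * target
    if trunc_mean(b) < target:  # target unreachable within the range
        return b
    for _ in range(60):
        mid = 0.5 * (a + b)
        if trunc_mean(mid) < target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def _truncated_gamma(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    """Skewed monthly total: gamma draw resampled into [lo, hi], with the
    underlying mean adjusted so the truncated mean equals ``mean``."""
    if mean <= 0:
        return 0.0
    scale = _gamma_mean_for_truncated_target(mean, lo, hi) / RAIN_GAMMA_SHAPE
    for _ in range(200):
        x = rng.gamma(RAIN_GAMMA_SHAPE, scale)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_synthetic_weather(
    normals: ClimateNormals,
    n_years: int,
    seed: int,
    start_year: int = 1981,
) -> WeatherSeries:
    """Generate ``n_years`` calendar years of daily weather matching ``normals``.

    Temperatures and radiation follow smooth mean-preserving seasonal curves
    (piecewise linear between month midpoints, corrected so every month's
    long-run mean equals its normal) plus autocorrelated day-to-day noise.
    Monthly rain totals are gamma-distributed around the normal mean,
    truncated to the observed range, and split over a small random number of
    event days; radiation is reduced on wet days.  Fully reproducible from
    ``seed``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)

    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(dates)
    doy = np.minimum(dates.dayofyear.to_numpy(), 365) - 1  # fold leap day
    month = dates.month.to_numpy()
    year = dates.year.to_numpy()

    month_len = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    mid = np.cumsum(month_len) - month_len / 2.0
    base = {}
    for attr in ("tmax", "tmin", "radn"):
        knots = _mean_preserving_knots(normals.array(attr))
        base[attr] = _interp_periodic(doy, mid, knots)

    # AR(1) temperature anomalies: one shared synoptic signal plus
    # independent components, stationary sd ~2.5 degC.
    rho = 0.6
    innov_sd = np.sqrt(1.0 - rho**2)
    shared = np.empty(n)
    shared[0] = rng.normal(0, 1)
    eps = rng.normal(0, innov_sd, n)
    for i in range(1, n):
        shared[i] = rho * shared[i - 1] + eps[i]
    tmax = base["tmax"] + 2.2 * shared + rng.normal(0, 1.1, n)
    tmin = base["tmin"] + 1.6 * shared + rng.normal(0, 1.0, n)
    tmax = np.maximum(tmax, tmin + 0.5)

    # Radiation: multiplicative noise, mean one.  The wet-day cloud factor
    # below would bias monthly means low, so the clear-sky base is raised by
    # each month's expected wet-day fraction.
    sigma_r = 0.15
    comp = np.ones(12)
    for m in range(1, 13):
        nm = normals.months[m]
        if nm.rain_mean > 0:
            expected_events = 1.0 + min(4.0, nm.rain_mean / 15.0)
            p_wet = min(1.0, expected_events / month_len[m - 1])
            comp[m - 1] = 1.0 / (1.0 - (1.0 - WET_DAY_RADN_FACTOR) * p_wet)
    radn = (base["radn"] * comp[month - 1]
            * rng.lognormal(-0.5 * sigma_r**2, sigma_r, n))

    rain = np.zeros(n)
    for yr in np.unique(year):
        for m in range(1, 13):
            idx = np.flatnonzero((year == yr) & (month == m))
            norm = normals.months[m]
            total = _truncated_gamma(rng, norm.rain_mean, norm.rain_min, norm.rain_max)
            if total <= 0:
                continue
            n_events = 1 + rng.poisson(min(4.0, total / 15.0))
            n_events = min(n_events, len(idx))
            days = rng.choice(idx, size=n_events, replace=False)
            weights = rng.dirichlet(np.full(n_events, 0.8))
            rain[days] += total * weights
    wet = rain > 0.2
    radn = np.where(wet, radn * WET_DAY_RADN_FACTOR, radn)
    radn = np.clip(radn, 0.5, None)

    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax": np.round(tmax, 2),
            "tmin": np.round(tmin, 2),
            "radn": np.round(radn, 2),
            "rain": np.round(rain, 2),
        }
    )
    return WeatherSeries(frame, normals.latitude)


def monthly_summary(series: WeatherSeries) -> pd.DataFrame:
    """Per (year, month): mean tmax/tmin/radn and total rain."""
    if len(series) == 0:
        raise ValueError("empty weather series")
    f = series.frame
    g = f.groupby([f["date"].dt.year.rename("year"), f["date"].dt.month.rename("month")])
    out = g.agg(tmax=("tmax", "mean"), tmin=("tmin", "mean"), radn=("radn", "mean"),
                rain=("rain", "sum"), n_days=("rain", "size"))
    return out.reset_index()


def monthly_climatology(series: WeatherSeries) -> pd.DataFrame:
    """Across-year means of the monthly summaries, indexed by month."""
    per_month = monthly_summary(series)
    return per_month.groupby("month")[["tmax", "tmin", "radn", "rain"]].mean()
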