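"""Daily climate forcing for the mosquito population model.

The stage-structured ODE is driven by four forcings derived from a daily
station record: the raw daily mean temperature ``T(t)`` and daily cumulative
precipitation ``R(t)``, the half-month mean temperature ``T_month(t)`` that
controls the diapause switch, and the standardized trailing-week
precipitation ``R_norm(t)`` entering the emergence-success term.

All forcings are exposed to the solver as piecewise-constant (day-step)
functions of continuous time, right-continuous at day boundaries, so that a
simulation is exactly reproducible regardless of solver step placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "DerivedForcing",
    "read_climate_csv",
    "half_month_mean_temperature",
    "weekly_precip_norm",
    "derive_forcing",
    "forcing_at",
]


@dataclass
class ClimateSeries:
    """A validated daily climate record for one city.

    Attributes
    ----------
    city_id : str
        Label of the station/city.
    dates : pandas.DatetimeIndex
        Consecutive calendar days, strictly increasing, no gaps.
    temp : numpy.ndarray
        Daily mean temperature (deg C).
    precip : numpy.ndarray
        Daily cumulative precipitation (mm), nonnegative.
    """

    city_id: str
    dates: pd.DatetimeIndex
    temp: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        self.temp = np.asarray(self.temp, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        n = len(self.dates)
        if len(self.temp) != n or len(self.precip) != n:
            raise ValueError("dates, temp and precip must have equal length")
        if n == 0:
            raise ValueError("empty climate series")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if n > 1 and not np.all(deltas == 1):
            bad = int(np.flatnonzero(deltas != 1)[0])
            raise ValueError(
                f"dates must be consecutive days; gap/disorder after row {bad} "
                f"({self.dates[bad].date()} -> {self.dates[bad + 1].date()})"
            )
        if np.any(self.precip < 0):
            bad = int(np.flatnonzero(self.precip < 0)[0])
            raise ValueError(
                f"negative precipitation at row {bad} ({self.dates[bad].date()}): "
                f"{self.precip[bad]}"
            )
        if not (np.all(np.isfinite(self.temp)) and np.all(np.isfinite(self.precip))):
            raise ValueError("non-finite values in climate series")

    def __len__(self) -> int:
        return len(self.dates)

    def day_index(self, date) -> int:
        """Integer day offset of ``date`` from the first record."""
        return int((pd.Timestamp(date) - self.dates[0]).days)


@dataclass
class DerivedForcing:
    """Forcings derived from a :class:`ClimateSeries`, one value per day.

    ``t_month`` is constant within each calendar half-month block;
    ``r_norm`` is the trailing 7-day precipitation sum min-max scaled to
    [0, 1] so the ``(R_norm + 1)`` denominator of the emergence term never
    vanishes.
    """

    t_month: np.ndarray
    r_week: np.ndarray
    r_norm: np.ndarray
    scale_max: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.any(self.r_norm < 0):
            raise ValueError("r_norm must be nonnegative")


def read_climate_csv(path, city_id: str | None = None) -> ClimateSeries:
    """Read a daily climate CSV with columns ``date, temp_c, precip_mm``.

    A long-format file with an additional ``city`` column is accepted when
    ``city_id`` selects one city. Gaps of at most 2 consecutive missing days
    are filled by linear interpolation; longer gaps are an error.
    """
    df = pd.read_csv(path)
    required = {"date", "temp_c", "precip_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV {path} missing columns: {sorted(missing)}")
    if "city" in df.columns:
        if city_id is None:
            cities = df["city"].unique()
            if len(cities) > 1:
                raise ValueError(
                    f"{path} contains {len(cities)} cities; pass city_id to select one"
                )
            city_id = str(cities[0])
        df = df[df["city"] == city_id]
        if df.empty:
            raise ValueError(f"city {city_id!r} not found in {path}")
    dates = pd.to_datetime(df["date"])
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        bad = int(np.flatnonzero(~np.concatenate(([True], np.diff(dates.values) > np.timedelta64(0))))[0]) \
            if not dates.is_monotonic_increasing else int(np.flatnonzero(dates.duplicated())[0])
        raise ValueError(f"dates not strictly increasing at row {bad} ({dates.iloc[bad].date()})")
    neg = df["precip_mm"] < 0
    if neg.any():
        bad = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValueError(
            f"negative precipitation at row {bad} ({dates.iloc[bad].date()}): "
            f"{df['precip_mm'].iloc[bad]}"
        )
    # reindex onto the full daily range; interpolate short gaps
    full = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    gap = len(full) - len(dates)
    if gap > 0:
        present = pd.Series(True, index=pd.DatetimeIndex(dates))
        present = present.reindex(full, fill_value=False)
        runs = _max_missing_run(present.to_numpy())
        if runs > 2:
            first_missing = full[~present.to_numpy()][0]
            raise ValueError(
                f"gap of {runs} consecutive missing days (starting {first_missing.date()}) "
                "exceeds the 2-day interpolation limit"
            )
    frame = (
        pd.DataFrame({"temp_c": df["temp_c"].to_numpy(), "precip_mm": df["precip_mm"].to_numpy()},
                     index=pd.DatetimeIndex(dates))
        .reindex(full)
        .interpolate(method="time", limit_area="inside")
    )
    return ClimateSeries(
        city_id=city_id if city_id is not None else "city",
        dates=full,
        temp=frame["temp_c"].to_numpy(),
        precip=frame["precip_mm"].to_numpy(),
    )


def _max_missing_run(present: np.ndarray) -> int:
    worst = run = 0
    for p in present:
        run = 0 if p else run + 1
        worst = max(worst, run)
    return worst


def half_month_mean_temperature(series: ClimateSeries) -> np.ndarray:
    """Half-month block mean temperature, one value per day.

    Every day in a calendar half-month block (1st-15th, 16th-end) carries the
    mean daily temperature of that block — the cadence of the mosquito
    surveillance index, and the signal controlling diapause switching.
    """
    return _block_broadcast(series.dates, series.temp, np.mean)


def _half_month_key(dates: pd.DatetimeIndex) -> np.ndarray:
    return dates.year * 10000 + dates.month * 100 + (dates.day > 15).astype(int)


def half_month_edges(dates: pd.DatetimeIndex) -> np.ndarray:
    """Start offsets of each calendar half-month block; sentinel end appended."""
    key = _half_month_key(dates)
    starts = np.flatnonzero(np.concatenate(([True], key[1:] != key[:-1])))
    return np.concatenate((starts, [len(dates)]))


def _block_broadcast(dates: pd.DatetimeIndex, values: np.ndarray, reducer) -> np.ndarray:
    edges = half_month_edges(dates)
    out = np.empty_like(np.asarray(values, dtype=float))
    for a, b in zip(edges[:-1], edges[1:]):
        out[a:b] = reducer(values[a:b])
    return out


def weekly_precip_norm(series: ClimateSeries, scale_max: float | None = None) -> DerivedForcing:
    """Standardized trailing-week precipitation in [0, 1].

    The trailing 7-day cumulative precipitation (partial sums over the first
    6 days) is divided by ``scale_max`` and clipped at 1. By default
    ``scale_max`` is the series' own maximum trailing 7-day sum, i.e. the
    training-window maximum.
    """
    r_week = trailing_week_sum(series.precip)
    if scale_max is None:
        scale_max = float(r_week.max())
        if scale_max == 0.0:
            scale_max = 1.0  # all-dry record: r_norm is identically 0
    if scale_max <= 0:
        raise ValueError(f"scale_max must be positive, got {scale_max}")
    r_norm = np.minimum(r_week / scale_max, 1.0)
    return DerivedForcing(
        t_month=half_month_mean_temperature(series),
        r_week=r_week,
        r_norm=r_norm,
        scale_max=float(scale_max),
    )


def trailing_week_sum(precip: np.ndarray) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(np.asarray(precip, dtype=float))))
    n = len(precip)
    lo = np.maximum(np.arange(n) - 6, 0)
    return c[np.arange(1, n + 1)] - c[lo]


# ``derive_forcing`` is the one-call path used by the simulation layer.
derive_forcing = weekly_precip_norm


def forcing_at(series: ClimateSeries, forcing: DerivedForcing, t: float):
    """Forcing tuple ``(T, R, T_month, R_norm)`` at continuous time ``t``.

    ``t`` is in days since the first record. Lookup is piecewise constant per
    day and right-continuous at day boundaries; ``t == len(series)`` returns
    the final day's values so solvers may evaluate the closing endpoint.
    """
    n = len(series)
    if not (0 <= t <= n):
        raise ValueError(f"t={t} outside the covered range [0, {n}]")
    d = min(int(np.floor(t)), n - 1)
    return (
        float(series.temp[d]),
        float(series.precip[d]),
        float(forcing.t_month[d]),
        float(forcing.r_norm[d]),
    )
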