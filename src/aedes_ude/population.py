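"""The two-stage (immature P, adult A) population ODE and its observables.

    dP/dt = b(T, R) * A - dp(T) * P - mp(T) * P
    dA/dt = ef(R_norm, P) * dp(T) * P - ma(T) * A

where ``b`` is a pluggable oviposition-rate function (the trained network, a
closed-form expression, or a constant), and the vital rates come from
:mod:`aedes_ude.vital_rates` under daily piecewise-constant climate forcing.

Observed abundance indices (MOI-like) are proportional to adult abundance,
published per calendar half-month; the observation map is the half-month
mean of daily adults times a per-city positive scale factor ("rotation
factor") ``lambda_j``, and the fitting loss is the mean absolute error
between scaled simulation and index.

The default solver is an implicit stiff method (scipy's Radau) applied
day-by-day — forcings are constant within a day, so each day is a smooth
autonomous problem and discontinuities never fall inside a solver step. A
fixed-step RK4 path (``method="rk4"``) provides an independent cross-check
and is the discretization the trainer differentiates through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import vital_rates as vr
from .climate import ClimateSeries, DerivedForcing, derive_forcing, half_month_edges
from .vital_rates import VitalParams

__all__ = [
    "PopulationState", "Trajectory", "MOISeries", "ScaleFactors",
    "simulate", "default_initial_condition", "half_month_aggregate",
    "loss", "fit_scale_factor", "read_moi_csv", "write_moi_csv",
]


@dataclass
class PopulationState:
    P: float  # immatures (egg+larva+pupa), individuals
    A: float  # adults, individuals

    def __post_init__(self):
        if self.P < 0 or self.A < 0:
            raise ValueError("population states must be nonnegative")


@dataclass
class Trajectory:
    """Daily-resolution solution: state at the start of each simulated day."""

    dates: pd.DatetimeIndex
    P: np.ndarray
    A: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "P": self.P, "A": self.A})


@dataclass
class MOISeries:
    """Half-month abundance-index observations for one city."""

    city_id: str
    periods: pd.DatetimeIndex   # start date of each half-month (1st or 16th)
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("abundance index values must be nonnegative")
        if len(self.periods) != len(self.values):
            raise ValueError("periods and values must align")


@dataclass
class ScaleFactors:
    """Per-city positive scale aligning simulated adults with the index."""

    lambda_j: dict  # city_id -> float > 0

    def __post_init__(self):
        for c, v in self.lambda_j.items():
            if not v > 0:
                raise ValueError(f"scale factor for {c} must be positive, got {v}")


def default_initial_condition():
    """Packaged starting point: 1e6 diapausing immatures, no adults, 2015-01-01.

    The first simulated year is burn-in — excluded from the loss — with
    evaluation starting 2016-01-01.
    """
    return PopulationState(P=1_000_000.0, A=0.0), pd.Timestamp("2015-01-01")


EVAL_START_DEFAULT = pd.Timestamp("2016-01-01")


def _daily_rates(series: ClimateSeries, p: VitalParams, forcing: DerivedForcing,
                 ovi: Callable):
    """Per-day rate coefficient arrays (b, dp, mp, ma, r_norm)."""
    T, R = series.temp, series.precip
    b = np.broadcast_to(np.asarray(ovi(T, R), dtype=float), T.shape).copy()
    dp = np.asarray(vr.development_rate(T, forcing.t_month, p))
    mp = np.asarray(vr.immature_mortality(T, forcing.t_month, p))
    ma = np.asarray(vr.adult_mortality(T, p))
    return b, dp, mp, ma, forcing.r_norm


def rhs_factory(b, dp, mp, ma, r_norm, day: int):
    """Autonomous RHS for one day's constant coefficients."""
    bi, di, mpi, mai, rni = b[day], dp[day], mp[day], ma[day], r_norm[day]
    alpha = vr.EMERGENCE_COEFFICIENT * di / (vr.CARRYING_CONSTANT * (rni + 1.0))

    def rhs(t, y):
        P, A = y
        ef = np.exp(-vr.EMERGENCE_COEFFICIENT - alpha * P)
        return (bi * A - (di + mpi) * P, ef * di * P - mai * A)

    return rhs


def simulate(series: ClimateSeries, p: VitalParams, ovi: Callable,
             init: PopulationState, t_start=None, t_end=None,
             forcing: DerivedForcing | None = None, method: str = "radau",
             rtol: float = 1e-6, atol: float = 1e-8, rk4_dt: float = 0.5,
             neg_tol: float = 1e-6) -> Trajectory:
    """Solve the two-stage ODE over [t_start, t_end] at daily output resolution.

    ``ovi`` maps vectorized (T, R) to an oviposition rate. ``method`` is
    ``"radau"`` (implicit stiff, per-day integration) or ``"rk4"``
    (fixed-step, ``rk4_dt`` days). Small solver undershoots below zero are
    clipped; undershoot beyond ``neg_tol`` (relative to 1 + max state) is an
    error naming the day.
    """
    t_start = series.dates[0] if t_start is None else pd.Timestamp(t_start)
    t_end = series.dates[-1] + pd.Timedelta(days=1) if t_end is None else pd.Timestamp(t_end)
    d0 = series.day_index(t_start)
    d1 = series.day_index(t_end)
    if d0 < 0 or d1 > len(series):
        raise ValueError("climate series does not cover the simulation window")
    if forcing is None:
        forcing = derive_forcing(series)
    coeffs = _daily_rates(series, p, forcing=forcing, ovi=ovi)

    n_days = d1 - d0
    P_out = np.empty(n_days + 1)
    A_out = np.empty(n_days + 1)
    y = np.array([init.P, init.A], dtype=float)
    P_out[0], A_out[0] = y

    if method == "rk4":
        n_sub = max(1, int(round(1.0 / rk4_dt)))
        dt = 1.0 / n_sub
        for k in range(n_days):
            rhs = rhs_factory(*coeffs, day=d0 + k)
            for _ in range(n_sub):
                y = _rk4_step(rhs, y, dt)
            y = _clip_state(y, k, neg_tol)
            P_out[k + 1], A_out[k + 1] = y
    elif method == "radau":
        for k in range(n_days):
            rhs = rhs_factory(*coeffs, day=d0 + k)
            sol = solve_ivp(rhs, (0.0, 1.0), y, method="Radau", rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"stiff solver failed on day {k} ({series.dates[d0 + k].date()}): {sol.message}")
            y = _clip_state(sol.y[:, -1], k, neg_tol)
            P_out[k + 1], A_out[k + 1] = y
    else:
        raise ValueError(f"unknown solver method {method!r}")

    dates = pd.date_range(t_start, periods=n_days + 1, freq="D")
    return Trajectory(dates=dates, P=P_out, A=A_out)


def _rk4_step(rhs, y, dt):
    k1 = np.asarray(rhs(0.0, y))
    k2 = np.asarray(rhs(0.0, y + 0.5 * dt * k1))
    k3 = np.asarray(rhs(0.0, y + 0.5 * dt * k2))
    k4 = np.asarray(rhs(0.0, y + dt * k3))
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _clip_state(y, day, neg_tol):
    scale = 1.0 + max(abs(y[0]), abs(y[1]))
    if np.any(y < -neg_tol * scale):
        raise RuntimeError(f"negative state beyond tolerance on day {day}: P={y[0]}, A={y[1]}")
    return np.maximum(y, 0.0)


def half_month_aggregate(traj: Trajectory, window_start=None, window_end=None):
    """Mean of daily adults within each calendar half-month of the window.

    Returns (period start dates, means). The window must cover whole
    half-month blocks; a partial trailing block is an error.
    """
    start = traj.dates[0] if window_start is None else pd.Timestamp(window_start)
    end = (traj.dates[-1] + pd.Timedelta(days=1)) if window_end is None else pd.Timestamp(window_end)
    mask = (traj.dates >= start) & (traj.dates < end)
    dates = traj.dates[mask]
    if len(dates) == 0:
        raise ValueError("aggregation window not covered by trajectory")
    A = traj.A[mask]
    edges = half_month_edges(dates)
    # verify whole blocks: first day must be a block start, last block complete
    if dates[0].day not in (1, 16):
        raise ValueError(f"window must start on the 1st or 16th, got {dates[0].date()}")
    last_block = dates[edges[-2]:]
    expect_end = _block_end(last_block[0])
    if last_block[-1] != expect_end:
        raise ValueError(
            f"partial trailing half-month: block starting {last_block[0].date()} "
            f"ends {last_block[-1].date()}, expected {expect_end.date()}"
        )
    means = np.add.reduceat(A, edges[:-1]) / np.diff(edges)
    return dates[edges[:-1]], means


def _block_end(day0: pd.Timestamp) -> pd.Timestamp:
    if day0.day == 1:
        return day0.replace(day=15)
    return day0 + pd.offsets.MonthEnd(0)


def loss(sim: dict, obs: dict, lam: ScaleFactors) -> float:
    """Mean absolute error between index observations and scaled simulation.

    ``sim`` maps city -> half-month adult means aligned with ``obs`` (city ->
    :class:`MOISeries`); averaged over all cities and periods.
    """
    total, count = 0.0, 0
    for city, series in obs.items():
        if city not in lam.lambda_j:
            raise KeyError(f"no scale factor for city {city!r}")
        s = np.asarray(sim[city], dtype=float)
        if len(s) != len(series.values):
            raise ValueError(f"misaligned periods for city {city!r}: {len(s)} vs {len(series.values)}")
        total += float(np.abs(series.values - lam.lambda_j[city] * s).sum())
        count += len(s)
    return total / count


def fit_scale_factor(sim, obs) -> float:
    """L1-optimal positive slope: argmin_lambda sum_t |obs_t - lambda*sim_t|.

    The objective is piecewise linear in lambda with kinks at the ratios
    obs_t/sim_t; the exact minimizer is the weighted median of those ratios
    with weights sim_t (lowest minimizer returned on a flat stretch).
    """
    s = np.asarray(sim, dtype=float)
    o = obs.values if isinstance(obs, MOISeries) else np.asarray(obs, dtype=float)
    if len(s) != len(o):
        raise ValueError("sim and obs must align")
    pos = s > 0
    if not pos.any():
        raise ValueError("simulation series is identically zero; scale undefined")
    ratios = o[pos] / s[pos]
    weights = s[pos]
    order = np.argsort(ratios)
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(ratios[order][idx])


def read_moi_csv(path) -> dict:
    """Read half-month index observations: columns city, period_start, moi."""
    df = pd.read_csv(path)
    missing = {"city", "period_start", "moi"} - set(df.columns)
    if missing:
        raise ValueError(f"MOI CSV {path} missing columns: {sorted(missing)}")
    out = {}
    for city, grp in df.groupby("city", sort=False):
        periods = pd.DatetimeIndex(pd.to_datetime(grp["period_start"]))
        if any(d.day not in (1, 16) for d in periods):
            raise ValueError(f"period_start must be the 1st or 16th (city {city})")
        out[str(city)] = MOISeries(str(city), periods, grp["moi"].to_numpy(dtype=float))
    return out


def write_moi_csv(obs: dict, path) -> None:
    rows = [
        {"city": c, "period_start": d.date().isoformat(), "moi": v}
        for c, series in obs.items()
        for d, v in zip(series.periods, series.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
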