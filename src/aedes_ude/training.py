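"""Joint estimation of biological and network parameters against index data.

The loss is the mean absolute error between per-city half-month adult means
(scaled by per-city rotation factors) and the observed abundance index,
with all cities sharing one biological parameter set (theta1) and one
oviposition network (theta2). Gradients are exact derivatives of a
fixed-step RK4 discretization of the ODE (discretize-then-optimize): the
forward sweep caches every stage state and the reverse sweep propagates
vector-Jacobian products through the solver steps, the vital-rate formulas
and the network. The diapause indicator (half-month mean temperature below
21 deg C) is precomputed from the forcing and treated as data, so it is
never differentiated through.

Biological parameters are trained in an unconstrained space and mapped to
their admissible ranges by smooth bijections (sigmoid for the survival
peaks and the diapause ratio, exp for positive scales, 273.15 + exp for the
half-inactivation temperature); rotation factors are trained as
log-lambda. Optimization is plain ADAM in three stages: both parameter
sets together, then the network alone at a lower rate, then the biological
parameters alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, pearsonr

from . import oviposition_net as onet
from . import vital_rates as vr
from .climate import ClimateSeries, derive_forcing, half_month_edges
from .oviposition_net import NetParams
from .population import MOISeries, ScaleFactors, fit_scale_factor
from .vital_rates import (DIAPAUSE_THRESHOLD_C, GAS_CONSTANT, KELVIN_OFFSET,
                          T_REFERENCE_K, VitalParams)

__all__ = ["StageSpec", "TrainConfig", "FitResult", "fit", "gradient_check",
           "correlation_diagnostics", "predict_half_month"]


@dataclass(frozen=True)
class StageSpec:
    lr: float
    iterations: int
    train_bio: bool   # theta1 (+ rotation factors)
    train_net: bool   # theta2

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.iterations < 1:
            raise ValueError("every stage needs at least one iteration")


@dataclass
class TrainConfig:
    """Three-stage schedule; defaults follow the full-scale protocol
    (500 joint iterations at lr 0.01, 2000 network-only at 0.001,
    1000 biology-only at 0.01)."""

    stages: tuple = (
        StageSpec(lr=0.01, iterations=500, train_bio=True, train_net=True),
        StageSpec(lr=0.001, iterations=2000, train_bio=False, train_net=True),
        StageSpec(lr=0.01, iterations=1000, train_bio=True, train_net=False),
    )
    seed: int = 0
    gradient_mode: str = "discretize-then-optimize"
    rk4_dt: float = 0.5           # days per RK4 step inside the trainer
    log_every: int = 0            # 0 = silent; else print loss every k iterations

    def __post_init__(self):
        if self.gradient_mode != "discretize-then-optimize":
            raise ValueError("only discretize-then-optimize gradients are implemented")
        if not self.stages:
            raise ValueError("at least one stage required")

    @classmethod
    def reduced(cls, iterations=(100, 400, 200), seed: int = 0) -> "TrainConfig":
        """The desk-scale schedule used by the packaged benchmarks."""
        s1, s2, s3 = iterations
        return cls(stages=(
            StageSpec(0.01, s1, True, True),
            StageSpec(0.001, s2, False, True),
            StageSpec(0.01, s3, True, False),
        ), seed=seed)


@dataclass
class FitResult:
    params: VitalParams
    net: NetParams
    scales: ScaleFactors
    loss_history: np.ndarray
    per_city_r: dict
    stage_boundaries: list = field(default_factory=list)
    stage_params: list = field(default_factory=list)   # (u1, netflat, loglam) after each stage
    fitted: dict = field(default_factory=dict)         # city -> scaled fitted half-month series
    cities: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter transforms

_N_BIO = 11
_EPS_SIG = 1e-7


def bio_to_unconstrained(p: VitalParams) -> np.ndarray:
    clip = lambda x: np.clip(x, _EPS_SIG, 1 - _EPS_SIG)
    return np.array([
        logit(clip(p.mu_p)), p.T_p, np.log(p.V_p),
        logit(clip(p.mu_a)), p.T_a, np.log(p.V_a),
        np.log(p.AA), np.log(p.HA), np.log(p.HH),
        np.log(p.TH - KELVIN_OFFSET), logit(clip(p.delta)),
    ])


def unconstrained_to_bio(u: np.ndarray) -> VitalParams:
    return VitalParams(
        mu_p=float(expit(u[0])), T_p=float(u[1]), V_p=float(np.exp(u[2])),
        mu_a=float(expit(u[3])), T_a=float(u[4]), V_a=float(np.exp(u[5])),
        AA=float(np.exp(u[6])), HA=float(np.exp(u[7])), HH=float(np.exp(u[8])),
        TH=float(KELVIN_OFFSET + np.exp(u[9])), delta=float(expit(u[10])),
    )


def _transform_jacobian(u: np.ndarray) -> np.ndarray:
    """d(theta)/d(u) for each of the 11 coordinates."""
    s0, s3, s10 = expit(u[0]), expit(u[3]), expit(u[10])
    return np.array([
        s0 * (1 - s0), 1.0, np.exp(u[2]),
        s3 * (1 - s3), 1.0, np.exp(u[5]),
        np.exp(u[6]), np.exp(u[7]), np.exp(u[8]),
        np.exp(u[9]), s10 * (1 - s10),
    ])


# ---------------------------------------------------------------------------
# problem assembly


class Problem:
    """Stacked multi-city data ready for the differentiable forward model.

    All cities must share the same daily date range; the evaluation window
    starts at ``eval_start`` (default: one year after the simulation start,
    the burn-in convention) and the observation periods must match the
    calendar half-months of that window exactly.
    """

    def __init__(self, data, eval_start=None, init_state=(1_000_000.0, 0.0)):
        items = sorted(data.items()) if isinstance(data, dict) else list(data)
        self.cities = [c for c, _ in items]
        pairs = [v for _, v in items]
        dates = pairs[0][0].dates
        for series, _ in pairs:
            if not series.dates.equals(dates):
                raise ValueError("all cities must share one daily date range")
        self.dates = dates
        self.n_cities = len(pairs)
        self.n_days = len(dates)
        self.init_state = init_state

        T = np.stack([s.temp for s, _ in pairs])
        R = np.stack([s.precip for s, _ in pairs])
        forcings = [derive_forcing(s) for s, _ in pairs]
        self.T, self.R = T, R
        self.Rn = np.stack([f.r_norm for f in forcings])
        t_month = np.stack([f.t_month for f in forcings])
        self.diap = t_month < DIAPAUSE_THRESHOLD_C
        self.T_eff = np.where(self.diap, DIAPAUSE_THRESHOLD_C, T)

        if eval_start is None:
            eval_start = dates[0].replace(year=dates[0].year + 1)
        self.eval_start = pd.Timestamp(eval_start)
        sel = dates >= self.eval_start
        eval_dates = dates[sel]
        if len(eval_dates) == 0 or eval_dates[0].day not in (1, 16):
            raise ValueError("evaluation window must start on a half-month boundary")
        self.day_offset = int(np.flatnonzero(sel)[0])
        edges = half_month_edges(eval_dates)
        # drop a partial trailing block
        if eval_dates[-1] != _complete_end(eval_dates[edges[-2]]):
            edges = edges[:-1]
        self.period_starts = eval_dates[edges[:-1]]
        self.edges = edges + self.day_offset   # day indices into the full range
        self.period_len = np.diff(edges).astype(float)
        self.n_periods = len(self.period_len)

        obs = []
        for series, moi in pairs:
            if len(moi.periods) != self.n_periods or not (
                    pd.DatetimeIndex(moi.periods) == self.period_starts).all():
                raise ValueError(
                    f"observation periods for {moi.city_id} do not match the "
                    f"evaluation half-months ({self.n_periods} expected)")
            obs.append(moi.values)
        self.obs = np.stack(obs)
        self.mn = float(self.obs.size)

    # -- rate fields -------------------------------------------------------

    def rates(self, p: VitalParams):
        mp = 1.0 - p.mu_p * np.exp(-((self.T_eff - p.T_p) ** 2) / p.V_p**2)
        ma = 1.0 - p.mu_a * np.exp(-((self.T - p.T_a) ** 2) / p.V_a**2)
        TK = self.T + KELVIN_OFFSET
        num = p.AA * (TK / T_REFERENCE_K) * np.exp(
            (p.HA / GAS_CONSTANT) * (1.0 / T_REFERENCE_K - 1.0 / TK))
        g = np.clip((p.HH / GAS_CONSTANT) * (1.0 / p.TH - 1.0 / TK), -60.0, 60.0)
        dpn = num / (1.0 + np.exp(g))
        dpn = np.where(self.diap, p.delta * dpn, dpn)
        return mp, ma, dpn

    def rate_partials(self, p: VitalParams, mp_bar, ma_bar, dp_bar):
        """Chain day-level rate adjoints to the 11 biological parameters."""
        E_p = np.exp(-((self.T_eff - p.T_p) ** 2) / p.V_p**2)
        E_a = np.exp(-((self.T - p.T_a) ** 2) / p.V_a**2)
        TK = self.T + KELVIN_OFFSET
        g = np.clip((p.HH / GAS_CONSTANT) * (1.0 / p.TH - 1.0 / TK), -60.0, 60.0)
        s = expit(g)
        _, _, dpn = self.rates(p)

        grad = np.empty(_N_BIO)
        grad[0] = np.sum(mp_bar * (-E_p))
        grad[1] = np.sum(mp_bar * (-p.mu_p * E_p * 2 * (self.T_eff - p.T_p) / p.V_p**2))
        grad[2] = np.sum(mp_bar * (-p.mu_p * E_p * 2 * (self.T_eff - p.T_p) ** 2 / p.V_p**3))
        grad[3] = np.sum(ma_bar * (-E_a))
        grad[4] = np.sum(ma_bar * (-p.mu_a * E_a * 2 * (self.T - p.T_a) / p.V_a**2))
        grad[5] = np.sum(ma_bar * (-p.mu_a * E_a * 2 * (self.T - p.T_a) ** 2 / p.V_a**3))
        grad[6] = np.sum(dp_bar * dpn / p.AA)
        grad[7] = np.sum(dp_bar * dpn * (1.0 / GAS_CONSTANT) * (1.0 / T_REFERENCE_K - 1.0 / TK))
        grad[8] = np.sum(dp_bar * (-dpn * s * (1.0 / GAS_CONSTANT) * (1.0 / p.TH - 1.0 / TK)))
        grad[9] = np.sum(dp_bar * dpn * s * (p.HH / GAS_CONSTANT) / p.TH**2)
        grad[10] = np.sum(np.where(self.diap, dp_bar * dpn / p.delta, 0.0))
        return grad


def _complete_end(day0: pd.Timestamp) -> pd.Timestamp:
    return day0.replace(day=15) if day0.day == 1 else day0 + pd.offsets.MonthEnd(0)


# ---------------------------------------------------------------------------
# differentiable forward model


def _ode_forward(problem: Problem, mp, ma, dpn, b, n_sub: int):
    """Fixed-step RK4 over the full window; returns daily adults and caches."""
    C, D = problem.n_cities, problem.n_days
    dt = 1.0 / n_sub
    alpha = vr.EMERGENCE_COEFFICIENT * dpn / (vr.CARRYING_CONSTANT * (problem.Rn + 1.0))
    loss_coef = dpn + mp

    n_steps = D * n_sub
    cache = np.empty((n_steps, 4, 2, C))   # per step: y, k1, k2, k3
    y = np.empty((2, C))
    y[0] = problem.init_state[0]
    y[1] = problem.init_state[1]
    A_daily = np.empty((C, D + 1))
    A_daily[:, 0] = y[1]

    def f(yv, d):
        P, A = yv
        ef = np.exp(-vr.EMERGENCE_COEFFICIENT - alpha[:, d] * P)
        return np.stack([b[:, d] * A - loss_coef[:, d] * P,
                         ef * dpn[:, d] * P - ma[:, d] * A])

    s = 0
    for d in range(D):
        for _ in range(n_sub):
            k1 = f(y, d)
            k2 = f(y + (0.5 * dt) * k1, d)
            k3 = f(y + (0.5 * dt) * k2, d)
            k4 = f(y + dt * k3, d)
            cache[s, 0], cache[s, 1], cache[s, 2], cache[s, 3] = y, k1, k2, k3
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            s += 1
        A_daily[:, d + 1] = y[1]
    return A_daily, cache, alpha


def _ode_backward(problem: Problem, mp, ma, dpn, b, alpha, cache,
                  A_daily_bar, n_sub: int):
    """Reverse sweep: day-level adjoints of (b, dpn, mp, ma)."""
    C, D = problem.n_cities, problem.n_days
    dt = 1.0 / n_sub
    b_bar = np.zeros((C, D))
    dp_bar = np.zeros((C, D))
    mp_bar = np.zeros((C, D))
    ma_bar = np.zeros((C, D))

    def f_eval(yv, d):
        P = yv[0]
        ef = np.exp(-vr.EMERGENCE_COEFFICIENT - alpha[:, d] * P)
        return ef

    def f_vjp(yv, kbar, d):
        P, A = yv
        ef = f_eval(yv, d)
        aP = alpha[:, d] * P
        ybar = np.empty_like(yv)
        ybar[0] = kbar[0] * (-(dpn[:, d] + mp[:, d])) + kbar[1] * (dpn[:, d] * ef * (1.0 - aP))
        ybar[1] = kbar[0] * b[:, d] + kbar[1] * (-ma[:, d])
        b_bar[:, d] += kbar[0] * A
        dp_bar[:, d] += kbar[0] * (-P) + kbar[1] * (ef * P * (1.0 - aP))
        mp_bar[:, d] += kbar[0] * (-P)
        ma_bar[:, d] += kbar[1] * (-A)
        return ybar

    ybar = np.zeros((2, C))
    for s in range(D * n_sub - 1, -1, -1):
        if (s + 1) % n_sub == 0:
            ybar[1] += A_daily_bar[:, (s + 1) // n_sub]
        y, k1, k2, k3 = cache[s]
        d = s // n_sub
        kbar1 = (dt / 6.0) * ybar
        kbar2 = (dt / 3.0) * ybar
        kbar3 = (dt / 3.0) * ybar
        kbar4 = (dt / 6.0) * ybar
        y4bar = f_vjp(y + dt * k3, kbar4, d)
        kbar3 = kbar3 + dt * y4bar
        y3bar = f_vjp(y + (0.5 * dt) * k2, kbar3, d)
        kbar2 = kbar2 + (0.5 * dt) * y3bar
        y2bar = f_vjp(y + (0.5 * dt) * k1, kbar2, d)
        kbar1 = kbar1 + (0.5 * dt) * y2bar
        y1bar = f_vjp(y, kbar1, d)
        ybar = ybar + y1bar + y2bar + y3bar + y4bar
    return b_bar, dp_bar, mp_bar, ma_bar


def _aggregate(problem: Problem, A_daily):
    # reduceat's final segment runs to the array end; keep the true periods only
    sums = np.add.reduceat(A_daily, problem.edges, axis=1)
    return sums[:, : problem.n_periods] / problem.period_len


def loss_and_grads(problem: Problem, u_bio, net: NetParams, net_flat,
                   log_lam, n_sub: int = 2, need_grads=(True, True, True)):
    """Loss of the discretized model and gradients for the requested groups
    (biology, network, log rotation factors)."""
    p = unconstrained_to_bio(u_bio)
    mp, ma, dpn = problem.rates(p)
    net_cur = onet.set_flat(net, net_flat)
    b_flat, acts = onet.forward_cached(net_cur, problem.T.ravel(), problem.R.ravel())
    b = b_flat.reshape(problem.T.shape)

    A_daily, cache, alpha = _ode_forward(problem, mp, ma, dpn, b, n_sub)
    A_hm = _aggregate(problem, A_daily)
    lam = np.exp(log_lam)
    resid = problem.obs - lam[:, None] * A_hm
    loss = float(np.abs(resid).sum() / problem.mn)

    need_bio, need_net, need_lam = need_grads
    g_bio = g_net = g_lam = None
    sgn = np.sign(resid)
    if need_lam:
        g_lam = (-(sgn * A_hm).sum(axis=1) / problem.mn) * lam
    if need_bio or need_net:
        A_hm_bar = -(lam[:, None] * sgn) / problem.mn
        A_daily_bar = np.zeros_like(A_daily)
        per_day = A_hm_bar / problem.period_len
        for j in range(problem.n_periods):
            A_daily_bar[:, problem.edges[j]:problem.edges[j + 1]] += per_day[:, [j]]
        b_bar, dp_bar, mp_bar, ma_bar = _ode_backward(
            problem, mp, ma, dpn, b, alpha, cache, A_daily_bar, n_sub)
        if need_net:
            gW, gb = onet.backward(net_cur, acts, b_bar.ravel())
            g_net = onet.flat_grads(gW, gb)
        if need_bio:
            g_bio = problem.rate_partials(p, mp_bar, ma_bar, dp_bar) * _transform_jacobian(u_bio)
    return loss, g_bio, g_net, g_lam, A_hm


# ---------------------------------------------------------------------------
# ADAM and the three-stage schedule


class _Adam:
    def __init__(self, n, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, x, g):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit(data, cfg: TrainConfig, init_params: VitalParams,
        init_net: NetParams, eval_start=None) -> FitResult:
    """Run the three-stage estimation; returns the best-loss parameters.

    ``data`` maps city -> (ClimateSeries, MOISeries) with one shared daily
    window per city; all cities share theta1/theta2 while rotation factors
    are per city (trained jointly with theta1). Deterministic given the
    config seed.
    """
    problem = Problem(data, eval_start=eval_start)
    n_sub = max(1, int(round(1.0 / cfg.rk4_dt)))
    u_bio = bio_to_unconstrained(init_params)
    net = init_net.copy()
    net_flat = onet.get_flat(net)

    # rotation factors: L1-optimal slope of the initial forward pass
    loss0, _, _, _, A_hm = loss_and_grads(
        problem, u_bio, net, net_flat, np.zeros(problem.n_cities),
        n_sub=n_sub, need_grads=(False, False, False))
    log_lam = np.array([
        np.log(max(fit_scale_factor(A_hm[i], problem.obs[i]), 1e-300))
        for i in range(problem.n_cities)
    ])

    history = []
    boundaries = []
    stage_params = []
    best = None   # (loss, u_bio, net_flat, log_lam)

    for stage_idx, stage in enumerate(cfg.stages):
        opt_bio = _Adam(u_bio.size + log_lam.size, stage.lr) if stage.train_bio else None
        opt_net = _Adam(net_flat.size, stage.lr) if stage.train_net else None
        for it in range(stage.iterations):
            loss, g_bio, g_net, g_lam, _ = loss_and_grads(
                problem, u_bio, net, net_flat, log_lam, n_sub=n_sub,
                need_grads=(stage.train_bio, stage.train_net, stage.train_bio))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at stage {stage_idx + 1}, iteration {it}")
            history.append(loss)
            if best is None or loss < best[0]:
                best = (loss, u_bio.copy(), net_flat.copy(), log_lam.copy())
            if cfg.log_every and it % cfg.log_every == 0:
                print(f"[stage {stage_idx + 1}] iter {it:5d} loss {loss:.6g}")
            if stage.train_bio:
                joint = opt_bio.step(np.concatenate([u_bio, log_lam]),
                                     np.concatenate([g_bio, g_lam]))
                u_bio, log_lam = joint[:u_bio.size], joint[u_bio.size:]
            if stage.train_net:
                net_flat = opt_net.step(net_flat, g_net)
        # each stage hands its best-so-far parameters to the next
        _, u_bio, net_flat, log_lam = best
        u_bio, net_flat, log_lam = u_bio.copy(), net_flat.copy(), log_lam.copy()
        boundaries.append(len(history))
        stage_params.append((u_bio.copy(), net_flat.copy(), log_lam.copy()))

    loss_fin, _, _, _, A_hm = loss_and_grads(
        problem, u_bio, net, net_flat, log_lam, n_sub=n_sub,
        need_grads=(False, False, False))
    history.append(loss_fin)
    lam = np.exp(log_lam)
    fitted = {c: lam[i] * A_hm[i] for i, c in enumerate(problem.cities)}
    per_city_r = {}
    for i, c in enumerate(problem.cities):
        per_city_r[c] = _safe_pearson(fitted[c], problem.obs[i])

    return FitResult(
        params=unconstrained_to_bio(u_bio),
        net=onet.set_flat(net, net_flat),
        scales=ScaleFactors({c: float(lam[i]) for i, c in enumerate(problem.cities)}),
        loss_history=np.asarray(history),
        per_city_r=per_city_r,
        stage_boundaries=boundaries,
        stage_params=stage_params,
        fitted=fitted,
        cities=problem.cities,
    )


def _safe_pearson(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(pearsonr(x, y)[0])


def predict_half_month(data, params: VitalParams, net: NetParams,
                       scales: ScaleFactors, eval_start=None, n_sub: int = 2):
    """Scaled fitted half-month adult series for each city (no training)."""
    problem = Problem(data, eval_start=eval_start)
    u = bio_to_unconstrained(params)
    flat = onet.get_flat(net)
    _, _, _, _, A_hm = loss_and_grads(
        problem, u, net, flat, np.zeros(problem.n_cities), n_sub=n_sub,
        need_grads=(False, False, False))
    return {c: scales.lambda_j[c] * A_hm[i] for i, c in enumerate(problem.cities)}, problem


# ---------------------------------------------------------------------------
# gradient verification and diagnostics


def gradient_check(seed: int = 0, n_net_coords: int = 12, n_sub: int = 2,
                   h: float = 1e-4):
    """Compare solver-propagated gradients against central finite differences.

    Builds a tiny 2-city, ~60-day evaluation problem in a warm (diapause-free)
    regime, then checks a sample of biological coordinates, network
    coordinates and rotation factors. Returns a dict with the max relative
    error and per-group details. The diapause ratio has no influence in this
    regime, so it is reported separately as a dead coordinate.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2021-01-01", periods=91, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    data = {}
    for c in range(2):
        temp = 26.0 + 2.0 * np.sin(2 * np.pi * doy / 45.0 + c) + rng.normal(0, 0.5, len(dates))
        precip = np.where(rng.random(len(dates)) < 0.4, rng.gamma(0.8, 12.0, len(dates)), 0.0)
        series = ClimateSeries(f"g{c}", dates, temp, precip)
        data[f"g{c}"] = series
    eval_start = pd.Timestamp("2021-02-01")  # 4 half-months: Feb-Mar

    # observations: model output under default params/random net, noised
    p0 = VitalParams.default()
    net0 = onet.init_net(int(rng.integers(2**31)))
    prob_data = {}
    for c, series in data.items():
        # placeholder obs; replaced after a forward pass
        periods = pd.DatetimeIndex([pd.Timestamp(d) for d in
                                    ["2021-02-01", "2021-02-16", "2021-03-01", "2021-03-16"]])
        prob_data[c] = (series, MOISeries(c, periods, np.ones(4)))
    problem = Problem(prob_data, eval_start=eval_start, init_state=(5000.0, 50.0))
    u0 = bio_to_unconstrained(p0)
    flat0 = onet.get_flat(net0)
    _, _, _, _, A_hm = loss_and_grads(problem, u0, net0, flat0,
                                      np.zeros(2), n_sub=n_sub,
                                      need_grads=(False, False, False))
    problem.obs = A_hm * np.exp(rng.normal(0.0, 0.25, size=A_hm.shape))

    u = u0 + rng.normal(0, 0.05, size=u0.shape)
    flat = flat0 + rng.normal(0, 0.05, size=flat0.shape)
    log_lam = rng.normal(0, 0.1, size=2)

    loss, g_bio, g_net, g_lam, _ = loss_and_grads(problem, u, net0, flat, log_lam,
                                                  n_sub=n_sub)

    def fd(setter, x0):
        def loss_at(x):
            return loss_and_grads(problem, *setter(x), n_sub=n_sub,
                                  need_grads=(False, False, False))[0]
        return (loss_at(x0 + h * max(1.0, abs(x0))) -
                loss_at(x0 - h * max(1.0, abs(x0)))) / (2 * h * max(1.0, abs(x0)))

    records = []
    live_bio = [i for i in range(_N_BIO) if i != 10]  # delta is dead (no diapause days)
    for i in live_bio:
        def setter(x, i=i):
            uu = u.copy(); uu[i] = x
            return uu, net0, flat, log_lam
        records.append(("bio", i, g_bio[i], fd(setter, u[i])))
    net_idx = rng.choice(flat.size, size=min(n_net_coords, flat.size), replace=False)
    for i in net_idx:
        def setter(x, i=i):
            ff = flat.copy(); ff[i] = x
            return u, net0, ff, log_lam
        records.append(("net", int(i), g_net[i], fd(setter, flat[i])))
    for i in range(2):
        def setter(x, i=i):
            ll = log_lam.copy(); ll[i] = x
            return u, net0, flat, ll
        records.append(("lam", i, g_lam[i], fd(setter, log_lam[i])))

    scale = max(1e-10, max(abs(r[3]) for r in records))
    errors = [abs(g - gfd) / max(abs(gfd), 1e-3 * scale) for _, _, g, gfd in records]
    return {
        "max_rel_error": float(max(errors)),
        "records": records,
        "dead_delta_grad": float(g_bio[10]),
        "loss": loss,
    }


def correlation_diagnostics(fitres: FitResult, data) -> pd.DataFrame:
    """Per-city Pearson r and standardized-residual P-P pairs.

    Residuals (observed minus fitted, pooled per city) are standardized and
    paired as (theoretical normal cumulative probability, empirical
    cumulative probability). Cities with constant series get r = NaN.
    """
    rows = []
    items = sorted(data.items()) if isinstance(data, dict) else list(data)
    obs = {c: moi.values for c, (_, moi) in items}
    for city in fitres.cities:
        f = np.asarray(fitres.fitted[city])
        o = np.asarray(obs[city])
        r = _safe_pearson(f, o)
        resid = o - f
        sd = resid.std(ddof=1)
        z = (resid - resid.mean()) / sd if sd > 0 else np.zeros_like(resid)
        z_sorted = np.sort(z)
        n = len(z)
        emp = (np.arange(1, n + 1) - 0.5) / n
        theo = norm.cdf(z_sorted)
        for t, e in zip(theo, emp):
            rows.append({"city": city, "pearson_r": r,
                         "theoretical_cp": t, "empirical_cp": e})
    return pd.DataFrame(rows)
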