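"""Synthetic climate and abundance-index data with known ground truth.

Emulates the study setting — subtropical monsoon climate (mild winters near
15 deg C, hot wet summers near 28-30 deg C, episodic convective rain) and a
half-monthly ovitrap-style abundance index proportional to adult abundance —
so that every stage of the pipeline (forcing derivation, ODE simulation,
training, symbolic distillation) can be validated against a planted truth
without any external download.

Temperature is a seasonal sinusoid peaking in mid-July plus AR(1) noise;
precipitation is a seasonal Bernoulli wet-day process with gamma-distributed
amounts. Observations are half-month adult means from a truth simulation
(default truth oviposition: the closed-form reference expression in
:mod:`aedes_ude.symreg`), scaled by a per-city factor and perturbed by
multiplicative log-normal noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate import ClimateSeries
from .population import (MOISeries, default_initial_condition,
                         half_month_aggregate, simulate, write_moi_csv)
from .vital_rates import VitalParams

__all__ = ["SynthConfig", "gen_climate", "gen_observations", "make_benchmark",
           "load_benchmark", "BENCHMARKS"]


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the subtropical study region."""

    n_cities: int = 3
    years: int = 2                  # evaluation years (one burn-in year precedes them)
    seed: int = 0
    start: str = "2015-01-01"       # burn-in year start
    temp_mean: tuple = (20.5, 23.5)         # annual mean range across cities (deg C)
    temp_amplitude: tuple = (6.5, 7.5)      # seasonal amplitude range (deg C)
    temp_noise_sd: float = 1.5              # daily AR(1) noise sd (deg C)
    temp_noise_ar: float = 0.7              # AR(1) autocorrelation
    wet_prob_summer: float = 0.6            # wet-day probability at the summer peak
    wet_prob_winter: float = 0.15
    rain_shape: float = 0.8                 # gamma shape of wet-day amounts
    rain_scale_peak: float = 25.0           # gamma scale at the summer peak (mm)
    rain_scale_winter: float = 5.0
    obs_noise_sd: float = 0.1               # log-scale sd of multiplicative obs noise
    lambda_range: tuple = (1e-5, 1e-4)      # per-city index-per-individual scale

    def __post_init__(self):
        if self.n_cities < 1 or self.years < 1:
            raise ValueError("need n_cities >= 1 and years >= 1")
        for v in (self.temp_noise_sd, self.rain_shape, self.rain_scale_peak,
                  self.obs_noise_sd):
            if v < 0:
                raise ValueError("noise/scale settings must be nonnegative")


def _season(doy: np.ndarray) -> np.ndarray:
    """Seasonal phase in [-1, 1], peaking mid-July (doy ~ 196)."""
    return np.sin(2.0 * np.pi * (doy - 105.0) / 365.0)


def gen_climate(cfg: SynthConfig) -> list[ClimateSeries]:
    """Per-city daily climate series spanning burn-in plus evaluation years."""
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start)
    end = start.replace(year=start.year + cfg.years + 1) - pd.Timedelta(days=1)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    phase = _season(doy)
    out = []
    for c in range(cfg.n_cities):
        mean = rng.uniform(*cfg.temp_mean)
        amp = rng.uniform(*cfg.temp_amplitude)
        noise = np.empty(len(dates))
        eps = rng.normal(0.0, cfg.temp_noise_sd, size=len(dates))
        # stationary AR(1): innovation sd scaled so the marginal sd is temp_noise_sd
        innov = eps * np.sqrt(1.0 - cfg.temp_noise_ar**2)
        acc = eps[0]
        for i in range(len(dates)):
            acc = cfg.temp_noise_ar * acc + innov[i] if i else eps[0]
            noise[i] = acc
        temp = mean + amp * phase + noise

        s01 = 0.5 * (1.0 + phase)
        wet_p = cfg.wet_prob_winter + (cfg.wet_prob_summer - cfg.wet_prob_winter) * s01
        scale = cfg.rain_scale_winter + (cfg.rain_scale_peak - cfg.rain_scale_winter) * s01
        wet = rng.random(len(dates)) < wet_p
        amounts = rng.gamma(cfg.rain_shape, scale)
        precip = np.where(wet, amounts, 0.0)
        out.append(ClimateSeries(f"city{c:02d}", dates, temp, precip))
    return out


def gen_observations(cfg: SynthConfig, climate: list[ClimateSeries],
                     truth_ovi=None, p: VitalParams | None = None):
    """Simulate the truth model and emit noisy scaled half-month observations.

    Returns ``(obs, truth)`` where ``obs`` maps city -> :class:`MOISeries`
    and ``truth`` records the hidden trajectories, scale factors and the
    identifier of the planted oviposition function.
    """
    from .symreg import eval_reference  # default planted truth

    if truth_ovi is None:
        truth_ovi = eval_reference
        truth_id = "reference_expression"
    else:
        truth_id = getattr(truth_ovi, "__name__", "custom")
    p = p or VitalParams.default()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    init, t0 = default_initial_condition()
    eval_start = pd.Timestamp(cfg.start).replace(year=pd.Timestamp(cfg.start).year + 1)

    obs, truth = {}, {"lambda": {}, "trajectory": {}, "ovi_id": truth_id,
                      "params": p.to_dict(), "half_month_A": {}}
    log_lo, log_hi = np.log(cfg.lambda_range[0]), np.log(cfg.lambda_range[1])
    for series in climate:
        if series.dates[0] != pd.Timestamp(cfg.start):
            raise ValueError("climate must include the burn-in year from cfg.start")
        traj = simulate(series, p, truth_ovi, init, t_start=t0)
        periods, means = half_month_aggregate(
            traj, window_start=eval_start, window_end=traj.dates[-1])
        lam = float(np.exp(rng.uniform(log_lo, log_hi)))
        noise = rng.normal(0.0, cfg.obs_noise_sd, size=len(means)) if cfg.obs_noise_sd > 0 else 0.0
        values = lam * means * np.exp(noise)
        obs[series.city_id] = MOISeries(series.city_id, periods, values)
        truth["lambda"][series.city_id] = lam
        truth["trajectory"][series.city_id] = traj
        truth["half_month_A"][series.city_id] = means
    return obs, truth


BENCHMARKS = {
    "small": dict(n_cities=3, years=2, seed=2016),
    "paperlike": dict(n_cities=12, years=4, seed=2016),
}


def make_benchmark(name: str, outdir) -> Path:
    """Write a packaged benchmark (climate CSVs, MOI CSV, truth, manifest).

    ``small`` is 3 cities x 2 evaluation years; ``paperlike`` is 12 cities x
    4 evaluation years (9 train + 3 test by convention of the city order).
    Outputs are deterministic for the manifest's seed.
    """
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    cfg = SynthConfig(**BENCHMARKS[name])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    climate = gen_climate(cfg)
    obs, truth = gen_observations(cfg, climate)
    for series in climate:
        pd.DataFrame({
            "date": series.dates.strftime("%Y-%m-%d"),
            "temp_c": np.round(series.temp, 4),
            "precip_mm": np.round(series.precip, 4),
        }).to_csv(outdir / f"climate_{series.city_id}.csv", index=False)
    write_moi_csv(obs, outdir / "moi.csv")
    truth_doc = {
        "ovi_id": truth["ovi_id"],
        "params": truth["params"],
        "lambda": truth["lambda"],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1)
    manifest = {
        "name": name,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "truth_ovi": truth["ovi_id"],
        "cities": [s.city_id for s in climate],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def load_benchmark(name: str):
    """Regenerate a named benchmark in memory (climate, observations, truth)."""
    if name not in BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}")
    cfg = SynthConfig(**BENCHMARKS[name])
    climate = gen_climate(cfg)
    obs, truth = gen_observations(cfg, climate)
    return cfg, climate, obs, truth
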