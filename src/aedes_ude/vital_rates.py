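"""Temperature-dependent vital rates of the two-stage Aedes model.

Immature and adult mortality follow a Gaussian survival form
``m(T) = 1 - mu * exp(-(T - T_opt)^2 / V^2)``; development from immatures to
adults follows the Sharpe & DeMichele enzyme-kinetics equation; emergence
success is density- and precipitation-limited. Diapause — triggered when the
half-month mean temperature drops below 21 deg C — freezes immature
mortality at its 21 deg C value and scales development by the ratio
``delta``. Adult rates are not modified during diapause.

All rates are per day; temperatures are deg C at the interface and converted
to Kelvin only inside the Sharpe-DeMichele expression, whose gas constant is
in cal/(mol K).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "VitalParams",
    "GAS_CONSTANT",
    "KELVIN_OFFSET",
    "T_REFERENCE_K",
    "DIAPAUSE_THRESHOLD_C",
    "CARRYING_CONSTANT",
    "EMERGENCE_COEFFICIENT",
    "immature_mortality",
    "adult_mortality",
    "development_rate",
    "emergence_success",
]

# Fixed physical constants (not estimated).
GAS_CONSTANT = 1.987            # cal mol^-1 K^-1
KELVIN_OFFSET = 273.15          # deg C -> K
T_REFERENCE_K = 298.15          # K, Sharpe-DeMichele reference temperature
DIAPAUSE_THRESHOLD_C = 21.0     # deg C, half-month mean triggering diapause
CARRYING_CONSTANT = 250_000.0   # immature carrying constant of the emergence term
EMERGENCE_COEFFICIENT = 0.1     # leading coefficient of the emergence exponent

_PARAM_FIELDS = ("mu_p", "T_p", "V_p", "mu_a", "T_a", "V_a",
                 "AA", "HA", "HH", "TH", "delta")


@dataclass(frozen=True)
class VitalParams:
    """The eleven estimated biological parameters of the vital-rate functions.

    mu_p, mu_a : peak daily survival of immatures / adults, in (0, 1]
    T_p, T_a   : optimal survival temperatures (deg C)
    V_p, V_a   : Gaussian width scales (deg C), > 0
    AA         : base development rate (day^-1) at the 25 deg C reference
    HA, HH     : activation / high-temperature inactivation enthalpies (cal/mol)
    TH         : temperature of 50% enzyme inactivation (K), > 273.15
    delta      : diapause:normal development-rate ratio, in (0, 1]
    """

    mu_p: float
    T_p: float
    V_p: float
    mu_a: float
    T_a: float
    V_a: float
    AA: float
    HA: float
    HH: float
    TH: float
    delta: float

    def __post_init__(self):
        if not (0 < self.mu_p <= 1 and 0 < self.mu_a <= 1):
            raise ValueError("mu_p and mu_a must be in (0, 1]")
        if self.V_p <= 0 or self.V_a <= 0 or self.AA <= 0:
            raise ValueError("V_p, V_a, AA must be positive")
        if self.TH <= KELVIN_OFFSET:
            raise ValueError("TH must exceed 273.15 K")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")

    @classmethod
    def default(cls) -> "VitalParams":
        """The packaged default estimates (shipped YAML)."""
        with resources.files("aedes_ude.data").joinpath("vital_params.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "VitalParams":
        return cls(**{k: float(d[k]) for k in _PARAM_FIELDS})

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in _PARAM_FIELDS}

    def replace(self, **kw) -> "VitalParams":
        return dataclasses.replace(self, **kw)


def immature_mortality(T, T_month, p: VitalParams):
    """Daily immature mortality; frozen at the 21 deg C value during diapause."""
    T = np.asarray(T, dtype=float)
    T_eff = np.where(np.asarray(T_month, dtype=float) >= DIAPAUSE_THRESHOLD_C,
                     T, DIAPAUSE_THRESHOLD_C)
    out = 1.0 - p.mu_p * np.exp(-((T_eff - p.T_p) ** 2) / p.V_p**2)
    return out if out.ndim else float(out)


def adult_mortality(T, p: VitalParams):
    """Daily adult mortality, Gaussian about the adult optimum ``T_a``."""
    T = np.asarray(T, dtype=float)
    out = 1.0 - p.mu_a * np.exp(-((T - p.T_a) ** 2) / p.V_a**2)
    return out if out.ndim else float(out)


def development_rate(T, T_month, p: VitalParams):
    """Sharpe-DeMichele immature-to-adult development rate (day^-1).

    Scaled by ``delta`` when the half-month mean temperature signals diapause.
    The high-temperature inactivation exponent is clipped to avoid overflow
    far outside the biological range.
    """
    T = np.asarray(T, dtype=float)
    TK = T + KELVIN_OFFSET
    num = p.AA * (TK / T_REFERENCE_K) * np.exp(
        (p.HA / GAS_CONSTANT) * (1.0 / T_REFERENCE_K - 1.0 / TK)
    )
    g = np.clip((p.HH / GAS_CONSTANT) * (1.0 / p.TH - 1.0 / TK), -60.0, 60.0)
    rate = num / (1.0 + np.exp(g))
    rate = np.where(np.asarray(T_month, dtype=float) >= DIAPAUSE_THRESHOLD_C,
                    rate, p.delta * rate)
    return rate if rate.ndim else float(rate)


def emergence_success(R_norm, P, dp, p: VitalParams | None = None):
    """Density- and precipitation-dependent adult emergence success.

    ``exp(-0.1 * (1 + dp * P / (250000 * (R_norm + 1))))`` — bounded in
    ``(0, e^-0.1]``, increasing in standardized weekly precipitation and
    decreasing in immature load ``dp * P``. Pure function of its arguments so
    it can be exercised independently of the ODE state.
    """
    R_norm = np.asarray(R_norm, dtype=float)
    out = np.exp(-EMERGENCE_COEFFICIENT * (
        1.0 + np.asarray(dp, dtype=float) * np.asarray(P, dtype=float)
        / (CARRYING_CONSTANT * (R_norm + 1.0))
    ))
    return out if out.ndim else float(out)
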