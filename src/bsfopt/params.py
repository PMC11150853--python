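"""Model parameters and numerical configuration.

The adult black soldier fly (BSF, *Hermetia illucens*) model is fully
determined by a flat set of rate constants, degree-day thresholds and
environment-response coefficients.  :class:`ModelParameters` is the single
source of truth for these values; every other module receives an instance
rather than reading constants of its own.

Parameters serialize to/from a flat TOML file whose keys are the attribute
names, so a parameter set round-trips bit-exactly.  A packaged default file
(``data/default_params.toml``) carries the literature values.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["ModelParameters", "NumericsConfig", "load_params", "save_params"]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, thresholds and response-curve coefficients.

    Units: time in days, temperature in °C, development sums in °C·d,
    photoperiod in light-hours per day, egg mass in mg.  The dying-rate
    state μ is treated as dimensionless (negative = energy reserves remain).
    """

    # life-stage transition rates, d⁻¹
    k_y2act: float = 0.28
    k_act2fert: float = 0.62
    k_fert2old: float = 0.55

    # degree-day development: base temperature (°C) and gate thresholds (°C·d)
    k_T_sum_min: float = 12.0
    k_sum_y2act: float = 28.0
    k_sum_ovi: float = 56.0

    # oviposition rate per fertilized female, mg d⁻¹
    k_ovi: float = 5.9

    # dying-rate (reserve depletion) dynamics
    k_mu: float = 0.0183      # base growth rate of μ, d⁻¹
    k_mu_old: float = 2.14    # death-rate coefficient of the old stage, d⁻¹
    k_mu_ovi: float = 2.5     # reserve weighting on fecundity, dimensionless
    k_mu_N: float = 1.0       # death-rate coefficient of pre-old stages, d⁻¹

    # photoperiod response ξ_L(u_L) = a1·(1 − exp(−a2·u_L))
    a1: float = 0.986
    a2: float = 0.368         # d h⁻¹

    # temperature→fecundity quadratic ξ_T,ovi = c2·T² + c1·T + c0
    k_T_ovi_0: float = -3.17
    k_T_ovi_1: float = 0.286   # K⁻¹
    k_T_ovi_2: float = -0.005  # K⁻²

    # temperature→dying-rate quadratic ξ_T,μ = c2·T² + c1·T + c0
    k_T_mu_0: float = 3.13
    k_T_mu_1: float = -0.166   # K⁻¹
    k_T_mu_2: float = 0.0033   # K⁻²

    # initial conditions
    mu0: float = -0.1          # initial dying-rate state (negative: reserves remain)
    N_y0: float = 50.0         # initial number of young female flies

    def __post_init__(self) -> None:
        positive = (
            "k_y2act", "k_act2fert", "k_fert2old", "k_T_sum_min",
            "k_sum_y2act", "k_sum_ovi", "k_ovi", "k_mu", "k_mu_old",
            "k_mu_ovi", "k_mu_N", "a2", "N_y0",
        )
        for name in positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0.0 < self.a1 <= 1.0:
            raise ValueError(f"a1 must lie in (0, 1], got {self.a1!r}")
        if not self.k_sum_y2act < self.k_sum_ovi:
            raise ValueError("mating threshold k_sum_y2act must precede k_sum_ovi")
        if not self.k_T_ovi_2 < 0:
            raise ValueError("fecundity response must be concave (k_T_ovi_2 < 0)")
        if not self.k_T_mu_2 > 0:
            raise ValueError("mortality response must be convex (k_T_mu_2 > 0)")
        for name in ("mu0", "k_T_ovi_0", "k_T_ovi_1", "k_T_mu_0", "k_T_mu_1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class NumericsConfig:
    """Switching-function numerics.

    The model gates stage transitions and starvation deaths with step
    functions.  For gradient-based optimization these are replaced by the
    smooth surrogate ½ + ½·tanh(k·x); ``switch_steepness`` is k, in inverse
    units of whatever quantity is switched (°C·d for development gates,
    dimensionless μ for deaths).  ``hard_mode`` selects the exact step/max.
    """

    switch_steepness: float = 50.0
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.switch_steepness) and self.switch_steepness > 0):
            raise ValueError("switch_steepness must be strictly positive")


def _format_value(value: float) -> str:
    if isinstance(value, bool):  # pragma: no cover - no bool fields today
        return "true" if value else "false"
    return repr(float(value))


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as a flat TOML file (keys = attribute names)."""
    lines = [f"{k} = {_format_value(v)}" for k, v in params.as_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_params(path: str | Path | None = None) -> ModelParameters:
    """Load a parameter set from a flat TOML file.

    With ``path=None`` the packaged default (literature values) is used.
    Unknown keys raise, so typos in config files fail loudly.
    """
    if path is None:
        text = (
            resources.files("bsfopt").joinpath("data/default_params.toml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = tomllib.loads(text)
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in raw.items()})
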