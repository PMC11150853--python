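"""Core dynamics of the adult BSF egg-production model.

Seven states describe a breeding cage of female flies:

====  ==========  =====================================================
idx   name        meaning
====  ==========  =====================================================
0     N_y         young flies (pupae through wing hardening), count
1     N_act       sexually active flies searching for mates, count
2     N_fert      fertilized flies producing eggs, count
3     N_old       flies that completed oviposition, count
4     T_sum       accumulated development sum (degree-days), °C·d
5     mu          dying-rate / consumed-reserve state, dimensionless
6     m_e         cumulative egg mass, mg
====  ==========  =====================================================

Two controls drive the system: cage temperature ``u_T`` (°C) and daily
photoperiod ``u_L`` (light hours per day).  Development accumulates as
degree-days above a base temperature; gates on the development sum open
stage transitions (mating behaviour, oviposition).  The dying-rate state μ
grows at a temperature-dependent rate; once it crosses zero the flies are
starving and die in proportion to μ.

All functions broadcast over trailing axes and accept complex input, so
the same right-hand side serves plain simulation and complex-step
differentiation inside the optimal-control transcription.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import ModelParameters, NumericsConfig

__all__ = [
    "STATE_NAMES",
    "PopulationState",
    "smooth_switch",
    "smooth_max0",
    "xi_light",
    "xi_temp_fecundity",
    "xi_temp_mortality",
    "stage_gates",
    "rhs",
    "initial_state",
]

STATE_NAMES = ("N_y", "N_act", "N_fert", "N_old", "T_sum", "mu", "m_e")


class PopulationState(NamedTuple):
    """Convenience view of one state vector (see module docstring for units)."""

    N_y: float
    N_act: float
    N_fert: float
    N_old: float
    T_sum: float
    mu: float
    m_e: float

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PopulationState":
        return cls(*(float(v) for v in np.asarray(y)))


def initial_state(p: ModelParameters) -> np.ndarray:
    """Cage start: ``N_y0`` young flies, everything else empty, μ = μ0."""
    y0 = np.zeros(7)
    y0[0] = p.N_y0
    y0[5] = p.mu0
    return y0


def _check_finite(x, name: str) -> None:
    if not np.all(np.isfinite(np.asarray(x))):
        raise ValueError(f"{name} must be finite")


def smooth_switch(x, cfg: NumericsConfig = NumericsConfig()):
    """Unit step sw(x) (0 for x ≤ 0, 1 for x > 0) or its tanh surrogate.

    Smooth mode returns ½ + ½·tanh(k·x) with k = ``cfg.switch_steepness``;
    the surrogate deviates from the step by < 1.1e−9 once |x| ≥ 10/k.
    """
    if not np.iscomplexobj(x):
        _check_finite(x, "switch argument")
    if cfg.hard_mode:
        return np.where(np.asarray(x).real > 0, 1.0, 0.0)
    return 0.5 + 0.5 * np.tanh(cfg.switch_steepness * np.asarray(x))


def smooth_max0(x, cfg: NumericsConfig = NumericsConfig()):
    """max(0, x), smoothed as x·sw(x) in smooth mode."""
    if not np.iscomplexobj(x):
        _check_finite(x, "max argument")
    if cfg.hard_mode:
        return np.maximum(0.0, np.asarray(x))
    return np.asarray(x) * smooth_switch(x, cfg)


def xi_light(u_L, p: ModelParameters):
    """Photoperiod response ξ_L(u_L) = a1·(1 − exp(−a2·u_L)).

    Saturating effect of daily light hours on the chance of finding a
    mating partner; dimensionless, strictly increasing, bounded by a1.
    """
    u = np.asarray(u_L)
    if not np.iscomplexobj(u):
        _check_finite(u, "u_L")
        if np.any(u < 0):
            raise ValueError("photoperiod u_L must be nonnegative")
    return p.a1 * (1.0 - np.exp(-p.a2 * u))


def xi_temp_fecundity(u_T, p: ModelParameters, clip: bool = False):
    """Temperature→fecundity factor, a concave quadratic in u_T.

    ``clip=True`` floors the polynomial at zero for out-of-range
    exploration; the literature coefficients are positive throughout the
    admissible 20–37 °C band, so the default is the literal polynomial.
    """
    u = np.asarray(u_T)
    if not np.iscomplexobj(u):
        _check_finite(u, "u_T")
    val = p.k_T_ovi_2 * u**2 + p.k_T_ovi_1 * u + p.k_T_ovi_0
    if clip:
        val = np.maximum(0.0, val)
    return val


def xi_temp_mortality(u_T, p: ModelParameters):
    """Temperature→dying-rate factor, a convex quadratic in u_T."""
    u = np.asarray(u_T)
    if not np.iscomplexobj(u):
        _check_finite(u, "u_T")
    return p.k_T_mu_2 * u**2 + p.k_T_mu_1 * u + p.k_T_mu_0


def stage_gates(T_sum, p: ModelParameters, cfg: NumericsConfig = NumericsConfig()):
    """Development-sum gated transition rates.

    Returns ``(f_y2act, f_fert2old, f_ovi)``: the young→active rate opens
    at ``k_sum_y2act`` degree-days, oviposition completion and egg laying
    both open at ``k_sum_ovi``.
    """
    ts = np.asarray(T_sum)
    gate_mating = smooth_switch(ts - p.k_sum_y2act, cfg)
    gate_ovi = smooth_switch(ts - p.k_sum_ovi, cfg)
    return (
        gate_mating * p.k_y2act,
        gate_ovi * p.k_fert2old,
        gate_ovi * p.k_ovi,
    )


def rhs(
    state,
    u_T,
    u_L,
    p: ModelParameters,
    cfg: NumericsConfig = NumericsConfig(),
):
    """Combined right-hand side dy/dt of the seven-state model.

    ``state`` has shape ``(7, ...)``; ``u_T``/``u_L`` broadcast against the
    trailing axes.  Stage-coupling terms cancel pairwise, so the total
    population only changes through the starvation death terms
    ``k_mu_N·max(0, μ)`` (pre-old stages) and ``k_mu_old·max(0, μ)`` (old
    stage); with μ < 0 the population is exactly conserved in hard mode.
    """
    y = np.asarray(state)
    if y.shape[0] != 7:
        raise ValueError("state must have leading dimension 7")
    N_y, N_act, N_fert, N_old, T_sum, mu, _ = y

    f_y2act, f_fert2old, f_ovi = stage_gates(T_sum, p, cfg)
    death = smooth_max0(mu, cfg)
    mating = p.k_act2fert * xi_light(u_L, p)

    dN_y = -f_y2act * N_y - p.k_mu_N * death * N_y
    dN_act = f_y2act * N_y - mating * N_act - p.k_mu_N * death * N_act
    dN_fert = mating * N_act - f_fert2old * N_fert - p.k_mu_N * death * N_fert
    dN_old = f_fert2old * N_fert - p.k_mu_old * death * N_old
    dT_sum = smooth_max0(np.asarray(u_T) - p.k_T_sum_min, cfg) + 0.0 * T_sum
    dmu = xi_temp_mortality(u_T, p) * p.k_mu + 0.0 * mu
    dm_e = (1.0 - p.k_mu_ovi * mu) * xi_temp_fecundity(u_T, p) * f_ovi * N_fert

    return np.stack(
        np.broadcast_arrays(dN_y, dN_act, dN_fert, dN_old, dT_sum, dmu, dm_e)
    )
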