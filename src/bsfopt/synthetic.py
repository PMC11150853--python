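"""Synthetic observation sets with known ground truth.

Every calibration pathway needs data; the originals are scattered journal
tables.  This module generates stand-ins from the model itself — response
curves evaluated at a design, or simulated population/egg-mass series —
optionally corrupted with seeded noise, so parameter-recovery behaviour
can be tested end to end.  Each set embeds the generating truth in its
``meta`` for recovery checks.

Relative (multiplicative) normal noise is the default family, reflecting
the heteroscedastic scatter of biological count data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import ObservationSet
from .model import xi_light, xi_temp_fecundity
from .params import ModelParameters, NumericsConfig
from .simulate import ControlSchedule, Trajectory, longevity_5pct, simulate

__all__ = ["NoiseSpec", "generate_response_observations", "generate_timeseries"]

NOISE_FAMILIES = ("none", "additive-normal", "relative-normal")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise family, scale and seed; identical seeds give identical draws."""

    family: str = "none"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be nonnegative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.family == "none" or self.scale == 0.0:
            return np.asarray(values, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        draws = rng.standard_normal(np.shape(values))
        if self.family == "additive-normal":
            return values + self.scale * draws
        return values * (1.0 + self.scale * draws)


def generate_response_observations(
    kind: str,
    p: ModelParameters,
    design,
    noise: NoiseSpec = NoiseSpec(),
    cfg: NumericsConfig = NumericsConfig(),
    longevity_u_L: float = 16.0,
    longevity_horizon: float = 40.0,
) -> ObservationSet:
    """Evaluate a true response at the design points, normalize, add noise.

    Kinds: ``photoperiod_eggmass`` (saturating light curve),
    ``temperature_fecundity`` (concave quadratic), ``temperature_longevity``
    (5%-survival time from full simulations).  Longevity observations are
    in days and get normalized by the noise-free series maximum, as such
    data are published; the two response curves are already dimensionless
    normalized quantities and are emitted as-is, so noiseless fits recover
    the generating coefficients exactly.
    """
    design = np.asarray(design, dtype=float)
    if kind == "photoperiod_eggmass":
        truth = np.asarray(xi_light(design, p), dtype=float)
        truth_params = {"a1": p.a1, "a2": p.a2}
    elif kind == "temperature_fecundity":
        truth = np.asarray(xi_temp_fecundity(design, p), dtype=float)
        truth_params = {
            "k_T_ovi_0": p.k_T_ovi_0,
            "k_T_ovi_1": p.k_T_ovi_1,
            "k_T_ovi_2": p.k_T_ovi_2,
        }
    elif kind == "temperature_longevity":
        truth = np.empty(design.size)
        for i, u_T in enumerate(design):
            traj = simulate(
                p,
                ControlSchedule.constant(u_T, longevity_u_L, longevity_horizon),
                cfg=cfg,
            )
            truth[i] = longevity_5pct(traj)
        truth_params = {
            "k_T_mu_0": p.k_T_mu_0,
            "k_T_mu_1": p.k_T_mu_1,
            "k_T_mu_2": p.k_T_mu_2,
        }
    else:
        raise ValueError(f"invalid response observation kind {kind!r}")

    scale = float(np.max(truth)) if kind == "temperature_longevity" else 1.0
    normalized = truth / scale
    noisy = noise.apply(normalized)
    # keep the normalized-kind invariant (max ≤ 1.05) under mild noise
    noisy = np.minimum(noisy, 1.05)
    return ObservationSet(
        kind,
        design,
        noisy,
        meta={
            "truth": truth_params,
            "normalization": scale,
            "noise": (noise.family, noise.scale, noise.seed),
        },
    )


def generate_timeseries(
    p: ModelParameters,
    sched: ControlSchedule,
    sample_times,
    noise: NoiseSpec = NoiseSpec(),
    cfg: NumericsConfig = NumericsConfig(),
    trajectory: Trajectory | None = None,
) -> tuple[ObservationSet, ObservationSet]:
    """Simulated total-population and egg-mass series at the sample times.

    Counts are floored at zero after noising (a census cannot go
    negative).  The same seed noises both series reproducibly, with
    independent draws per series.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(sample_times < 0) or sample_times[-1] > sched.horizon + 1e-12:
        raise ValueError("sample times must lie within the schedule horizon")
    traj = trajectory if trajectory is not None else simulate(p, sched, cfg=cfg)
    pop = np.interp(sample_times, traj.times, traj.total_population)
    egg = np.interp(sample_times, traj.times, traj.egg_mass)

    pop_noise = noise
    egg_noise = NoiseSpec(noise.family, noise.scale, noise.seed + 1) \
        if noise.family != "none" else noise
    pop_noisy = np.maximum(0.0, pop_noise.apply(pop))
    egg_noisy = np.maximum(0.0, egg_noise.apply(egg))

    meta = {
        "truth": {k: getattr(p, k) for k in
                  ("k_y2act", "k_act2fert", "k_fert2old", "k_ovi", "k_mu")},
        "noise": (noise.family, noise.scale, noise.seed),
    }
    return (
        ObservationSet("population_timeseries", sample_times, pop_noisy, meta=meta),
        ObservationSet("eggmass_timeseries", sample_times, egg_noisy, meta=meta),
    )
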