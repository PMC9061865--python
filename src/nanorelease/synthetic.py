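"""Synthetic release-profile generation.

Emulates the in-vitro dialysis release experiment: a nanoparticle suspension
incubated in a stirred buffer volume, sampled at scheduled times by
withdrawing an aliquot that is replenished with fresh buffer.  The generator
evaluates a BR or BRD model forward on the sampling schedule and adds iid
Gaussian measurement noise on the fraction scale (the default sd of 0.01 is
a declared stand-in for triplicate experimental scatter, for which no error
model is published).

The sampling-withdrawal mass balance is also provided: with medium volume
``V``, aliquot volume ``v`` and measured concentrations ``C_k``, the
cumulative released mass at the k-th sample is
``M_k = V C_k + v * sum_{i<k} C_i`` — the second term restores the drug
removed with the earlier aliquots.  Its inverse converts a known cumulative
release into the concentrations a spectrophotometer would actually read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .arrhenius import ArrheniusLaw
from .fitting import ReleaseProfile
from .kernels import MechanismParams, ParticleGeometry, evaluate_model

__all__ = [
    "SamplingSchedule",
    "NoiseSpec",
    "default_schedule",
    "generate_profile",
    "withdrawal_mass_balance",
    "concentrations_from_cumulative",
    "generate_multitemperature_set",
]


@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling times and withdrawal volumes of a release experiment.

    Defaults mirror the dialysis protocol: 30 mL incubation medium, 1 mL
    aliquots withdrawn and replenished, samples spanning 0–27 days.
    """

    sample_times: np.ndarray
    medium_volume_ml: float = 30.0
    aliquot_volume_ml: float = 1.0
    replenished: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("sample_times must be a nonempty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if not 0 < self.aliquot_volume_ml <= self.medium_volume_ml:
            raise ValueError("need 0 < aliquot_volume_ml <= medium_volume_ml")
        object.__setattr__(self, "sample_times", t)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise on the fraction scale."""

    sd: float = 0.01
    seed: Optional[int] = None
    truncate: bool = True

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def default_schedule(n_times: int = 30, t_end: float = 27.0) -> SamplingSchedule:
    """Evenly spaced schedule over ``[0, t_end]`` days, including the
    time-zero measurement the dialysis protocol records."""
    return SamplingSchedule(sample_times=np.linspace(0.0, t_end, n_times))


def generate_profile(
    params: MechanismParams,
    schedule: Optional[SamplingSchedule] = None,
    noise: Optional[NoiseSpec] = None,
    geom: Optional[ParticleGeometry] = None,
    temperature_K: Optional[float] = None,
    label: str = "",
) -> ReleaseProfile:
    """Forward-simulate one release profile from a model parameter set.

    The model (BR vs BRD) is inferred from ``params``.  With ``sd=0`` the
    output equals the model curve exactly; a given seed makes the output
    bit-reproducible.
    """
    schedule = schedule or default_schedule()
    noise = noise or NoiseSpec()
    t = schedule.sample_times
    f = evaluate_model(t, params, geom)
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        f = f + rng.normal(0.0, noise.sd, size=f.shape)
        if noise.truncate:
            n_clipped = int(np.sum((f < 0) | (f > 1)))
            if n_clipped:
                warnings.warn(
                    f"truncated {n_clipped} noisy fraction(s) to [0, 1]",
                    UserWarning,
                    stacklevel=2,
                )
            f = np.clip(f, 0.0, 1.0)
    return ReleaseProfile(
        times=t, fractions=f, temperature_K=temperature_K, label=label
    )


def withdrawal_mass_balance(raw_concentrations, schedule: SamplingSchedule):
    """Cumulative released mass from sequential aliquot concentrations.

    ``M_k = V C_k + v sum_{i<k} C_i`` for a replenished schedule: the medium
    holds ``V C_k`` at sample k, and each earlier aliquot permanently removed
    ``v C_i`` of drug that must be added back.
    """
    C = np.asarray(raw_concentrations, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    if not schedule.replenished:
        raise ValueError("mass balance implemented for replenished sampling only")
    if C.size != schedule.sample_times.size:
        raise ValueError("one concentration per scheduled sample required")
    V = schedule.medium_volume_ml
    v = schedule.aliquot_volume_ml
    removed_before = v * np.concatenate(([0.0], np.cumsum(C)[:-1]))
    return V * C + removed_before


def concentrations_from_cumulative(cumulative_mass, schedule: SamplingSchedule):
    """Inverse of :func:`withdrawal_mass_balance`: the concentrations each
    aliquot would measure given the true cumulative released mass."""
    M = np.asarray(cumulative_mass, dtype=float)
    if M.size != schedule.sample_times.size:
        raise ValueError("one cumulative mass per scheduled sample required")
    V = schedule.medium_volume_ml
    v = schedule.aliquot_volume_ml
    C = np.empty_like(M)
    removed = 0.0
    for k in range(M.size):
        C[k] = (M[k] - removed) / V
        removed += v * C[k]
    return C


def generate_multitemperature_set(
    laws: dict,
    weights,
    temperatures_K: Sequence[float],
    schedule: Optional[SamplingSchedule] = None,
    noise: Optional[NoiseSpec] = None,
    geom: Optional[ParticleGeometry] = None,
    model: str = "br",
):
    """Generate one profile per temperature with rate parameters driven by
    Arrhenius laws.

    Parameters
    ----------
    laws : dict
        Maps parameter names to :class:`~nanorelease.arrhenius.ArrheniusLaw`:
        ``k_b``, ``k_r``, ``t_max`` (and ``D_e`` for the BRD model).
    weights : dict or sequence of dicts
        Mechanism weights, either one dict (``theta_b`` and, for BRD,
        ``theta_r``) applied at every temperature or one dict per temperature.
    temperatures_K : sequence of float
        Absolute temperatures.
    noise : NoiseSpec, optional
        Each profile k draws from an independent stream seeded with
        ``seed + k`` so profiles are reproducible individually.
    """
    schedule = schedule or default_schedule()
    noise = noise or NoiseSpec()
    temperatures_K = list(temperatures_K)
    if isinstance(weights, dict):
        weights = [weights] * len(temperatures_K)
    if len(weights) != len(temperatures_K):
        raise ValueError("need one weight set per temperature")
    required = {"k_b", "k_r", "t_max"} | ({"D_e"} if model == "brd" else set())
    missing = required - set(laws)
    if missing:
        raise ValueError(f"missing Arrhenius laws for {sorted(missing)}")
    profiles = []
    for k, (T, w) in enumerate(zip(temperatures_K, weights)):
        kwargs = dict(
            theta_b=w["theta_b"],
            k_b=float(laws["k_b"].value(T)),
            k_r=float(laws["k_r"].value(T)),
            t_max=float(laws["t_max"].value(T)),
        )
        if model == "brd":
            kwargs["theta_r"] = w["theta_r"]
            kwargs["D_e"] = float(laws["D_e"].value(T))
        elif model != "br":
            raise ValueError(f"unknown model {model!r}")
        params = MechanismParams(**kwargs)
        prof_noise = noise
        if noise.seed is not None:
            prof_noise = NoiseSpec(
                sd=noise.sd, seed=noise.seed + k, truncate=noise.truncate
            )
        profiles.append(
            generate_profile(
                params,
                schedule=schedule,
                noise=prof_noise,
                geom=geom,
                temperature_K=float(T),
                label=f"synthetic-{model}-{T:.2f}K",
            )
        )
    return profiles
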