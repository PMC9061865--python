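"""Parametric temperature sweeps of the release models.

Evaluates a release surface ``fraction(T, t)`` over a temperature range with
every rate parameter (``k_b``, ``k_r``, ``t_max`` and, for the three-stage
model, ``D_e``) driven by its Arrhenius law.  The mechanism weights theta are
NOT governed by Arrhenius laws, and how they vary with temperature is a
genuine modeling choice; the sweep therefore takes an explicit theta policy —
constants, or linear interpolation of per-temperature fitted weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kernels import MechanismParams, ParticleGeometry, evaluate_model

__all__ = ["ThetaPolicy", "ConstantTheta", "InterpolatedTheta", "SweepSurface", "temperature_sweep"]


class ThetaPolicy:
    """Maps absolute temperature to mechanism weights."""

    def weights_at(self, T_kelvin: float) -> dict:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantTheta(ThetaPolicy):
    """Temperature-independent weights."""

    theta_b: float
    theta_r: Optional[float] = None

    def weights_at(self, T_kelvin: float) -> dict:
        w = {"theta_b": self.theta_b}
        if self.theta_r is not None:
            w["theta_r"] = self.theta_r
        return w


@dataclass(frozen=True)
class InterpolatedTheta(ThetaPolicy):
    """Linear interpolation of per-temperature fitted weights, clamped to the
    end values outside the fitted range."""

    temperatures_K: Sequence[float]
    theta_b: Sequence[float]
    theta_r: Optional[Sequence[float]] = None

    def weights_at(self, T_kelvin: float) -> dict:
        T = np.asarray(self.temperatures_K, dtype=float)
        w = {"theta_b": float(np.interp(T_kelvin, T, np.asarray(self.theta_b, float)))}
        if self.theta_r is not None:
            w["theta_r"] = float(
                np.interp(T_kelvin, T, np.asarray(self.theta_r, float))
            )
        return w


@dataclass(frozen=True)
class SweepSurface:
    """Release fractions on a (temperature, time) grid."""

    temperatures_K: np.ndarray
    times: np.ndarray
    fractions: np.ndarray  # shape (n_temperatures, n_times)
    model_tag: str

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (len(self.temperatures_K), len(self.times)):
            raise ValueError("fractions must have shape (n_temperatures, n_times)")


def temperature_sweep(
    model: str,
    laws: dict,
    theta_policy: ThetaPolicy,
    temperatures_K=None,
    t_grid=None,
    geom: Optional[ParticleGeometry] = None,
    validity_window_K: tuple = (306.15, 333.15),
) -> SweepSurface:
    """Evaluate the release surface over a temperature range.

    Parameters
    ----------
    model : {"br", "brd"}
    laws : dict
        Arrhenius laws per rate parameter (``k_b``, ``k_r``, ``t_max``; plus
        ``D_e`` for ``"brd"``).
    theta_policy : ThetaPolicy
        How the mechanism weights vary with temperature.
    temperatures_K : array, optional
        Defaults to 33–60 degC in 1 degC steps.
    t_grid : array, optional
        Defaults to 0–27 days in 0.1-day steps.
    validity_window_K : (float, float)
        Temperatures outside this window raise a warning (extrapolation
        beyond the regressed range), not an error.
    """
    if temperatures_K is None:
        temperatures_K = 273.15 + np.arange(33.0, 60.0 + 0.5, 1.0)
    if t_grid is None:
        t_grid = np.arange(0.0, 27.0 + 1e-9, 0.1)
    temperatures_K = np.asarray(temperatures_K, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    lo, hi = validity_window_K
    if np.any(temperatures_K < lo) or np.any(temperatures_K > hi):
        warnings.warn(
            f"sweep extrapolates outside the validity window [{lo}, {hi}] K",
            UserWarning,
            stacklevel=2,
        )
    required = {"k_b", "k_r", "t_max"} | ({"D_e"} if model == "brd" else set())
    missing = required - set(laws)
    if missing:
        raise ValueError(f"missing Arrhenius laws for {sorted(missing)}")
    if model not in ("br", "brd"):
        raise ValueError(f"unknown model {model!r}")
    rows = []
    for T in temperatures_K:
        w = theta_policy.weights_at(float(T))
        kwargs = dict(
            theta_b=w["theta_b"],
            k_b=float(laws["k_b"].value(T)),
            k_r=float(laws["k_r"].value(T)),
            t_max=float(laws["t_max"].value(T)),
        )
        if model == "brd":
            if "theta_r" not in w:
                raise ValueError("BRD sweep requires a theta_r in the policy")
            kwargs["theta_r"] = w["theta_r"]
            kwargs["D_e"] = float(laws["D_e"].value(T))
        rows.append(evaluate_model(t_grid, MechanismParams(**kwargs), geom))
    return SweepSurface(
        temperatures_K=temperatures_K,
        times=t_grid,
        fractions=np.vstack(rows),
        model_tag=model,
    )
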