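"""Mechanism kernels for multi-stage drug release from spherical nanoparticles.

Three release mechanisms are modeled, each as a cumulative fractional-release
curve ``Mt/Minf : t -> [0, 1]``:

* **initial burst** — first-order interfacial transfer of surface-proximal
  drug, ``1 - exp(-k_b t)``;
* **degradation–relaxation** — hydrolytic bulk degradation / chain relaxation
  of the polymer matrix, a Prout–Tompkins-type logistic
  ``1 / (1 + exp(-k_r (t - t_max)))`` with midpoint ``t_max``;
* **Fickian diffusion** — drug diffusing out of a sphere of radius ``r1``
  under sink conditions, the classical series solution
  ``1 - (6/pi^2) * sum_n n^-2 exp(-n^2 pi^2 D_e t / r1^2)``.

The two composite models are convex combinations of these kernels: the
burst + relaxation (BR) model uses weights ``(theta_b, 1 - theta_b)`` and the
burst + relaxation + diffusion (BRD) model uses ``(theta_b, theta_r,
theta_d)`` with ``theta_b + theta_r + theta_d = 1``.

Times are in days at the interface; diffusivities in cm^2/s and particle
radius in cm, converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "SECONDS_PER_DAY",
    "DEFAULT_RADIUS_CM",
    "ParticleGeometry",
    "MechanismParams",
    "ReleaseCurve",
    "burst_fraction",
    "degradation_fraction",
    "diffusion_fraction",
    "br_model",
    "brd_model",
    "mechanism_contributions",
]

SECONDS_PER_DAY = 86400.0

#: Default particle radius: half of the 142 nm mean hydrodynamic diameter.
DEFAULT_RADIUS_CM = 7.1e-6

_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class ParticleGeometry:
    """Sphere geometry and unit conventions for the diffusion kernel.

    Parameters
    ----------
    radius_cm : float
        Particle radius ``r1`` in cm. Defaults to 7.1e-6 cm (142 nm diameter).
    seconds_per_day : float
        Conversion applied to the day-scale times before they multiply the
        cm^2/s diffusivity.
    """

    radius_cm: float = DEFAULT_RADIUS_CM
    seconds_per_day: float = SECONDS_PER_DAY

    def __post_init__(self) -> None:
        if not self.radius_cm > 0:
            raise ValueError(f"radius_cm must be positive, got {self.radius_cm}")
        if not self.seconds_per_day > 0:
            raise ValueError("seconds_per_day must be positive")


@dataclass(frozen=True)
class MechanismParams:
    """Parameter set of a BR or BRD release model at one temperature.

    ``theta_r=None`` marks a BR parameter set, where the relaxation weight is
    implicitly ``1 - theta_b`` and no diffusion term exists.  A BRD set
    carries an explicit ``theta_r`` and a diffusivity ``D_e``; the diffusion
    weight is the remainder ``theta_d = 1 - theta_b - theta_r``.
    """

    theta_b: float
    k_b: float
    k_r: float
    t_max: float
    theta_r: Optional[float] = None
    D_e: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_b <= 1.0:
            raise ValueError(f"theta_b must be in [0, 1], got {self.theta_b}")
        if not self.k_b > 0:
            raise ValueError(f"k_b must be positive, got {self.k_b}")
        if not self.k_r > 0:
            raise ValueError(f"k_r must be positive, got {self.k_r}")
        if not self.t_max > 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if self.theta_r is not None:
            if not 0.0 <= self.theta_r <= 1.0:
                raise ValueError(f"theta_r must be in [0, 1], got {self.theta_r}")
            if self.theta_b + self.theta_r > 1.0 + _CLAMP_TOL:
                raise ValueError(
                    f"theta_b + theta_r = {self.theta_b + self.theta_r} exceeds 1"
                )
            if self.D_e is None:
                raise ValueError("a BRD parameter set requires D_e")
            if self.D_e < 0:
                raise ValueError(f"D_e must be nonnegative, got {self.D_e}")

    @property
    def is_brd(self) -> bool:
        return self.theta_r is not None

    @property
    def theta_d(self) -> float:
        """Diffusion weight ``1 - theta_b - theta_r`` (0 for a BR set)."""
        if self.theta_r is None:
            return 0.0
        return max(0.0, 1.0 - self.theta_b - self.theta_r)

    @property
    def weights(self) -> tuple:
        """Mechanism weights: ``(theta_b, theta_r)`` for BR (with
        ``theta_r = 1 - theta_b``), ``(theta_b, theta_r, theta_d)`` for BRD."""
        if self.theta_r is None:
            return (self.theta_b, 1.0 - self.theta_b)
        return (self.theta_b, self.theta_r, self.theta_d)


@dataclass(frozen=True)
class ReleaseCurve:
    """A model-evaluated cumulative release curve on a time grid."""

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times and fractions must have the same shape")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(f < -_CLAMP_TOL) or np.any(f > 1 + _CLAMP_TOL):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", np.clip(f, 0.0, 1.0))


def _validate_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    return t


def _clamp01(x: np.ndarray) -> np.ndarray:
    """Clamp floating-point spill outside [0, 1]; larger violations raise."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -_CLAMP_TOL) or np.any(x > 1 + _CLAMP_TOL):
        raise FloatingPointError("kernel value outside [0, 1] beyond tolerance")
    return np.clip(x, 0.0, 1.0)


def burst_fraction(t, k_b: float):
    """First-order initial-burst release fraction ``1 - exp(-k_b t)``.

    Parameters
    ----------
    t : array_like
        Time in days, nonnegative.
    k_b : float
        Burst rate constant in 1/day, positive.
    """
    t = _validate_times(t)
    if not k_b > 0:
        raise ValueError(f"k_b must be positive, got {k_b}")
    return -np.expm1(-k_b * t)


def degradation_fraction(t, k_r: float, t_max: float):
    """Prout–Tompkins degradation–relaxation fraction.

    A logistic in time, ``1 / (1 + exp(-k_r (t - t_max)))``, reaching one half
    exactly at the maximum-rate time ``t_max``.

    Parameters
    ----------
    t : array_like
        Time in days, nonnegative.
    k_r : float
        Degradation–relaxation rate constant in 1/day, positive.
    t_max : float
        Time of 50% release for this mechanism, in days, positive.
    """
    t = _validate_times(t)
    if not k_r > 0:
        raise ValueError(f"k_r must be positive, got {k_r}")
    if not t_max > 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    return expit(k_r * (t - t_max))


def diffusion_fraction(
    t,
    D_e: float,
    geom: Optional[ParticleGeometry] = None,
    tol: float = 1e-12,
    max_terms: int = 10_000,
):
    """Fractional release by Fickian diffusion out of a sphere (sink surface).

    Evaluates the separation-of-variables series
    ``Mt/Minf = 1 - (6/pi^2) sum_{n>=1} n^-2 exp(-n^2 pi^2 tau)`` with the
    dimensionless time ``tau = D_e * t_sec / r1^2``.  The series is truncated
    adaptively: terms are added until the next term falls below ``tol`` (or
    ``max_terms`` is reached, which raises a warning).  ``t = 0`` is
    special-cased to exactly 0 — there the untruncated series sums to 1.

    Parameters
    ----------
    t : array_like
        Time in days, nonnegative.
    D_e : float
        Effective diffusion coefficient in cm^2/s, nonnegative.
    geom : ParticleGeometry, optional
        Particle radius and unit conversion; defaults to the 142 nm particle.
    """
    t = _validate_times(t)
    if D_e < 0:
        raise ValueError(f"D_e must be nonnegative, got {D_e}")
    if geom is None:
        geom = ParticleGeometry()
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    tau = D_e * t * geom.seconds_per_day / geom.radius_cm**2
    out = np.zeros_like(tau)
    pos = tau > 0
    if np.any(pos):
        tau_min = tau[pos].min()
        # term n has magnitude <= exp(-n^2 pi^2 tau_min); solve for tol
        n_needed = int(np.ceil(np.sqrt(max(-np.log(tol), 1.0) / (np.pi**2 * tau_min))))
        if n_needed > max_terms:
            warnings.warn(
                f"diffusion series truncated at max_terms={max_terms} before "
                f"reaching tol={tol} (smallest dimensionless time {tau_min:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
        n = np.arange(1, min(n_needed, max_terms) + 1, dtype=float)
        terms = np.exp(-np.outer(tau[pos], n**2) * np.pi**2) / n**2
        out[pos] = 1.0 - (6.0 / np.pi**2) * terms.sum(axis=1)
    out = _clamp01(out)
    return out[0] if scalar else out


def br_model(t, params: MechanismParams):
    """Two-stage burst + degradation–relaxation (BR) release model.

    ``theta_b * burst(t; k_b) + (1 - theta_b) * relaxation(t; k_r, t_max)``.
    """
    f = params.theta_b * burst_fraction(t, params.k_b) + (
        1.0 - params.theta_b
    ) * degradation_fraction(t, params.k_r, params.t_max)
    return _clamp01(f)


def brd_model(t, params: MechanismParams, geom: Optional[ParticleGeometry] = None):
    """Three-stage burst + relaxation + diffusion (BRD) release model.

    ``theta_b * burst + theta_r * relaxation + theta_d * diffusion`` with
    ``theta_d = 1 - theta_b - theta_r``.
    """
    if not params.is_brd:
        raise ValueError("brd_model requires a BRD parameter set (theta_r, D_e)")
    f = (
        params.theta_b * burst_fraction(t, params.k_b)
        + params.theta_r * degradation_fraction(t, params.k_r, params.t_max)
        + params.theta_d * diffusion_fraction(t, params.D_e, geom)
    )
    return _clamp01(f)


def evaluate_model(t, params: MechanismParams, geom: Optional[ParticleGeometry] = None):
    """Evaluate whichever composite model ``params`` describes (BR or BRD)."""
    if params.is_brd:
        return brd_model(t, params, geom)
    return br_model(t, params)


def mechanism_contributions(
    t_grid, params: MechanismParams, geom: Optional[ParticleGeometry] = None
) -> dict:
    """Decompose a model curve into its theta-weighted mechanism components.

    Returns a dict with keys ``"weights"`` (mechanism name -> theta) and
    ``"curves"`` (mechanism name -> weighted component curve); the pointwise
    sum of the curves equals the composite model curve exactly.
    """
    t_grid = _validate_times(t_grid)
    curves = {
        "burst": params.theta_b * burst_fraction(t_grid, params.k_b),
    }
    weights = {"burst": params.theta_b}
    if params.is_brd:
        weights["relaxation"] = params.theta_r
        weights["diffusion"] = params.theta_d
        curves["relaxation"] = params.theta_r * degradation_fraction(
            t_grid, params.k_r, params.t_max
        )
        curves["diffusion"] = params.theta_d * diffusion_fraction(
            t_grid, params.D_e, geom
        )
    else:
        weights["relaxation"] = 1.0 - params.theta_b
        curves["relaxation"] = (1.0 - params.theta_b) * degradation_fraction(
            t_grid, params.k_r, params.t_max
        )
    return {"weights": weights, "curves": curves}
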