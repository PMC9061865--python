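"""Arrhenius-form temperature laws for release-rate parameters.

Each release parameter ``theta`` governed by temperature is modeled as
``theta(T) = A * exp(-Ea / (R T))`` with prefactor ``A`` in the parameter's
own units and activation energy ``Ea`` in cal/mol (negative values are
allowed and encode parameters that shrink with rising temperature, such as
the 50%-release time).  Estimation is the classical linearization: ordinary
least squares of ``ln(theta)`` on ``1/T``, with ``Ea = -slope * R`` and
``A = exp(intercept)``.

Two regression modes are provided: ``"all"`` (OLS over every temperature)
and ``"endpoints"`` (the line through the lowest- and highest-temperature
points only — the variant that best matches tabulated constants produced by
two-point linearizations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GAS_CONSTANT_CAL",
    "ArrheniusLaw",
    "ArrheniusRegression",
    "arrhenius_value",
    "fit_arrhenius",
    "celsius_to_kelvin",
]

#: Gas constant in cal / (mol K).
GAS_CONSTANT_CAL = 1.9872


def celsius_to_kelvin(T_celsius):
    """Convert Celsius to absolute temperature (K = degC + 273.15)."""
    return np.asarray(T_celsius, dtype=float) + 273.15


@dataclass(frozen=True)
class ArrheniusLaw:
    """``value(T) = A * exp(-Ea / (R T))`` for one release parameter.

    Parameters
    ----------
    prefactor : float
        ``A``, in the units of the governed parameter; positive.
    activation_energy_cal : float
        ``Ea`` in cal/mol; may be negative.
    gas_constant : float
        ``R`` in cal/(mol K).
    """

    prefactor: float
    activation_energy_cal: float
    gas_constant: float = GAS_CONSTANT_CAL

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise ValueError(f"prefactor must be positive, got {self.prefactor}")
        if not self.gas_constant > 0:
            raise ValueError("gas_constant must be positive")

    @property
    def activation_energy_kcal(self) -> float:
        """``Ea`` in kcal/mol, the unit conventional for reporting."""
        return self.activation_energy_cal / 1000.0

    def value(self, T_kelvin):
        """Evaluate the law at absolute temperature(s) ``T_kelvin``."""
        T = np.asarray(T_kelvin, dtype=float)
        if np.any(T <= 0):
            raise ValueError("absolute temperature must be positive")
        return self.prefactor * np.exp(
            -self.activation_energy_cal / (self.gas_constant * T)
        )


def arrhenius_value(T_kelvin, law: ArrheniusLaw):
    """Evaluate ``law`` at absolute temperature(s) ``T_kelvin``."""
    return law.value(T_kelvin)


class ArrheniusRegression(RegressorMixin, BaseEstimator):
    """Estimate an Arrhenius law from parameter values at several temperatures.

    Fits ``ln(value)`` against ``1/T`` by ordinary least squares and converts
    slope and intercept to activation energy and prefactor.

    Parameters
    ----------
    mode : {"all", "endpoints"}
        Use every point, or only the lowest- and highest-temperature points.
    gas_constant : float
        ``R`` in cal/(mol K); scales the activation energy.

    Attributes
    ----------
    law_ : ArrheniusLaw
        The fitted law.
    prefactor_ : float
    activation_energy_cal_ : float
    activation_energy_kcal_ : float
    r_squared_ : float
        Coefficient of determination of the line in (1/T, ln value) space.
    """

    def __init__(self, mode: str = "all", gas_constant: float = GAS_CONSTANT_CAL):
        self.mode = mode
        self.gas_constant = gas_constant

    def fit(self, T_kelvin, values):
        T = np.asarray(T_kelvin, dtype=float).ravel()
        v = np.asarray(values, dtype=float).ravel()
        if T.shape != v.shape:
            raise ValueError("temperatures and values must have the same length")
        if T.size < 2:
            raise ValueError("at least two temperatures are required")
        if np.any(T <= 0):
            raise ValueError("absolute temperatures must be positive")
        if np.any(v <= 0):
            raise ValueError("parameter values must be positive for a log fit")
        if self.mode not in ("all", "endpoints"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "endpoints":
            idx = [int(np.argmin(T)), int(np.argmax(T))]
            T, v = T[idx], v[idx]
        if T[0] == T[-1] or np.unique(T).size < 2:
            raise ValueError("need at least two distinct temperatures")
        x = 1.0 / T
        y = np.log(v)
        slope, intercept = np.polyfit(x, y, 1)
        self.activation_energy_cal_ = float(-slope * self.gas_constant)
        self.activation_energy_kcal_ = self.activation_energy_cal_ / 1000.0
        self.prefactor_ = float(np.exp(intercept))
        yhat = slope * x + intercept
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum((y - yhat) ** 2))
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        self.law_ = ArrheniusLaw(
            prefactor=self.prefactor_,
            activation_energy_cal=self.activation_energy_cal_,
            gas_constant=self.gas_constant,
        )
        return self

    def predict(self, T_kelvin):
        return self.law_.value(T_kelvin)


def fit_arrhenius(
    T_kelvin,
    values,
    mode: str = "all",
    gas_constant: float = GAS_CONSTANT_CAL,
) -> ArrheniusLaw:
    """Fit an :class:`ArrheniusLaw` to parameter values at several temperatures.

    Thin wrapper over :class:`ArrheniusRegression`; see its docstring.
    """
    return ArrheniusRegression(mode=mode, gas_constant=gas_constant).fit(
        T_kelvin, values
    ).law_
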