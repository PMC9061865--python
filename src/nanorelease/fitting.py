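"""Constrained nonlinear least-squares estimation of the BR and BRD models.

A release profile (times, cumulative fractions) measured at one temperature
is fitted by trust-region-reflective least squares from a deterministic
lattice of starting points, because the residual surface of the composite
models is multimodal.  The best (lowest-cost) solution over all starts is
returned.  The three-mechanism model's weight constraint
``theta_b + theta_r <= 1`` is enforced by reparameterization —
``theta_b = u``, ``theta_r = (1 - u) v`` with ``u, v`` in the unit box — so
the optimizer never visits an infeasible point; the diffusivity is searched
in log10 space because plausible values span many decades.

Model comparison uses the adjusted coefficient of determination
``R2_adj = 1 - (1 - R2) (n_dp - 1) / (n_dp - p - 1)``, which, unlike R2,
can decrease when an extra mechanism does not earn its parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .kernels import (
    MechanismParams,
    ParticleGeometry,
    br_model,
    brd_model,
)

__all__ = [
    "ReleaseProfile",
    "FitResult",
    "BurstRelaxationModel",
    "BurstRelaxationDiffusionModel",
    "fit_br",
    "fit_brd",
    "goodness_of_fit",
]

_BOUND_TOL = 1e-6
_RATE_LOWER = 1e-8
_RATE_UPPER = 100.0
_LOG10_DE_BOUNDS = (-22.0, -12.0)


@dataclass(frozen=True)
class ReleaseProfile:
    """One temperature's cumulative fractional release time series.

    Parameters
    ----------
    times : array
        Sampling times in days, strictly increasing.
    fractions : array
        Cumulative ``Mt/Minf``.  Values up to 1.05 are tolerated on input
        (small experimental overshoot) but flagged with a warning.
    temperature_K : float, optional
        Incubation temperature in kelvin.
    label : str
        Free-text identifier.
    """

    times: np.ndarray
    fractions: np.ndarray
    temperature_K: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fractions must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(f < 0) or np.any(f > 1.05):
            raise ValueError("fractions must lie in [0, 1.05]")
        if np.any(f > 1.0):
            warnings.warn(
                "profile contains fractions above 1 (experimental overshoot)",
                UserWarning,
                stacklevel=2,
            )
        if self.temperature_K is not None and not self.temperature_K > 0:
            raise ValueError("temperature_K must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a constrained least-squares model fit."""

    params: MechanismParams
    residual_sum_of_squares: float
    r_squared: float
    r_squared_adjusted: float
    n_dp: int
    p: int
    converged: bool
    at_bound: dict = field(default_factory=dict)
    n_starts: int = 0


def goodness_of_fit(observed, predicted, p: int):
    """Coefficient of determination and its ``p``-parameter adjustment.

    ``R2 = 1 - SS_res / SS_tot`` about the observed mean and
    ``R2_adj = 1 - (1 - R2) (n - 1) / (n - p - 1)``.

    Raises for ``n <= p + 1`` (adjustment undefined) and for zero variance
    in the observations.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    n = obs.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 data points (n={n}, p={p})")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, r2_adj


def _lattice(axes: dict, jitter: float, rng: Optional[np.random.Generator]):
    """Cartesian product of per-parameter start values, optionally jittered."""
    names = list(axes)
    starts = [
        dict(zip(names, combo)) for combo in itertools.product(*axes.values())
    ]
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter requires a seed")
        for s in starts:
            for k in s:
                s[k] = s[k] * (1.0 + jitter * rng.uniform(-1.0, 1.0))
    return starts


class _ReleaseFitBase(RegressorMixin, BaseEstimator):
    """Shared multistart machinery of the BR and BRD estimators."""

    #: ordered names of the optimizer's parameter vector; set by subclass
    _param_names: tuple = ()

    def _check_fit_inputs(self, t, y):
        t = np.asarray(t, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:  # sklearn-style column vector
            t = t.ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        p = len(self._param_names)
        if t.size < p + 2:
            raise ValueError(
                f"need at least {p + 2} data points to fit {p} parameters"
            )
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        return t, y

    def _run_multistart(self, t, y, starts, bounds, n_polish: int = 8):
        """Two-phase deterministic multistart: a cheap screening pass from
        every start, then a full-tolerance polish of the best candidates."""
        lb, ub = bounds

        def residuals(x):
            return self._curve(t, x) - y

        screened = []
        for x0 in starts:
            x0 = np.clip(x0, lb, ub)
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lb, ub), method="trf",
                    max_nfev=60, ftol=1e-6, xtol=1e-6, gtol=1e-6,
                )
            except Exception:
                continue
            screened.append(sol)
        screened.sort(key=lambda s: s.cost)

        best = None
        converged = False
        for cand in screened[:n_polish]:
            try:
                sol = least_squares(
                    residuals, cand.x, bounds=(lb, ub), method="trf", max_nfev=400
                )
            except Exception:
                continue
            if sol.status > 0:
                converged = True
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not converged:
            raise RuntimeError(
                "model fit failed: no multistart converged "
                f"({len(starts)} starts attempted)"
            )
        return best

    def _finalize(self, t, y, sol, bounds, n_starts):
        lb, ub = bounds
        at_bound = {
            name: bool(
                abs(sol.x[i] - lb[i]) < _BOUND_TOL or abs(sol.x[i] - ub[i]) < _BOUND_TOL
            )
            for i, name in enumerate(self._param_names)
        }
        params = self._to_params(sol.x)
        pred = self._curve(t, sol.x)
        p = len(self._param_names)
        r2, r2_adj = goodness_of_fit(y, pred, p)
        self.params_ = params
        self.result_ = FitResult(
            params=params,
            residual_sum_of_squares=float(np.sum((pred - y) ** 2)),
            r_squared=r2,
            r_squared_adjusted=r2_adj,
            n_dp=int(t.size),
            p=p,
            converged=True,
            at_bound=at_bound,
            n_starts=n_starts,
        )
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        return self._predict_curve(t)


class BurstRelaxationModel(_ReleaseFitBase):
    """Two-stage (burst + degradation–relaxation) release model estimator.

    Fits ``(theta_b, k_b, k_r, t_max)`` by bounded trust-region least squares
    from a deterministic multistart lattice.

    Parameters
    ----------
    starts : "lattice" or sequence of 4-vectors
        Starting points ``(theta_b, k_b, k_r, t_max)``; the default lattice is
        ``theta_b in {0.2, 0.5, 0.8}``, ``k_b in {0.5, 2, 5}``,
        ``k_r in {0.05, 0.2, 1}`` and ``t_max in {0.25, 0.5, 0.75} * max(t)``.
    jitter : float
        Optional relative perturbation (e.g. 0.1 for +-10%) applied to the
        lattice; requires ``seed``.
    seed : int, optional
        Seeds the jitter only; the unjittered fit is fully deterministic.

    Attributes
    ----------
    params_ : MechanismParams
    result_ : FitResult
    """

    _param_names = ("theta_b", "k_b", "k_r", "t_max")

    def __init__(self, starts="lattice", jitter: float = 0.0, seed: Optional[int] = None):
        self.starts = starts
        self.jitter = jitter
        self.seed = seed

    def _curve(self, t, x):
        theta_b, k_b, k_r, t_max = x
        params = MechanismParams(theta_b=theta_b, k_b=k_b, k_r=k_r, t_max=t_max)
        return br_model(t, params)

    def _to_params(self, x):
        return MechanismParams(theta_b=x[0], k_b=x[1], k_r=x[2], t_max=x[3])

    def _predict_curve(self, t):
        return br_model(t, self.params_)

    def fit(self, t, y):
        t, y = self._check_fit_inputs(t, y)
        t_span = float(t.max())
        lb = np.array([0.0, _RATE_LOWER, _RATE_LOWER, _RATE_LOWER])
        ub = np.array([1.0, _RATE_UPPER, _RATE_UPPER, 10.0 * t_span])
        if isinstance(self.starts, str) and self.starts == "lattice":
            rng = np.random.default_rng(self.seed) if self.seed is not None else None
            axes = {
                "theta_b": (0.2, 0.5, 0.8),
                "k_b": (0.5, 2.0, 5.0),
                "k_r": (0.05, 0.2, 1.0),
                "t_max": tuple(f * t_span for f in (0.25, 0.5, 0.75)),
            }
            start_dicts = _lattice(axes, self.jitter, rng)
            starts = [
                np.array([s["theta_b"], s["k_b"], s["k_r"], s["t_max"]])
                for s in start_dicts
            ]
        else:
            starts = [np.asarray(s, dtype=float) for s in self.starts]
        sol = self._run_multistart(t, y, starts, (lb, ub))
        return self._finalize(t, y, sol, (lb, ub), len(starts))


class BurstRelaxationDiffusionModel(_ReleaseFitBase):
    """Three-stage (burst + relaxation + diffusion) release model estimator.

    Fits ``(theta_b, theta_r, k_b, k_r, t_max, D_e)``.  Internally the
    optimizer works on ``(u, v, k_b, k_r, t_max, log10(D_e))`` with
    ``theta_b = u`` and ``theta_r = (1 - u) v``, which keeps
    ``theta_b + theta_r <= 1`` satisfied by construction.

    Parameters
    ----------
    geometry : ParticleGeometry, optional
        Particle radius for the diffusion kernel (default 142 nm diameter).
    starts : "lattice" or sequence of 6-vectors
        Start vectors in the transformed coordinates
        ``(u, v, k_b, k_r, t_max, log10_D_e)``; the default lattice extends
        the two-stage one with ``theta_r in {0.1, 0.4}`` (converted to ``v``)
        and ``log10(D_e) in {-19, -17, -15}``.
    """

    _param_names = ("theta_b", "theta_r", "k_b", "k_r", "t_max", "log10_D_e")

    def __init__(
        self,
        geometry: Optional[ParticleGeometry] = None,
        starts="lattice",
        jitter: float = 0.0,
        seed: Optional[int] = None,
    ):
        self.geometry = geometry
        self.starts = starts
        self.jitter = jitter
        self.seed = seed

    def _geom(self):
        return self.geometry if self.geometry is not None else ParticleGeometry()

    def _to_params(self, x):
        u, v, k_b, k_r, t_max, log_de = x
        theta_b = float(u)
        theta_r = float((1.0 - u) * v)
        return MechanismParams(
            theta_b=theta_b,
            theta_r=theta_r,
            k_b=k_b,
            k_r=k_r,
            t_max=t_max,
            D_e=10.0**log_de,
        )

    def _curve(self, t, x):
        return brd_model(t, self._to_params(x), self._geom())

    def _predict_curve(self, t):
        return brd_model(t, self.params_, self._geom())

    def fit(self, t, y):
        t, y = self._check_fit_inputs(t, y)
        t_span = float(t.max())
        lb = np.array(
            [0.0, 0.0, _RATE_LOWER, _RATE_LOWER, _RATE_LOWER, _LOG10_DE_BOUNDS[0]]
        )
        ub = np.array([1.0, 1.0, _RATE_UPPER, _RATE_UPPER, 10.0 * t_span, _LOG10_DE_BOUNDS[1]])
        if isinstance(self.starts, str) and self.starts == "lattice":
            rng = np.random.default_rng(self.seed) if self.seed is not None else None
            axes = {
                "theta_b": (0.2, 0.5, 0.8),
                "theta_r": (0.1, 0.4),
                "k_b": (0.5, 2.0, 5.0),
                "k_r": (0.05, 0.2, 1.0),
                "t_max": tuple(f * t_span for f in (0.25, 0.5, 0.75)),
                "log10_D_e": (-19.0, -17.0, -15.0),
            }
            start_dicts = _lattice(axes, self.jitter, rng)
            starts = []
            for s in start_dicts:
                u = s["theta_b"]
                v = s["theta_r"] / (1.0 - u) if u < 1.0 else 0.0
                starts.append(
                    np.array(
                        [u, min(v, 1.0), s["k_b"], s["k_r"], s["t_max"], s["log10_D_e"]]
                    )
                )
        else:
            starts = [np.asarray(s, dtype=float) for s in self.starts]
        sol = self._run_multistart(t, y, starts, (lb, ub))
        return self._finalize(t, y, sol, (lb, ub), len(starts))


def fit_br(
    profile: ReleaseProfile,
    starts="lattice",
    seed: Optional[int] = None,
    jitter: float = 0.0,
) -> FitResult:
    """Fit the two-stage BR model to a release profile; see
    :class:`BurstRelaxationModel`."""
    est = BurstRelaxationModel(starts=starts, jitter=jitter, seed=seed)
    est.fit(profile.times, profile.fractions)
    return est.result_


def fit_brd(
    profile: ReleaseProfile,
    geometry: Optional[ParticleGeometry] = None,
    starts="lattice",
    seed: Optional[int] = None,
    jitter: float = 0.0,
) -> FitResult:
    """Fit the three-stage BRD model to a release profile; see
    :class:`BurstRelaxationDiffusionModel`."""
    est = BurstRelaxationDiffusionModel(
        geometry=geometry, starts=starts, jitter=jitter, seed=seed
    )
    est.fit(profile.times, profile.fractions)
    return est.result_
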