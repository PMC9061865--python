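"""Brute-force oracle for the sphere-diffusion kernel.

Solves the radial diffusion boundary-value problem directly — symmetry at the
center, sink (zero concentration) at the surface, uniform initial loading —
by the method of lines on the substituted variable ``u = rho * c``, which
turns the spherical Laplacian into a plain 1-D second difference.  Stepping
is implicit (BDF).  Entirely independent of the analytical series solution it
cross-checks.
"""

import numpy as np
from scipy.integrate import solve_ivp


def released_fraction_fd(times_days, D_e, radius_cm, n_shells=240,
                         seconds_per_day=86400.0):
    """Cumulative released fraction Mt/Minf at the given times (days)."""
    times_days = np.asarray(times_days, dtype=float)
    tau = D_e * times_days * seconds_per_day / radius_cm**2  # dimensionless
    n = n_shells
    h = 1.0 / n
    rho = np.linspace(0.0, 1.0, n + 1)
    u0 = rho[1:-1].copy()  # u(rho,0) = rho * c0, c0 = 1

    def rhs(_, u):
        du = np.empty_like(u)
        du[0] = (u[1] - 2 * u[0]) / h**2           # u(0) = 0
        du[-1] = (u[-2] - 2 * u[-1]) / h**2        # u(1) = 0
        du[1:-1] = (u[2:] - 2 * u[1:-1] + u[:-2]) / h**2
        return du

    from scipy.sparse import diags
    jac = diags(
        [np.full(n - 2, 1 / h**2), np.full(n - 1, -2 / h**2), np.full(n - 2, 1 / h**2)],
        [-1, 0, 1],
    )
    tau_pos = tau[tau > 0]
    out = np.zeros_like(tau)
    if tau_pos.size:
        order = np.argsort(tau_pos)
        sol = solve_ivp(
            rhs, (0.0, float(tau_pos.max())), u0, method="BDF",
            t_eval=np.sort(tau_pos), jac=jac, rtol=1e-8, atol=1e-10,
        )
        remaining = np.array([
            3.0 * np.trapezoid(
                np.concatenate(([0.0], u, [0.0])) * rho, rho
            )
            for u in sol.y.T
        ])  # 3 * int_0^1 u rho drho = fraction still inside
        frac_sorted = 1.0 - remaining
        frac = np.empty_like(frac_sorted)
        frac[order] = frac_sorted
        out[tau > 0] = frac
    return out
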