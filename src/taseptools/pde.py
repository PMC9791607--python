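"""Forward-time centred-space (FTCS) integration of the mean-field continuum equation.

The coarse-grained density obeys the viscous conservation law

    d(rho)/dt = (eps/2) d2(rho)/dx2 - d/dx [rho (1 - rho)],    eps = 1/L,

on x in (0, 1].  Interior nodes advance by the explicit scheme with diffusion
coefficient eps/2 and advection velocity (2 rho - 1); the two boundary nodes
advance by the discrete reservoir equations

    rho_1  += dt [alpha (1 - rho_1) - rho_1 (1 - rho_2)],
    rho_L  += dt [rho_{L-1} (1 - rho_L) - beta rho_L].

The scheme is stable for dt/dx^2 <= 1; that criterion ignores the advective
CFL contribution, so the default time step uses a safety factor of 0.5
(exposed as ``dt_factor``).  Iterating to the residual tolerance yields the
steady-state profile, whose bulk value reproduces the mean-field phase
diagram and whose boundary layers resolve the finite-L structure that the
strict bulk limit leaves open.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels
from .lattice import Boundary, SystemParams

__all__ = ["StabilityError", "ConvergenceError", "FTCSResult", "ftcs_step", "ftcs_solve"]


class StabilityError(ValueError):
    """Time step violates the explicit-scheme stability criterion dt/dx^2 <= 1."""


class ConvergenceError(RuntimeError):
    """Residual failed to drop below tolerance within the step budget."""


@dataclasses.dataclass
class FTCSResult:
    """Converged steady profile plus convergence metadata."""

    x: np.ndarray
    profile: np.ndarray
    alpha: float
    beta: float
    eps: float
    dt: float
    n_steps: int
    residual: float

    @property
    def mid_density(self) -> float:
        """Density at the lattice midpoint (mean of the two central nodes if L is even)."""
        L = self.profile.shape[0]
        if L % 2:
            return float(self.profile[L // 2])
        return float(self.profile[L // 2 - 1 : L // 2 + 1].mean())


def _check_stability(dt: float, dx: float) -> None:
    if dt / dx**2 > 1.0 + 1e-12:
        raise StabilityError(
            f"dt/dx^2 = {dt / dx**2:g} exceeds the stability criterion dt/dx^2 <= 1"
        )


def ftcs_step(profile: np.ndarray, alpha: float, beta: float, dt: float,
              dx: float, eps: float) -> np.ndarray:
    """One explicit step; returns the advanced profile (input untouched)."""
    _check_stability(dt, dx)
    rho = np.asarray(profile, dtype=float)
    if rho.ndim != 1 or rho.shape[0] < 3:
        raise ValueError("profile must be 1-D with at least 3 nodes")
    new = rho.copy()
    new[0] = rho[0] + dt * (alpha * (1.0 - rho[0]) - rho[0] * (1.0 - rho[1]))
    new[-1] = rho[-1] + dt * (rho[-2] * (1.0 - rho[-1]) - beta * rho[-1])
    new[1:-1] = (
        rho[1:-1]
        + eps * dt / (2.0 * dx**2) * (rho[2:] - 2.0 * rho[1:-1] + rho[:-2])
        + dt / (2.0 * dx) * (rho[2:] - rho[:-2]) * (2.0 * rho[1:-1] - 1.0)
    )
    return new


def ftcs_solve(
    params: SystemParams,
    tol: float = 1e-8,
    max_steps: int = 20_000_000,
    *,
    dt_factor: float = 0.5,
    eps: float | None = None,
    initial: np.ndarray | str = "uniform",
) -> FTCSResult:
    """Iterate the scheme to the stationary density profile of the open chain.

    Convergence is declared when max_i |rho_i^{j+1} - rho_i^j| / dt < tol, a
    dt-independent residual.  ``initial`` may be "uniform" (rho = 1/2),
    "riemann" (the step profile alpha | 1-beta at x = 0.5), or an explicit
    array.  ``eps`` defaults to 1/L but may be decoupled from the grid for
    refinement studies.
    """
    if params.boundary is not Boundary.OPEN:
        raise ValueError("the FTCS solver applies to open boundaries only")
    L = params.L
    if L < 3:
        raise ValueError("need at least 3 nodes")
    dx = 1.0 / L
    if eps is None:
        eps = dx
    dt = dt_factor * dx**2
    _check_stability(dt, dx)
    x = (np.arange(L) + 1.0) / L
    if isinstance(initial, str):
        if initial == "uniform":
            rho = np.full(L, 0.5)
        elif initial == "riemann":
            rho = np.where(x < 0.5, params.alpha, 1.0 - params.beta).astype(float)
        else:
            raise ValueError(f"unknown initial condition {initial!r}")
    else:
        rho = np.array(initial, dtype=float)
        if rho.shape != (L,):
            raise ValueError(f"initial profile must have shape ({L},)")
    steps, residual, ok = _kernels.run_ftcs(
        rho, params.alpha, params.beta, dt, dx, eps, tol, max_steps, True
    )
    if not ok:
        raise RuntimeError("density left [0,1] during integration (unstable parameters)")
    if residual >= tol:
        raise ConvergenceError(
            f"no convergence within {max_steps} steps; final residual {residual:g} >= tol {tol:g}"
        )
    return FTCSResult(x=x, profile=rho, alpha=params.alpha, beta=params.beta,
                      eps=eps, dt=dt, n_steps=int(steps), residual=float(residual))
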