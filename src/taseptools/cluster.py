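"""Two-site cluster mean-field theory for the parallel update rule.

The parallel rule induces nearest-neighbour particle-hole correlations that
the one-site closure misses.  Factorising the configuration probability into
overlapping two-site clusters and imposing the Kolmogorov consistency
conditions

    P(00) + P(01) + P(10) + P(11) = 1,
    P(10) + P(11) = rho,   P(00) + P(01) = 1 - rho,   P(01) = P(10),

closes the master equation for P(10) into the quadratic
P(10)^2 - P(10) + rho(1 - rho) = 0, whose admissible root is

    P(10) = (1 - sqrt(1 - 4 rho (1 - rho))) / 2  =  min(rho, 1 - rho).

The particle current equals P(10), i.e. J(rho) = min(rho, 1 - rho) — always
at least the uncorrelated value rho(1 - rho).  The open-chain phase diagram
follows from the extremal-current principle applied to the effective
boundary densities rho(0) = alpha/(1 + alpha), rho(1) = 1/(1 + beta); the
maximal-current phase shrinks to the single point alpha = beta = 1.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .meanfield import Phase, current_rs

__all__ = [
    "ClusterSolution",
    "pair_probabilities",
    "current_parallel",
    "boundary_densities_parallel",
    "extremal_current",
    "classify_phase_open_parallel",
]


@dataclasses.dataclass(frozen=True)
class ClusterSolution:
    """Pair probabilities and current of the two-site cluster closure.

    For the open chain, ``rho_left``/``rho_right`` are the effective densities
    at the extreme sites and ``label`` is the stationary phase; ``rho`` (and
    the pair probabilities) are None on the first-order coexistence line,
    where the bulk density is discontinuous.
    """

    rho: float | None
    P00: float | None
    P01: float | None
    P10: float | None
    P11: float | None
    J: float
    rho_left: float | None = None
    rho_right: float | None = None
    label: Phase | None = None


def _check_unit(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0,1]")


def pair_probabilities(rho: float) -> ClusterSolution:
    """Solve the two-site closure at bulk density rho.

    Of the two roots of the quadratic, the '-' root is the physical one: the
    '+' root exceeds min(rho, 1-rho) and would make P(11) or P(00) negative.
    """
    _check_unit(rho, "rho")
    rho = float(rho)
    disc = 1.0 - 4.0 * rho * (1.0 - rho)  # equals (1 - 2 rho)^2
    p10 = 0.5 * (1.0 - np.sqrt(max(disc, 0.0)))
    return ClusterSolution(
        rho=rho,
        P00=1.0 - rho - p10,
        P01=p10,
        P10=p10,
        P11=rho - p10,
        J=p10,
    )


def current_parallel(rho):
    """Parallel-update fundamental diagram J(rho) = min(rho, 1 - rho)."""
    _check_unit(rho, "rho")
    rho = np.asarray(rho, dtype=float)
    out = np.minimum(rho, 1.0 - rho)
    return float(out) if out.ndim == 0 else out


def boundary_densities_parallel(alpha: float, beta: float) -> tuple[float, float]:
    """Effective densities at the extreme sites: (alpha/(1+alpha), 1/(1+beta)).

    rho_left <= rho_right always, with equality exactly at alpha = beta = 1.
    """
    _check_unit(alpha, "alpha")
    _check_unit(beta, "beta")
    return alpha / (1.0 + alpha), 1.0 / (1.0 + beta)


#: fluxes with a known single maximum at rho = 1/2, handled in closed form
_UNIMODAL_FLUXES = (current_parallel, current_rs)


def extremal_current(
    rho_left: float,
    rho_right: float,
    flux: Callable = current_parallel,
    n_grid: int = 10_001,
) -> float:
    """Stationary current selected by the extremal principle.

    J = max of the flux over (rho_right, rho_left) when rho_right < rho_left,
    and min over (rho_left, rho_right) when rho_left < rho_right.  The two
    built-in fluxes are unimodal with peak at 1/2, so the extremum is taken in
    closed form; arbitrary fluxes fall back to a dense grid search.
    """
    _check_unit(rho_left, "rho_left")
    _check_unit(rho_right, "rho_right")
    if rho_left == rho_right:
        return float(flux(rho_left))
    lo, hi = min(rho_left, rho_right), max(rho_left, rho_right)
    maximise = rho_right < rho_left
    if flux in _UNIMODAL_FLUXES:
        f_lo, f_hi = float(flux(lo)), float(flux(hi))
        if maximise:
            return float(flux(0.5)) if lo <= 0.5 <= hi else max(f_lo, f_hi)
        return min(f_lo, f_hi)
    grid = np.linspace(lo, hi, n_grid)
    values = np.asarray([flux(g) for g in grid], dtype=float)
    return float(values.max() if maximise else values.min())


def classify_phase_open_parallel(alpha: float, beta: float) -> ClusterSolution:
    """Stationary phase of the open chain under the parallel rule.

    LD: rho = alpha/(1+alpha), J = rho for alpha < min(beta, 1); HD:
    rho = 1/(1+beta), J = 1 - rho for beta < min(alpha, 1); MC: rho = 1/2,
    J = 1/2 only at the single point alpha = beta = 1; alpha = beta < 1 is the
    first-order coexistence line.
    """
    _check_unit(alpha, "alpha")
    _check_unit(beta, "beta")
    rho_left, rho_right = boundary_densities_parallel(alpha, beta)
    if alpha < beta and alpha < 1.0:
        rho = rho_left
        label = Phase.LD
    elif beta < alpha and beta < 1.0:
        rho = rho_right
        label = Phase.HD
    elif alpha == beta == 1.0:
        rho = 0.5
        label = Phase.MC
    else:  # alpha == beta < 1: delocalised shock, discontinuous bulk density
        J = alpha / (1.0 + alpha)
        return ClusterSolution(
            rho=None, P00=None, P01=None, P10=None, P11=None, J=J,
            rho_left=rho_left, rho_right=rho_right, label=Phase.COEXISTENCE,
        )
    sol = pair_probabilities(rho)
    return dataclasses.replace(sol, rho_left=rho_left, rho_right=rho_right, label=label)
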