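"""One-site (naive) mean-field theory of the exclusion process.

Ignoring all correlations, the coarse-grained density obeys the conservation
law d(rho)/dt + d(J)/dx = 0 with flux J(rho) = rho(1 - rho).  This module
provides the fundamental diagram, the stationary phase diagram of the open
chain (low-density, high-density and maximal-current phases), the transient
solution of the Riemann problem with left state rho- = alpha and right state
rho+ = 1 - beta (a travelling shock when rho- < rho+, a rarefaction fan when
rho- > rho+), the asymptotic phase deduced from the wave dynamics, and the
phase line of the ring parameterised by the filling fraction n = N/L.

The initial discontinuity sits at x0 = 0.5 because the open chain is rescaled
to x in [0, 1]; it is configurable for generality.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

__all__ = [
    "Phase",
    "MeanFieldPhase",
    "current_rs",
    "classify_phase_open",
    "shock_speed",
    "riemann_density",
    "asymptotic_phase_from_waves",
    "periodic_phase",
]


class Phase(str, enum.Enum):
    LD = "LD"
    HD = "HD"
    MC = "MC"
    COEXISTENCE = "coexistence_line"


@dataclasses.dataclass(frozen=True)
class MeanFieldPhase:
    """Stationary phase of the mean-field solution.

    ``rho_bulk`` is None on the first-order coexistence line, where the bulk
    density is discontinuous (a delocalised shock separates an alpha- and a
    (1-beta)-density segment).  ``region`` labels the wave-dynamics region
    (I, II: shock; III, IV, V: rarefaction) when derived from the transient
    analysis.  ``on_boundary`` flags the second-order lines alpha = 1/2 <= beta
    and beta = 1/2 <= alpha, where the density is continuous and the point is
    resolved to the adjoining maximal-current value 1/2.
    """

    label: Phase
    rho_bulk: float | None
    J: float
    region: str | None = None
    on_boundary: bool = False


def _check_unit(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0,1]")


def current_rs(rho):
    """Mean-field (random-sequential) flux J(rho) = rho (1 - rho)."""
    _check_unit(rho, "rho")
    rho = np.asarray(rho, dtype=float)
    out = rho * (1.0 - rho)
    return float(out) if out.ndim == 0 else out


def classify_phase_open(alpha: float, beta: float) -> MeanFieldPhase:
    """Stationary phase of the open chain under one-site mean-field theory.

    LD with rho = alpha for alpha < min(beta, 1/2); HD with rho = 1 - beta for
    beta < min(alpha, 1/2); MC with rho = 1/2 for min(alpha, beta) > 1/2;
    the line alpha = beta < 1/2 is the first-order coexistence line.
    """
    _check_unit(alpha, "alpha")
    _check_unit(beta, "beta")
    if alpha < beta and alpha < 0.5:
        return MeanFieldPhase(Phase.LD, alpha, alpha * (1.0 - alpha))
    if beta < alpha and beta < 0.5:
        return MeanFieldPhase(Phase.HD, 1.0 - beta, beta * (1.0 - beta))
    if alpha > 0.5 and beta > 0.5:
        return MeanFieldPhase(Phase.MC, 0.5, 0.25)
    if alpha == beta and alpha < 0.5:
        return MeanFieldPhase(Phase.COEXISTENCE, None, alpha * (1.0 - alpha))
    # second-order lines alpha = 1/2 <= beta, beta = 1/2 <= alpha (density continuous)
    return MeanFieldPhase(Phase.MC, 0.5, 0.25, on_boundary=True)


def shock_speed(alpha: float, beta: float) -> float:
    """Rankine-Hugoniot speed s = beta - alpha of the travelling density step.

    Defined in the shock regime alpha < 1 - beta, where the left density
    alpha lies below the right density 1 - beta.
    """
    _check_unit(alpha, "alpha")
    _check_unit(beta, "beta")
    if not alpha < 1.0 - beta:
        raise ValueError(
            "shock regime requires alpha < 1 - beta; for alpha > 1 - beta the step "
            "relaxes into a rarefaction fan (see riemann_density)"
        )
    return beta - alpha


def riemann_density(alpha: float, beta: float, x, t: float, x0: float = 0.5):
    """Density field rho(x, t) of the Riemann problem with step (alpha, 1 - beta) at x0.

    Shock case (alpha < 1 - beta): the step translates rigidly at speed
    beta - alpha.  Rarefaction case (alpha > 1 - beta): a self-similar fan
    f(z) = (1 - z)/2, z = (x - x0)/t, interpolates between the edge
    characteristics x0 + (1 - 2 alpha) t and x0 + (1 - 2(1 - beta)) t.
    Degenerate case alpha = 1 - beta: constant profile.
    """
    _check_unit(alpha, "alpha")
    _check_unit(beta, "beta")
    if t < 0:
        raise ValueError("t must be >= 0")
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    if np.any(x_arr < 0.0) or np.any(x_arr > 1.0):
        raise ValueError("x must lie in [0,1] (rescaled lattice coordinate)")
    rho_m = alpha
    rho_p = 1.0 - beta
    if t == 0.0 or rho_m == rho_p:
        out = np.where(x_arr < x0, rho_m, rho_p)
    elif rho_m < rho_p:  # shock
        xs = x0 + (beta - alpha) * t
        out = np.where(x_arr < xs, rho_m, rho_p)
    else:  # rarefaction fan
        x_left = x0 + (1.0 - 2.0 * rho_m) * t
        x_right = x0 + (1.0 - 2.0 * rho_p) * t
        fan = 0.5 * (1.0 - (x_arr - x0) / t)
        out = np.where(x_arr <= x_left, rho_m, np.where(x_arr >= x_right, rho_p, fan))
    return float(out[0]) if scalar else out


def asymptotic_phase_from_waves(alpha: float, beta: float) -> MeanFieldPhase:
    """Long-time phase deduced from the fate of the transient wave.

    Regions I (shock moves right, density -> alpha) and II (shock moves left,
    density -> 1 - beta) cover alpha < 1 - beta; regions III (fan expelled
    right, -> alpha), IV (fan expelled left, -> 1 - beta) and V (fan keeps
    expanding, -> 1/2) cover alpha > 1 - beta.  Off the boundary lines the
    result coincides with :func:`classify_phase_open`.
    """
    _check_unit(alpha, "alpha")
    _check_unit(beta, "beta")
    if alpha < 1.0 - beta:
        if alpha < beta:
            return MeanFieldPhase(Phase.LD, alpha, alpha * (1 - alpha), region="I")
        if beta < alpha:
            return MeanFieldPhase(Phase.HD, 1 - beta, beta * (1 - beta), region="II")
        return MeanFieldPhase(Phase.COEXISTENCE, None, alpha * (1 - alpha), region="I")
    if alpha > 1.0 - beta:
        if alpha < 0.5:
            return MeanFieldPhase(Phase.LD, alpha, alpha * (1 - alpha), region="III")
        if beta < 0.5:
            return MeanFieldPhase(Phase.HD, 1 - beta, beta * (1 - beta), region="IV")
        if alpha > 0.5 and beta > 0.5:
            return MeanFieldPhase(Phase.MC, 0.5, 0.25, region="V")
        return MeanFieldPhase(Phase.MC, 0.5, 0.25, region="V", on_boundary=True)
    # degenerate line alpha = 1 - beta: zero-amplitude step, constant profile
    if alpha < 0.5:
        return MeanFieldPhase(Phase.LD, alpha, alpha * (1 - alpha), region="I")
    if alpha > 0.5:
        return MeanFieldPhase(Phase.HD, 1 - beta, beta * (1 - beta), region="II")
    return MeanFieldPhase(Phase.MC, 0.5, 0.25, region="V", on_boundary=True)


def periodic_phase(n: float) -> MeanFieldPhase:
    """Phase of the ring: density rho = n, current J = n(1 - n), phase set by n vs 1/2."""
    _check_unit(n, "n")
    J = n * (1.0 - n)
    if n < 0.5:
        return MeanFieldPhase(Phase.LD, float(n), J)
    if n > 0.5:
        return MeanFieldPhase(Phase.HD, float(n), J)
    return MeanFieldPhase(Phase.MC, 0.5, 0.25)
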