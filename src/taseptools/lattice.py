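"""Domain types and parameter validation shared by every component of the toolkit.

Conventions
-----------
Sites are numbered 1..L in documentation and figures; storage is 0-based and
implementation-internal.  Bond ``k`` denotes the pair of sites ``(k, k+1)``;
on a ring, bond ``L`` couples site ``L`` back to site ``1``.  The entry rate
``alpha`` and exit rate ``beta`` double as per-attempt probabilities in the
discrete Monte Carlo realisation, which is why both are restricted to
``[0, 1]``; bulk hops occur with unit rate.  Time is measured in units of the
inverse hop rate (one sweep of L random-sequential attempts, or one parallel
step, advances time by 1).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Any, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Boundary",
    "Update",
    "ParamError",
    "SystemParams",
    "LatticeState",
    "SimResult",
    "validate_params",
]


class Boundary(str, enum.Enum):
    """Boundary condition of the lattice."""

    OPEN = "open"
    PERIODIC = "periodic"


class Update(str, enum.Enum):
    """Microscopic update rule."""

    RANDOM_SEQUENTIAL = "random_sequential"
    PARALLEL = "parallel"


#: accepted spellings for CLI/config convenience
_UPDATE_ALIASES = {
    "rs": Update.RANDOM_SEQUENTIAL,
    "random": Update.RANDOM_SEQUENTIAL,
    "random-sequential": Update.RANDOM_SEQUENTIAL,
    "random_sequential": Update.RANDOM_SEQUENTIAL,
    "parallel": Update.PARALLEL,
}


class ParamError(ValueError):
    """Raised when a parameter set violates the model constraints."""


def _coerce_boundary(value: Any) -> Boundary:
    if isinstance(value, Boundary):
        return value
    try:
        return Boundary(str(value).strip().lower())
    except ValueError:
        raise ParamError(f"boundary must be 'open' or 'periodic', got {value!r}") from None


def _coerce_update(value: Any) -> Update:
    if isinstance(value, Update):
        return value
    key = str(value).strip().lower()
    if key in _UPDATE_ALIASES:
        return _UPDATE_ALIASES[key]
    raise ParamError(f"update must be 'random_sequential'/'rs' or 'parallel', got {value!r}")


@dataclasses.dataclass(frozen=True)
class SystemParams:
    """Definition of one lattice-gas experiment.

    Parameters
    ----------
    L:
        Number of lattice sites, ``L >= 1``.
    boundary:
        Open boundaries couple the chain to reservoirs of density ``alpha``
        (left) and ``1 - beta`` (right); periodic boundaries close the chain
        into a ring with a conserved particle number ``N``.
    update:
        Random-sequential (continuous-time realisation) or fully parallel
        (discrete-time) dynamics.
    alpha, beta:
        Entry/exit rates in ``[0, 1]``; ignored on a ring.
    N:
        Particle count, required (and only allowed) for periodic boundaries.
    """

    L: int
    boundary: Boundary = Boundary.OPEN
    update: Update = Update.RANDOM_SEQUENTIAL
    alpha: float = 0.0
    beta: float = 0.0
    N: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundary", _coerce_boundary(self.boundary))
        object.__setattr__(self, "update", _coerce_update(self.update))
        if not (isinstance(self.L, (int, np.integer)) and self.L >= 1):
            raise ParamError(f"L must be an integer >= 1, got {self.L!r}")
        object.__setattr__(self, "L", int(self.L))
        for name in ("alpha", "beta"):
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ParamError(f"{name} must be a number in [0,1], got {value!r}") from None
            if not 0.0 <= value <= 1.0:
                raise ParamError(f"{name} must lie in [0,1], got {value}")
            object.__setattr__(self, name, value)
        if self.boundary is Boundary.PERIODIC:
            if self.N is None:
                raise ParamError("N (particle count) is required for periodic boundaries")
            if not (isinstance(self.N, (int, np.integer)) and 0 <= int(self.N) <= self.L):
                raise ParamError(f"N must be an integer in [0, L={self.L}], got {self.N!r}")
            object.__setattr__(self, "N", int(self.N))
            if self.alpha != 0.0 or self.beta != 0.0:
                # one config template serves both boundary types
                logger.warning(
                    "periodic boundaries ignore alpha=%g, beta=%g", self.alpha, self.beta
                )
        else:
            if self.N is not None:
                raise ParamError("N is only meaningful for periodic boundaries; leave it unset")

    @property
    def n(self) -> float:
        """Filling fraction N/L (periodic boundaries only)."""
        if self.boundary is not Boundary.PERIODIC:
            raise ParamError("filling fraction n is defined only for periodic boundaries")
        return self.N / self.L

    @property
    def n_bonds(self) -> int:
        """Number of nearest-neighbour bonds (L on a ring, L-1 for an open chain)."""
        return self.L if self.boundary is Boundary.PERIODIC else self.L - 1

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "L": self.L,
            "boundary": self.boundary.value,
            "update": self.update.value,
            "alpha": self.alpha,
            "beta": self.beta,
        }
        if self.N is not None:
            d["N"] = self.N
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SystemParams":
        return validate_params(d)


_PARAM_KEYS = {"L", "alpha", "beta", "boundary", "update", "N"}
#: protocol keys that may ride along in a flat config mapping
_PROTOCOL_KEYS = {"steps", "burn_in_fraction", "burn_in", "seed", "out", "t", "grid",
                  "dt_factor", "tol", "max_steps", "x0"}


def validate_params(raw: Mapping[str, Any]) -> SystemParams:
    """Validate a flat parameter mapping and return a :class:`SystemParams`.

    Unknown keys raise :class:`ParamError`; protocol keys (``steps``, ``seed``,
    ...) are tolerated so one flat config can drive a whole run.
    """
    unknown = set(raw) - _PARAM_KEYS - _PROTOCOL_KEYS
    if unknown:
        raise ParamError(f"unknown parameter(s): {sorted(unknown)}")
    if "L" not in raw:
        raise ParamError("L (lattice length) is required")
    kwargs: dict[str, Any] = {"L": raw["L"]}
    for key in ("boundary", "update", "alpha", "beta", "N"):
        if key in raw and raw[key] is not None:
            kwargs[key] = raw[key]
    return SystemParams(**kwargs)


@dataclasses.dataclass
class LatticeState:
    """Microscopic configuration: binary occupations plus elapsed time."""

    tau: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.uint8)

    def validate(self, params: SystemParams | None = None) -> None:
        """Assert the hardcore-exclusion and conservation invariants."""
        if self.tau.ndim != 1:
            raise ValueError("tau must be a 1-D occupation vector")
        if not np.isin(self.tau, (0, 1)).all():
            raise ValueError("every occupation number must be 0 or 1")
        if params is not None:
            if self.tau.shape[0] != params.L:
                raise ValueError(f"state has {self.tau.shape[0]} sites, params say L={params.L}")
            if params.boundary is Boundary.PERIODIC and int(self.tau.sum()) != params.N:
                raise ValueError(
                    f"ring conservation violated: sum(tau)={int(self.tau.sum())} != N={params.N}"
                )

    def copy(self) -> "LatticeState":
        return LatticeState(self.tau.copy(), self.time)


@dataclasses.dataclass
class SimResult:
    """Stationary observables measured by a Monte Carlo run.

    Densities are per-site time averages ``<tau_i>``; bond currents count hops
    per unit time across each bond; ``pair`` holds ``<tau_i tau_{i+1}>`` per
    bond.  ``batch_*`` arrays hold batch means used for standard errors.
    """

    params: SystemParams
    rho: np.ndarray
    rho_se: np.ndarray
    J_bond: np.ndarray
    J_bond_se: np.ndarray
    pair: np.ndarray
    J_enter: float | None
    J_enter_se: float | None
    J_exit: float | None
    J_exit_se: float | None
    n_sweeps: int
    burn_in: int
    seed: int
    n_batches: int
    batch_rho: np.ndarray | None = None
    batch_J_bond: np.ndarray | None = None
    batch_pair: np.ndarray | None = None
    batch_J_enter: np.ndarray | None = None
    batch_J_exit: np.ndarray | None = None
    final_state: LatticeState | None = None

    @property
    def C_nn(self) -> np.ndarray:
        """Nearest-neighbour correlation ``<tau_i tau_{i+1}> - <tau_i><tau_{i+1}>``."""
        L = self.params.L
        nb = self.params.n_bonds
        right = self.rho[(np.arange(nb) + 1) % L]
        return self.pair - self.rho[:nb] * right

    @property
    def J_mean(self) -> float:
        """Spatial mean of the bond currents (the stationary current estimate)."""
        if self.J_bond.size == 0:
            # an open single-site chain has no bulk bond; fall back to entry
            return float(self.J_enter)
        return float(self.J_bond.mean())
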