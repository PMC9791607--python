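"""Exact stationary solution of the master equation on small lattices.

The full configuration space of 2^L occupation vectors is enumerated; each
configuration maps to an integer whose bit ``i`` is the occupation of site
``i+1``.  For random-sequential dynamics the continuous-time generator
``W[to, from]`` is assembled (columns sum to zero) and the stationary vector
solves ``W P = 0``.  For parallel dynamics the one-step row-stochastic matrix
``M[from, to]`` is assembled from the deterministic bulk moves and the
independent entry/exit events, and the stationary vector solves ``P M = P``
— for periodic (cyclic) chains that vector equals the long-run time average.

Both solvers restrict the problem to the recurrent class reached from a
reference configuration (the empty lattice for open boundaries, the densest
left-packed configuration for a ring), which also handles absorbing chains
such as ``alpha=1, beta=0``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .lattice import Boundary, SystemParams, Update

__all__ = [
    "ConfigurationSpace",
    "GeneratorMatrix",
    "ExactStationary",
    "OracleSizeError",
    "build_generator_rs",
    "build_transition_parallel",
    "stationary_observables",
]

DEFAULT_CAP = 12
_RESIDUAL_TOL = 1e-10


class OracleSizeError(ValueError):
    """Lattice too large for exact enumeration; use the Monte Carlo simulator."""


class ConfigurationSpace:
    """Bijection between occupation vectors of length L and integers 0..2^L-1."""

    def __init__(self, L: int):
        self.L = int(L)
        self.size = 1 << self.L

    def occupations(self, code: int) -> np.ndarray:
        """Occupation vector tau for an integer configuration code."""
        return (code >> np.arange(self.L)) & 1

    def index(self, tau) -> int:
        tau = np.asarray(tau, dtype=np.int64)
        return int((tau << np.arange(self.L)).sum())


def _rs_events(c: int, L: int, alpha: float, beta: float, periodic: bool):
    """(target, rate) pairs leaving configuration c under random-sequential dynamics."""
    events = []
    last = L if periodic else L - 1
    for i in range(last):
        j = (i + 1) % L
        if j == i:
            continue
        if (c >> i) & 1 and not (c >> j) & 1:
            events.append((c ^ (1 << i) ^ (1 << j), 1.0))
    if not periodic:
        if not c & 1 and alpha > 0.0:
            events.append((c | 1, alpha))
        if (c >> (L - 1)) & 1 and beta > 0.0:
            events.append((c & ~(1 << (L - 1)), beta))
    return events


def _parallel_outcomes(c: int, L: int, alpha: float, beta: float, periodic: bool):
    """(target, probability) pairs for one parallel step from configuration c."""
    moved = 0
    for i in range(L - 1):
        if (c >> i) & 1 and not (c >> (i + 1)) & 1:
            moved |= 1 << i
    if periodic and L > 1 and (c >> (L - 1)) & 1 and not c & 1:
        moved |= 1 << (L - 1)
    d = c
    for i in range(L):
        if (moved >> i) & 1:
            d &= ~(1 << i)
            d |= 1 << ((i + 1) % L)
    if periodic:
        return [(d, 1.0)]
    p_enter = alpha if not c & 1 else 0.0
    p_exit = beta if (c >> (L - 1)) & 1 else 0.0
    out: dict[int, float] = {}
    for e in (0, 1):
        pe = p_enter if e else 1.0 - p_enter
        if pe <= 0.0:
            continue
        for x in (0, 1):
            px = p_exit if x else 1.0 - p_exit
            if px <= 0.0:
                continue
            t = d
            if x:
                t &= ~(1 << (L - 1))
            if e:
                t |= 1
            out[t] = out.get(t, 0.0) + pe * px
    return list(out.items())


@dataclasses.dataclass
class GeneratorMatrix:
    """Transition structure restricted to the recurrent class, plus its stationary vector."""

    params: SystemParams
    kind: str  # "rs" (rate matrix W[to, from]) or "parallel" (stochastic M[from, to])
    states: np.ndarray  # integer codes of the recurrent class
    W: sp.csr_matrix
    P: np.ndarray  # stationary probabilities over `states`
    residual: float
    space: ConfigurationSpace

    def full_distribution(self) -> np.ndarray:
        """Stationary distribution over the full 2^L configuration space."""
        full = np.zeros(self.space.size)
        full[self.states] = self.P
        return full

    def probability(self, tau) -> float:
        """Stationary probability of one occupation vector."""
        code = self.space.index(tau)
        where = np.nonzero(self.states == code)[0]
        return float(self.P[where[0]]) if where.size else 0.0


def _start_config(params: SystemParams) -> int:
    if params.boundary is Boundary.OPEN:
        return 0
    return (1 << params.N) - 1  # N left-packed particles on the ring


def _recurrent_class(params: SystemParams, events):
    """BFS the reachable set from the reference configuration, keep its terminal SCC."""
    start = _start_config(params)
    reachable = {start}
    frontier = [start]
    edges: list[tuple[int, int, float]] = []
    while frontier:
        nxt = []
        for c in frontier:
            for t, w in events(c):
                edges.append((c, t, w))
                if t not in reachable:
                    reachable.add(t)
                    nxt.append(t)
        frontier = nxt
    codes = np.array(sorted(reachable), dtype=np.int64)
    idx = {int(c): k for k, c in enumerate(codes)}
    n = codes.size
    if edges:
        rows = np.array([idx[a] for a, _, _ in edges])
        cols = np.array([idx[b] for _, b, _ in edges])
        adj = sp.csr_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    else:
        adj = sp.csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    # terminal components have no edge leaving them
    terminal = np.ones(n_comp, dtype=bool)
    coo = adj.tocoo()
    for a, b in zip(labels[coo.row], labels[coo.col]):
        if a != b:
            terminal[a] = False
    terminal_ids = np.nonzero(terminal)[0]
    if terminal_ids.size != 1:
        raise ValueError(
            "no unique recurrent class reachable from the reference configuration; "
            f"found {terminal_ids.size} closed classes"
        )
    keep = labels == terminal_ids[0]
    return codes[keep]


def _solve_null(A: sp.spmatrix, n: int) -> np.ndarray:
    """Solve A p = 0 with sum(p) = 1 by replacing the first equation."""
    if n == 1:
        return np.ones(1)
    A = A.tolil(copy=True)
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    if n <= 2048:
        p = np.linalg.solve(A.toarray(), b)
    else:
        p = spsolve(A.tocsc(), b)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _check_size(params: SystemParams, cap: int) -> None:
    if params.L > cap:
        raise OracleSizeError(
            f"L={params.L} exceeds the exact-enumeration cap of {cap} "
            "(2^L configurations); use the Monte Carlo simulator instead"
        )


def build_generator_rs(params: SystemParams, cap: int = DEFAULT_CAP) -> GeneratorMatrix:
    """Assemble and solve the random-sequential rate matrix on the recurrent class."""
    if params.update is not Update.RANDOM_SEQUENTIAL:
        raise ValueError("params.update must be random_sequential")
    _check_size(params, cap)
    L, alpha, beta = params.L, params.alpha, params.beta
    periodic = params.boundary is Boundary.PERIODIC

    def events(c):
        return _rs_events(c, L, alpha, beta, periodic)

    codes = _recurrent_class(params, events)
    idx = {int(c): k for k, c in enumerate(codes)}
    n = codes.size
    rows, cols, vals = [], [], []
    for k, c in enumerate(codes):
        out = 0.0
        for t, w in events(int(c)):
            rows.append(idx[int(t)])
            cols.append(k)
            vals.append(w)
            out += w
        rows.append(k)
        cols.append(k)
        vals.append(-out)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    P = _solve_null(W, n)
    residual = float(np.abs(W @ P).max()) if n > 1 else 0.0
    return GeneratorMatrix(params, "rs", codes, W, P, residual, ConfigurationSpace(L))


def build_transition_parallel(params: SystemParams, cap: int = DEFAULT_CAP) -> GeneratorMatrix:
    """Assemble and solve the one-step parallel transition matrix on the recurrent class."""
    if params.update is not Update.PARALLEL:
        raise ValueError("params.update must be parallel")
    _check_size(params, cap)
    L, alpha, beta = params.L, params.alpha, params.beta
    periodic = params.boundary is Boundary.PERIODIC

    def events(c):
        return _parallel_outcomes(c, L, alpha, beta, periodic)

    codes = _recurrent_class(params, events)
    idx = {int(c): k for k, c in enumerate(codes)}
    n = codes.size
    rows, cols, vals = [], [], []
    for k, c in enumerate(codes):
        for t, p in events(int(c)):
            rows.append(k)
            cols.append(idx[int(t)])
            vals.append(p)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # stationary vector of M equals the Cesaro (cycle) average for periodic chains
    P = _solve_null((M.T - sp.identity(n, format="csr")).tocsr(), n)
    residual = float(np.abs(P @ M - P).max()) if n > 1 else 0.0
    return GeneratorMatrix(params, "parallel", codes, M, P, residual, ConfigurationSpace(L))


@dataclasses.dataclass
class ExactStationary:
    """Stationary expectations computed from an exact distribution."""

    rho: np.ndarray
    pair: np.ndarray  # <tau_i tau_{i+1}> per bond
    J_bond: np.ndarray  # <tau_i (1 - tau_{i+1})> per bond
    J_enter: float | None
    J_exit: float | None

    @property
    def C_nn(self) -> np.ndarray:
        nb = self.J_bond.shape[0]
        L = self.rho.shape[0]
        right = self.rho[(np.arange(nb) + 1) % L]
        return self.pair - self.rho[:nb] * right

    @property
    def current(self) -> float:
        if self.J_bond.size:
            return float(self.J_bond.mean())
        return float(self.J_enter)


def stationary_observables(gen: GeneratorMatrix) -> ExactStationary:
    """Site densities, bond currents and boundary currents under the stationary law.

    The hop probability/rate is 1, so for both update rules the bond current
    is ``<tau_i (1 - tau_{i+1})>``; the boundary currents are
    ``alpha <1 - tau_1>`` and ``beta <tau_L>``.
    """
    params = gen.params
    L = params.L
    occ = (gen.states[:, None] >> np.arange(L)) & 1  # (n_states, L)
    P = gen.P
    rho = P @ occ
    nb = params.n_bonds
    ks = np.arange(nb)
    right = occ[:, (ks + 1) % L]
    left = occ[:, ks]
    pair = P @ (left * right)
    J_bond = P @ (left * (1 - right))
    if params.boundary is Boundary.OPEN:
        J_enter = float(params.alpha * (P @ (1 - occ[:, 0])))
        J_exit = float(params.beta * (P @ occ[:, L - 1]))
    else:
        J_enter = J_exit = None
    if gen.residual > _RESIDUAL_TOL:
        raise RuntimeError(f"stationarity residual {gen.residual:g} exceeds {_RESIDUAL_TOL:g}")
    return ExactStationary(np.asarray(rho, float), np.asarray(pair, float),
                           np.asarray(J_bond, float), J_enter, J_exit)
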