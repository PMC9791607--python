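"""Kinetic Monte Carlo engine for the exclusion process.

Two update rules are implemented:

* random-sequential — at each elementary attempt a site is drawn uniformly
  and its allowed move (bulk hop with unit rate, entry with probability
  ``alpha``, exit with probability ``beta``) is executed; L attempts form one
  sweep and advance time by one unit.  This is the standard discrete-time
  realisation of the continuous-time process.
* parallel — all sites are updated simultaneously against the configuration
  at time t; one step advances time by one unit.  Injection into site 1 is
  forbidden if site 1 was occupied at t even when its particle departs in the
  same step.

Observables are sampled once per sweep; currents are event counts divided by
the measured time.  Standard errors come from batch means (20 batches by
default).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .lattice import Boundary, LatticeState, SimResult, SystemParams, Update

__all__ = [
    "init_state",
    "step_random_sequential",
    "step_parallel",
    "run_simulation",
    "measure_nn_correlation",
]


def init_state(params: SystemParams, rng: np.random.Generator | None = None) -> LatticeState:
    """Initial configuration: empty chain (open) or N particles placed uniformly (ring).

    For random-sequential ring dynamics the uniform placement is already the
    stationary measure, so no burn-in is strictly required there.
    """
    if params.boundary is Boundary.OPEN:
        return LatticeState(np.zeros(params.L, dtype=np.uint8))
    if rng is None:
        rng = np.random.default_rng()
    tau = np.zeros(params.L, dtype=np.uint8)
    occupied = rng.choice(params.L, size=params.N, replace=False)
    tau[occupied] = 1
    return LatticeState(tau)


def step_random_sequential(
    state: LatticeState, params: SystemParams, rng: np.random.Generator
) -> LatticeState:
    """One elementary random-sequential attempt; time advances by 1/L.

    Reference implementation of the update table; the production path is the
    compiled kernel, which applies the identical rules.
    """
    if params.update is not Update.RANDOM_SEQUENTIAL:
        raise ValueError("params.update must be random_sequential")
    new = state.copy()
    tau = new.tau
    L = params.L
    i = int(rng.integers(L))
    if params.boundary is Boundary.PERIODIC:
        j = (i + 1) % L
        if j != i and tau[i] == 1 and tau[j] == 0:
            tau[i] = 0
            tau[j] = 1
    else:
        if i == L - 1 and tau[i] == 1:
            if rng.random() < params.beta:
                tau[i] = 0
        elif i == 0 and tau[i] == 0:
            if rng.random() < params.alpha:
                tau[i] = 1
        elif i < L - 1 and tau[i] == 1 and tau[i + 1] == 0:
            tau[i] = 0
            tau[i + 1] = 1
    new.time += 1.0 / L
    new.validate(params)
    return new


def step_parallel(
    state: LatticeState, params: SystemParams, rng: np.random.Generator
) -> LatticeState:
    """One fully parallel step; all decisions read the time-t configuration."""
    if params.update is not Update.PARALLEL:
        raise ValueError("params.update must be parallel")
    old = state.tau
    L = params.L
    tau = old.copy()
    move = np.zeros(L, dtype=bool)
    move[: L - 1] = (old[: L - 1] == 1) & (old[1:] == 0)
    entered = exited = False
    if params.boundary is Boundary.PERIODIC:
        if L > 1 and old[L - 1] == 1 and old[0] == 0:
            move[L - 1] = True
    else:
        entered = old[0] == 0 and rng.random() < params.alpha
        exited = old[L - 1] == 1 and rng.random() < params.beta
    tau[move] = 0
    tau[(np.nonzero(move)[0] + 1) % L] = 1
    if exited:
        tau[L - 1] = 0
    if entered:
        tau[0] = 1
    new = LatticeState(tau, state.time + 1.0)
    new.validate(params)
    return new


def _batch_stats(acc: np.ndarray, sweeps: np.ndarray):
    """Means and batch-means standard errors from per-batch sums."""
    total = sweeps.sum()
    mean = acc.sum(axis=0) / total
    means = acc / sweeps[:, None] if acc.ndim == 2 else acc / sweeps
    nb = sweeps.shape[0]
    if nb >= 2:
        se = means.std(axis=0, ddof=1) / np.sqrt(nb)
    else:
        se = np.full_like(np.asarray(mean, dtype=float), np.nan)
    return mean, se, means


def run_simulation(
    params: SystemParams,
    n_sweeps: int,
    burn_in_fraction: float = 0.05,
    *,
    burn_in: int | None = None,
    seed: int = 0,
    n_batches: int = 20,
    initial: LatticeState | None = None,
    keep_batches: bool = True,
) -> SimResult:
    """Run the Monte Carlo protocol and return stationary observables.

    ``n_sweeps`` is the total number of sweeps including burn-in; by default
    the first 5% are discarded.  ``burn_in`` (a sweep count) overrides the
    fraction.  Identical ``(params, n_sweeps, burn_in, seed)`` replay
    bit-identically.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if burn_in is None:
        if not 0.0 <= burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        burn_in = int(round(burn_in_fraction * n_sweeps))
    if burn_in < 0 or burn_in >= n_sweeps:
        raise ValueError(
            f"burn-in of {burn_in} sweeps leaves no measured sweeps out of {n_sweeps}"
        )
    n_meas = n_sweeps - burn_in
    n_batches = max(1, min(n_batches, n_meas))

    rng = np.random.default_rng(seed)
    state = initial.copy() if initial is not None else init_state(params, rng)
    state.validate(params)
    # numba's PRNG takes a 32-bit seed; derive one deterministically
    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0] & 0x7FFFFFFF)

    periodic = params.boundary is Boundary.PERIODIC
    kernel = (
        _kernels.run_random_sequential
        if params.update is Update.RANDOM_SEQUENTIAL
        else _kernels.run_parallel
    )
    tau = state.tau.copy()
    rho_acc, pair_acc, hop_acc, enter_acc, exit_acc, sweeps = kernel(
        tau, params.alpha, params.beta, periodic, burn_in, n_meas, n_batches, kernel_seed
    )
    final = LatticeState(tau, float(n_sweeps))
    final.validate(params)

    nb_bonds = params.n_bonds
    rho, rho_se, rho_b = _batch_stats(rho_acc, sweeps)
    pair, _, pair_b = _batch_stats(pair_acc[:, :nb_bonds], sweeps)
    J_bond, J_bond_se, J_b = _batch_stats(hop_acc[:, :nb_bonds], sweeps)
    if periodic:
        J_enter = J_enter_se = J_exit = J_exit_se = None
        enter_b = exit_b = None
    else:
        J_enter, J_enter_se, enter_b = _batch_stats(enter_acc, sweeps)
        J_exit, J_exit_se, exit_b = _batch_stats(exit_acc, sweeps)
        J_enter, J_exit = float(J_enter), float(J_exit)
        J_enter_se, J_exit_se = float(J_enter_se), float(J_exit_se)

    return SimResult(
        params=params,
        rho=rho,
        rho_se=rho_se,
        J_bond=J_bond,
        J_bond_se=J_bond_se,
        pair=pair,
        J_enter=J_enter,
        J_enter_se=J_enter_se,
        J_exit=J_exit,
        J_exit_se=J_exit_se,
        n_sweeps=int(n_sweeps),
        burn_in=int(burn_in),
        seed=int(seed),
        n_batches=int(n_batches),
        batch_rho=rho_b if keep_batches else None,
        batch_J_bond=J_b if keep_batches else None,
        batch_pair=pair_b if keep_batches else None,
        batch_J_enter=enter_b if keep_batches else None,
        batch_J_exit=exit_b if keep_batches else None,
        final_state=final,
    )


def measure_nn_correlation(result: SimResult) -> np.ndarray:
    """Per-bond nearest-neighbour correlation ``C_i = <t_i t_{i+1}> - <t_i><t_{i+1}>``."""
    return result.C_nn
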