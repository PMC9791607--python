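"""Numba-compiled inner loops for the Monte Carlo engine and the FTCS solver.

The kernels accumulate observables into per-batch arrays so that the caller
can form batch-means standard errors.  All randomness comes from numba's
internal PRNG seeded once per call; a fixed seed therefore yields a
bit-identical trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_random_sequential(tau, alpha, beta, periodic, n_burn, n_meas, n_batches, seed):
    """Attempt-based random-sequential dynamics; one sweep = L attempts = 1 time unit.

    Returns per-batch sums: occupancy (n_batches, L), pair occupancy and hop
    counts (n_batches, n_bonds), entry/exit counts, and sweeps per batch.
    """
    L = tau.shape[0]
    n_bonds = L if periodic else L - 1
    width = n_bonds if n_bonds > 0 else 1
    rho_acc = np.zeros((n_batches, L))
    pair_acc = np.zeros((n_batches, width))
    hop_acc = np.zeros((n_batches, width))
    enter_acc = np.zeros(n_batches)
    exit_acc = np.zeros(n_batches)
    sweeps = np.zeros(n_batches)
    np.random.seed(seed)
    for s in range(n_burn + n_meas):
        measuring = s >= n_burn
        b = 0
        if measuring:
            b = (s - n_burn) * n_batches // n_meas
        for _ in range(L):
            i = np.random.randint(0, L)
            if periodic:
                j = i + 1
                if j == L:
                    j = 0
                if j != i and tau[i] == 1 and tau[j] == 0:
                    tau[i] = 0
                    tau[j] = 1
                    if measuring:
                        hop_acc[b, i] += 1.0
            else:
                if i == L - 1 and tau[i] == 1:
                    if np.random.random() < beta:
                        tau[i] = 0
                        if measuring:
                            exit_acc[b] += 1.0
                elif i == 0 and tau[i] == 0:
                    if np.random.random() < alpha:
                        tau[i] = 1
                        if measuring:
                            enter_acc[b] += 1.0
                elif i < L - 1 and tau[i] == 1 and tau[i + 1] == 0:
                    tau[i] = 0
                    tau[i + 1] = 1
                    if measuring:
                        hop_acc[b, i] += 1.0
        if measuring:
            sweeps[b] += 1.0
            for i in range(L):
                rho_acc[b, i] += tau[i]
            for k in range(n_bonds):
                j = k + 1
                if j == L:
                    j = 0
                pair_acc[b, k] += tau[k] * tau[j]
    return rho_acc, pair_acc, hop_acc, enter_acc, exit_acc, sweeps


@njit(cache=True)
def run_parallel(tau, alpha, beta, periodic, n_burn, n_meas, n_batches, seed):
    """Fully parallel dynamics; every decision reads the configuration at time t.

    A site vacated during a step cannot be entered in the same step: movers
    require an empty target at time t, injection requires site 1 empty at t.
    """
    L = tau.shape[0]
    n_bonds = L if periodic else L - 1
    width = n_bonds if n_bonds > 0 else 1
    rho_acc = np.zeros((n_batches, L))
    pair_acc = np.zeros((n_batches, width))
    hop_acc = np.zeros((n_batches, width))
    enter_acc = np.zeros(n_batches)
    exit_acc = np.zeros(n_batches)
    sweeps = np.zeros(n_batches)
    move = np.zeros(L, np.uint8)
    np.random.seed(seed)
    for s in range(n_burn + n_meas):
        for i in range(L):
            move[i] = 0
        for i in range(L - 1):
            if tau[i] == 1 and tau[i + 1] == 0:
                move[i] = 1
        entered = False
        exited = False
        if periodic:
            if L > 1 and tau[L - 1] == 1 and tau[0] == 0:
                move[L - 1] = 1
        else:
            if tau[0] == 0 and np.random.random() < alpha:
                entered = True
            if tau[L - 1] == 1 and np.random.random() < beta:
                exited = True
        for i in range(L):
            if move[i] == 1:
                tau[i] = 0
        for i in range(L):
            if move[i] == 1:
                j = i + 1
                if j == L:
                    j = 0
                tau[j] = 1
        if exited:
            tau[L - 1] = 0
        if entered:
            tau[0] = 1
        if s >= n_burn:
            b = (s - n_burn) * n_batches // n_meas
            sweeps[b] += 1.0
            for k in range(n_bonds):
                hop_acc[b, k] += move[k]
            if entered:
                enter_acc[b] += 1.0
            if exited:
                exit_acc[b] += 1.0
            for i in range(L):
                rho_acc[b, i] += tau[i]
            for k in range(n_bonds):
                j = k + 1
                if j == L:
                    j = 0
                pair_acc[b, k] += tau[k] * tau[j]
    return rho_acc, pair_acc, hop_acc, enter_acc, exit_acc, sweeps


@njit(cache=True)
def run_ftcs(rho, alpha, beta, dt, dx, eps, tol, max_steps, check_bounds):
    """Iterate the explicit scheme until max|drho|/dt < tol or max_steps.

    Returns (steps done, final residual, bounds_ok flag).
    """
    L = rho.shape[0]
    new = np.empty(L)
    a = eps * dt / (2.0 * dx * dx)
    c = dt / (2.0 * dx)
    steps = 0
    res = np.inf
    ok = True
    while steps < max_steps:
        new[0] = rho[0] + dt * (alpha * (1.0 - rho[0]) - rho[0] * (1.0 - rho[1]))
        new[L - 1] = rho[L - 1] + dt * (rho[L - 2] * (1.0 - rho[L - 1]) - beta * rho[L - 1])
        for i in range(1, L - 1):
            new[i] = (
                rho[i]
                + a * (rho[i + 1] - 2.0 * rho[i] + rho[i - 1])
                + c * (rho[i + 1] - rho[i - 1]) * (2.0 * rho[i] - 1.0)
            )
        d = 0.0
        for i in range(L):
            di = abs(new[i] - rho[i])
            if di > d:
                d = di
            rho[i] = new[i]
            if check_bounds and (rho[i] < 0.0 or rho[i] > 1.0):
                ok = False
        steps += 1
        res = d / dt
        if not ok:
            break
        if res < tol:
            break
    return steps, res, ok
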