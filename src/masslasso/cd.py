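"""Cyclic coordinate descent with covariance updates, active sets and
warm starts, run independently per voxel.

The coordinate update for predictor j at penalty lam is

    beta_j <- S( c_j - sum_{k != j, beta_k != 0} C_jk beta_k , lam )

with unit denominator because the Gram diagonal is 1 on a z-scored
design.  The gradient term is assembled on demand from rows of the
precomputed Gram matrix restricted to the currently nonzero coordinates
("covariance updates"): no residual vector is ever maintained.

Sweep schedule per voxel and lambda:

1. one full sweep over all p coordinates;
2. repeated sweeps over the active set (coordinates ever set nonzero)
   until the max absolute coordinate change in a sweep < tol_value;
3. one more full sweep; if it activates a new coordinate or moves any
   coordinate by >= tol_value, return to 2, otherwise converged.

One "iteration" is one sweep (full or active-set); n_iter_max bounds the
total number of sweeps per voxel per lambda.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MSG_BUFFER_OVERFLOW,
    MSG_MAX_ITER,
    BufferOverflowError,
    ConvergenceError,
    compute_crossproducts,
    compute_gram,
    compute_intercepts,
    soft_threshold,
    validate_design,
    validate_lambda_sequence,
)
from .results import LassoPathResults, SparseBetaSet, convert_betas_full_to_sparse

__all__ = ["CDOptions", "CDVoxelState", "cd_solve_voxel", "cd_solve_path", "resolve_worker_count"]


@dataclass(frozen=True)
class CDOptions:
    """Technical parameters of the coordinate-descent solver.

    n_iter_max : sweep budget per voxel per lambda (default 1e5)
    tol_value : stopping threshold on max |beta_new - beta_old| per sweep,
        on the standardized-coefficient scale (default 1e-3)
    buffer_factor : sparse output capacity is ceil(buffer_factor * n)
        nonzeros per voxel (default 3)
    cpu_load_factor : fraction of CPU cores to engage, in [0, 1]
        (default 1 = all cores; 0 = a single core)
    """

    n_iter_max: int = 100_000
    tol_value: float = 1e-3
    buffer_factor: float = 3.0
    cpu_load_factor: float = 1.0

    def __post_init__(self):
        if self.n_iter_max < 1:
            raise ValueError("n_iter_max must be a positive integer")
        if self.tol_value <= 0:
            raise ValueError("tol_value must be positive")
        if self.buffer_factor <= 0:
            raise ValueError("buffer_factor must be positive")
        if not 0.0 <= self.cpu_load_factor <= 1.0:
            raise ValueError("cpu_load_factor must lie in [0, 1]")


@dataclass
class CDVoxelState:
    """Converged (or aborted) state of a single voxel's fit."""

    beta: np.ndarray
    active_flags: np.ndarray
    iterations_used: int
    converged: bool


def resolve_worker_count(cpu_load_factor: float, available_cores: int | None = None) -> int:
    """max(1, floor(cpu_load_factor * available_cores)).

    1.0 engages all cores, 0.0 a single core, 0.99 all but one.  Voxel
    fits are independent, so results do not depend on the worker count.
    """
    if available_cores is None:
        available_cores = os.cpu_count() or 1
    return max(1, int(np.floor(cpu_load_factor * available_cores)))


def _sweep(C, c, lam, beta, active, coords, capacity):
    """One sweep over `coords`; returns (max_change, n_activated).

    Updates beta and the ever-active flag vector in place.  Raises
    BufferOverflowError as soon as the nonzero count would exceed the
    sparse-buffer capacity.
    """
    max_change = 0.0
    activated = 0
    for j in coords:
        bj = beta[j]
        nz = np.flatnonzero(beta)
        g = c[j] - C[j, nz] @ beta[nz] + bj  # add back the k=j term
        new = soft_threshold(g, lam)
        if new != bj:
            was_zero = bj == 0.0
            beta[j] = new
            if new != 0.0 and was_zero:
                if not active[j]:
                    activated += 1
                    active[j] = True
                if np.count_nonzero(beta) > capacity:
                    raise BufferOverflowError(MSG_BUFFER_OVERFLOW)
            change = abs(new - bj)
            if change > max_change:
                max_change = change
    return max_change, activated


def cd_solve_voxel(C, c_v, lam, init=None, opts: CDOptions | None = None,
                   capacity: int | None = None, trace: list | None = None) -> CDVoxelState:
    """Fit one voxel at one lambda by cyclic coordinate descent.

    Parameters
    ----------
    C : (p, p) Gram matrix of a z-scored design (unit diagonal).
    c_v : (p,) cross-product column (1/n) X'y for this voxel.
    lam : non-negative penalty.
    init : optional warm-start coefficient vector (copied), zeros if None.
    capacity : sparse-buffer capacity; None disables the overflow check
        (used when n is unknown at this level).
    trace : optional list; when given, the Gram-space objective
        0.5 b'Cb - c'b + lam ||b||_1 is appended after every coordinate
        update (instrumentation for monotonicity checks on small runs).

    Raises
    ------
    ConvergenceError
        If n_iter_max sweeps are exhausted before convergence.
    BufferOverflowError
        If the nonzero count exceeds `capacity`.
    """
    opts = opts or CDOptions()
    C = np.asarray(C, dtype=np.float64)
    c = np.asarray(c_v, dtype=np.float64).ravel()
    p = c.shape[0]
    beta = np.zeros(p) if init is None else np.array(init, dtype=np.float64).copy()
    active = beta != 0.0
    if capacity is None:
        capacity = p
    if np.count_nonzero(beta) > capacity:
        raise BufferOverflowError(MSG_BUFFER_OVERFLOW)

    tol = opts.tol_value
    all_coords = np.arange(p)
    sweeps = 0

    def run_sweep(coords):
        nonlocal sweeps
        if sweeps >= opts.n_iter_max:
            raise ConvergenceError(MSG_MAX_ITER)
        sweeps += 1
        if trace is None:
            return _sweep(C, c, lam, beta, active, coords, capacity)
        return _traced_sweep(C, c, lam, beta, active, coords, capacity, trace)

    # (1) opening full sweep
    run_sweep(all_coords)
    while True:
        # (2) active-set sweeps to convergence
        while True:
            act = np.flatnonzero(active)
            if act.size == 0:
                break
            change, _ = run_sweep(act)
            if change < tol:
                break
        # (3) closing full sweep: admit newcomers
        change, activated = run_sweep(all_coords)
        if activated == 0 and change < tol:
            return CDVoxelState(beta=beta, active_flags=active,
                                iterations_used=sweeps, converged=True)


def _traced_sweep(C, c, lam, beta, active, coords, capacity, trace):
    """Like _sweep but records the Gram-space objective after each update."""
    max_change = 0.0
    activated = 0
    for j in coords:
        bj = beta[j]
        nz = np.flatnonzero(beta)
        g = c[j] - C[j, nz] @ beta[nz] + bj
        new = soft_threshold(g, lam)
        if new != bj:
            was_zero = bj == 0.0
            beta[j] = new
            if new != 0.0 and was_zero:
                if not active[j]:
                    activated += 1
                    active[j] = True
                if np.count_nonzero(beta) > capacity:
                    raise BufferOverflowError(MSG_BUFFER_OVERFLOW)
            max_change = max(max_change, abs(new - bj))
        trace.append(0.5 * beta @ C @ beta - c @ beta + lam * np.abs(beta).sum())
    return max_change, activated


def _solve_voxel_path(C, c_v, lambdas, opts, capacity):
    """Warm-started path for one voxel; returns (betas list, iters, conv)."""
    p = c_v.shape[0]
    beta = np.zeros(p)
    betas, iters, conv = [], [], []
    for lam in lambdas:
        state = cd_solve_voxel(C, c_v, lam, init=beta, opts=opts, capacity=capacity)
        beta = state.beta
        betas.append(beta.copy())
        iters.append(state.iterations_used)
        conv.append(state.converged)
    return betas, iters, conv


def cd_solve_path(X, Y, lambda_seq, opts: CDOptions | None = None,
                  n_workers: int | None = None) -> LassoPathResults:
    """Fit the full lambda path for every voxel.

    Each voxel is fitted independently along the lambda sequence with
    warm starts (the first lambda starts from zero).  Voxels are
    partitioned across workers resolved from cpu_load_factor; results
    are bitwise independent of the worker count.
    """
    opts = opts or CDOptions()
    X = validate_design(X)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    lambdas = validate_lambda_sequence(lambda_seq)
    n, p = X.shape
    v = Y.shape[1]
    if (lambdas == 0).any() and p > n:
        raise ValueError(
            "lambda = 0 is not allowed when p > n: the unregularized "
            "overparameterized fit is non-unique; use a positive lambda"
        )
    capacity = int(np.ceil(opts.buffer_factor * n))

    C = compute_gram(X)
    cp = compute_crossproducts(X, Y)
    intercepts = compute_intercepts(Y)

    if n_workers is None:
        n_workers = resolve_worker_count(opts.cpu_load_factor)

    if n_workers == 1 or v == 1:
        per_voxel = [_solve_voxel_path(C, cp[:, j], lambdas, opts, capacity)
                     for j in range(v)]
    else:
        from joblib import Parallel, delayed

        per_voxel = Parallel(n_jobs=n_workers, prefer="processes")(
            delayed(_solve_voxel_path)(C, cp[:, j], lambdas, opts, capacity)
            for j in range(v)
        )

    n_lam = lambdas.size
    iterations = np.array([pv[1] for pv in per_voxel], dtype=np.int64).T  # n_lam x v
    converged = np.array([pv[2] for pv in per_voxel], dtype=bool).T
    per_lambda = []
    for li in range(n_lam):
        dense = np.column_stack([per_voxel[j][0][li] for j in range(v)])
        sb = convert_betas_full_to_sparse(dense)
        if (sb.counts > capacity).any():
            raise BufferOverflowError(MSG_BUFFER_OVERFLOW)
        per_lambda.append(sb)

    return LassoPathResults(
        lambdas=lambdas,
        per_lambda=per_lambda,
        intercepts=intercepts,
        iterations=iterations,
        converged=converged,
        meta={
            "n": n, "p": p, "v": v,
            "solver": "cd",
            "options": {
                "n_iter_max": opts.n_iter_max,
                "tol_value": opts.tol_value,
                "buffer_factor": opts.buffer_factor,
                "cpu_load_factor": opts.cpu_load_factor,
            },
        },
    )
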