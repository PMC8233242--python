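"""Batched ADMM lasso solver: all coefficients of a block of voxels are
updated simultaneously via matrix products.

ADMM splits the lasso into a quadratic block, a soft-thresholding block
and a dual update.  With C = (1/n) X'X and c the cross-product block,
each iteration performs, for the whole batch at once:

    B <- (C + rho I)^-1 (c + rho (Z - U))
    Z <- S(B + U, lam / rho)        (elementwise; returned estimate)
    U <- U + B - Z

The p x p system matrix is factorized once per design and reused across
batches, iterations and lambdas.  When the design is overparameterized
(p > n) the matrix-inversion lemma turns the solve into an n x n one:

    (C + rho I)^-1 = (1/rho) (I - X' (n rho I + X X')^-1 X).

A batch stops when, for every voxel, both the dual movement
max |Z_new - Z_old| and the primal residual max |B - Z| drop below
tol_value; converged voxels' columns are frozen while the rest keep
iterating.  (The dual movement alone is not a safe stopping rule: Z can
sit still — e.g. pinned at zero early on — while B and U are far from
the fixed point.)
Coefficient and intercept outputs are downcast to single precision
(the GPU heritage of this algorithm); iterates are double by default,
with a switch to iterate fully in single precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core import (
    MSG_MAX_ITER,
    ConvergenceError,
    compute_crossproducts,
    compute_gram,
    compute_intercepts,
    soft_threshold,
    validate_design,
    validate_lambda_sequence,
)
from .results import LassoPathResults, convert_betas_full_to_sparse

__all__ = ["ADMMOptions", "ADMMFactorization", "ADMMBatchState",
           "admm_prepare", "admm_solve_batch", "admm_solve_path"]


@dataclass(frozen=True)
class ADMMOptions:
    """Technical parameters of the batched ADMM solver.

    n_iter_max : iteration budget per batch per lambda (default 1e5)
    tol_value : stopping threshold on max |Z_new - Z_old| (default 1e-3)
    buffer_size : voxels processed simultaneously per batch (default 8192)
    rho : augmented-Lagrangian penalty; fixed so the factorization can be
        cached (default 1.0)
    single_precision : iterate fully in float32 instead of only
        downcasting the outputs (default False)
    """

    n_iter_max: int = 100_000
    tol_value: float = 1e-3
    buffer_size: int = 8192
    rho: float = 1.0
    single_precision: bool = False

    def __post_init__(self):
        if self.n_iter_max < 1:
            raise ValueError("n_iter_max must be a positive integer")
        if self.tol_value <= 0:
            raise ValueError("tol_value must be positive")
        if self.buffer_size < 1:
            raise ValueError("buffer_size must be a positive integer")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class ADMMFactorization:
    """Cached triangular factorization of the quadratic-block system.

    branch is "underparameterized" (factor of C + rho I, p x p) when
    p <= n, else "overparameterized" (factor of n rho I + X X', n x n,
    applied through the matrix-inversion lemma).
    """

    branch: str
    factor: tuple
    rho: float
    X: np.ndarray | None  # kept only on the overparameterized branch
    n: int
    p: int

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Apply (C + rho I)^-1 to a p x b right-hand side."""
        if self.branch == "underparameterized":
            return cho_solve(self.factor, rhs)
        # Woodbury: (1/rho) (rhs - X' K^-1 X rhs), K = n rho I + X X'
        Xr = self.X @ rhs
        return (rhs - self.X.T @ cho_solve(self.factor, Xr)) / self.rho


@dataclass
class ADMMBatchState:
    """The (B, Z, U) ADMM triple for one batch of voxels.

    Z carries the sparse coefficient estimate; B the quadratic-block
    iterate; U the scaled dual.
    """

    B: np.ndarray
    Z: np.ndarray
    U: np.ndarray
    iterations_used: int
    converged_mask: np.ndarray


def admm_prepare(X, rho: float = 1.0) -> ADMMFactorization:
    """Factorize the quadratic-block system once for a given design.

    Chooses the p x p or the n x n (Woodbury) branch depending on
    whether the design is overparameterized.  For rho > 0 the system is
    positive definite, so a factorization failure signals corrupted
    input rather than a mathematical degeneracy.
    """
    X = validate_design(X)
    if rho <= 0:
        raise ValueError("rho must be positive")
    n, p = X.shape
    if p <= n:
        M = compute_gram(X) + rho * np.eye(p)
        return ADMMFactorization("underparameterized", cho_factor(M), rho, None, n, p)
    K = n * rho * np.eye(n) + X @ X.T
    return ADMMFactorization("overparameterized", cho_factor(K), rho, X.copy(), n, p)


def admm_solve_batch(fac: ADMMFactorization, c_batch, lam, init: ADMMBatchState | None = None,
                     opts: ADMMOptions | None = None) -> ADMMBatchState:
    """Run ADMM to convergence for one batch of voxels at one lambda.

    Raises
    ------
    ConvergenceError
        If any voxel in the batch is unconverged after n_iter_max
        iterations.
    """
    opts = opts or ADMMOptions()
    dtype = np.float32 if opts.single_precision else np.float64
    c = np.asarray(c_batch, dtype=dtype)
    if c.ndim == 1:
        c = c[:, None]
    p, b = c.shape
    if b > opts.buffer_size:
        raise ValueError(f"batch of {b} voxels exceeds buffer_size={opts.buffer_size}")
    rho = fac.rho
    if init is None:
        B = np.zeros((p, b), dtype=dtype)
        Z = np.zeros((p, b), dtype=dtype)
        U = np.zeros((p, b), dtype=dtype)
    else:
        B = init.B.astype(dtype).copy()
        Z = init.Z.astype(dtype).copy()
        U = init.U.astype(dtype).copy()

    pending = np.arange(b)
    converged = np.zeros(b, dtype=bool)
    thresh = lam / rho
    for it in range(1, opts.n_iter_max + 1):
        rhs = c[:, pending] + rho * (Z[:, pending] - U[:, pending])
        Bp = fac.solve(rhs).astype(dtype, copy=False)
        Zp = soft_threshold(Bp + U[:, pending], thresh).astype(dtype, copy=False)
        change = np.max(np.abs(Zp - Z[:, pending]), axis=0)
        Up = U[:, pending] + Bp - Zp
        B[:, pending] = Bp
        Z[:, pending] = Zp
        U[:, pending] = Up
        # Z_new - Z_old is (1/rho times) the dual residual; B - Z is the
        # primal residual.  Both must be small before a voxel is frozen:
        # the dual residual alone can vanish far from the optimum (e.g.
        # Z pinned at 0 on early iterations while B and U still move).
        primal = np.max(np.abs(Bp - Zp), axis=0)
        done = (change < opts.tol_value) & (primal < opts.tol_value)
        if done.any():
            converged[pending[done]] = True
            pending = pending[~done]
        if pending.size == 0:
            return ADMMBatchState(B=B, Z=Z, U=U, iterations_used=it,
                                  converged_mask=converged)
    raise ConvergenceError(MSG_MAX_ITER)


def admm_solve_path(X, Y, lambda_seq, opts: ADMMOptions | None = None) -> LassoPathResults:
    """Fit the full lambda path for every voxel with the batched ADMM.

    Voxels are split into consecutive batches of at most buffer_size.
    Within a batch, lambdas are fitted in sequence order with the whole
    (B, Z, U) triple carried across as warm start.  Coefficient and
    intercept outputs are stored in single precision; batching has no
    effect on results beyond that resolution.
    """
    opts = opts or ADMMOptions()
    X = validate_design(X)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    lambdas = validate_lambda_sequence(lambda_seq)
    n, p = X.shape
    v = Y.shape[1]

    fac = admm_prepare(X, rho=opts.rho)
    cp = compute_crossproducts(X, Y)
    intercepts = compute_intercepts(Y).astype(np.float32)

    n_lam = lambdas.size
    dense_paths = [np.zeros((p, v), dtype=np.float32) for _ in range(n_lam)]
    iterations = np.zeros((n_lam, v), dtype=np.int64)
    converged = np.zeros((n_lam, v), dtype=bool)

    for start in range(0, v, opts.buffer_size):
        stop = min(start + opts.buffer_size, v)
        state = None
        for li, lam in enumerate(lambdas):
            try:
                state = admm_solve_batch(fac, cp[:, start:stop], lam,
                                         init=state, opts=opts)
            except ConvergenceError as err:
                raise ConvergenceError(
                    f"{err} (batch voxels {start}:{stop}, lambda={lam!r})"
                ) from err
            dense_paths[li][:, start:stop] = state.Z.astype(np.float32)
            iterations[li, start:stop] = state.iterations_used
            converged[li, start:stop] = state.converged_mask

    per_lambda = [convert_betas_full_to_sparse(d) for d in dense_paths]
    return LassoPathResults(
        lambdas=lambdas,
        per_lambda=per_lambda,
        intercepts=intercepts[None, :] if intercepts.ndim == 1 else intercepts,
        iterations=iterations,
        converged=converged,
        meta={
            "n": n, "p": p, "v": v,
            "solver": "admmbatch",
            "options": {
                "n_iter_max": opts.n_iter_max,
                "tol_value": opts.tol_value,
                "buffer_size": opts.buffer_size,
                "rho": opts.rho,
                "single_precision": opts.single_precision,
            },
        },
    )
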