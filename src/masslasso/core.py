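"""Shared mathematical substrate for the mass-univariate lasso solvers.

The model, per response series (voxel) j, is

    minimize over (B_j, B0_j):  (1/2n) ||Y_j - X B_j - 1 B0_j||_2^2 + lam ||B_j||_1

with the columns of the design matrix X z-scored in the population sense:
column mean 0 and (1/n) sum x_i^2 = 1 (divisor n, not n-1).  Because X is
column-centered and the intercept is unpenalized, the intercept of the
penalized optimum is exactly the column mean of Y for every lam, and the
coefficient problem separates from it.  Both solvers therefore work purely
on the Gram matrix C = (1/n) X'X and the cross-products c = (1/n) X'Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardizationError",
    "ConvergenceError",
    "BufferOverflowError",
    "MSG_MAX_ITER",
    "MSG_BUFFER_OVERFLOW",
    "ScalingReport",
    "StandardizationReport",
    "zscore_columns",
    "check_standardized",
    "validate_design",
    "validate_lambda_sequence",
    "compute_gram",
    "compute_crossproducts",
    "compute_intercepts",
    "calculate_lambda_start",
    "calculate_lambda_start_per_voxel",
    "soft_threshold",
    "objective_value",
]

# Exact error strings of the original estimator's two hard failures.
MSG_MAX_ITER = "Max. iter. reached, no convergence!"
MSG_BUFFER_OVERFLOW = "N_nz over maximum, larger buffer is required!"

# z-scoring tolerances: centering is checked relative to n, the second
# moment absolutely; both intentionally loose enough for float32 input.
_CENTER_TOL = 1e-8
_MOMENT_TOL = 1e-6


class StandardizationError(ValueError):
    """Design matrix does not satisfy the z-scoring contract."""


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted before the stopping rule was met."""


class BufferOverflowError(RuntimeError):
    """A voxel's nonzero count exceeded the preallocated sparse buffer."""


@dataclass(frozen=True)
class ScalingReport:
    """Per-column centering/scaling applied by :func:`zscore_columns`.

    ``scale`` is the population standard deviation (divisor n), so a
    coefficient ``b`` on the standardized scale corresponds to
    ``b / scale[j]`` on the original scale of predictor j.
    """

    mean: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class StandardizationReport:
    """Pass/fail report of the z-scoring checks, per column."""

    centered_ok: np.ndarray      # bool, length p
    unit_moment_ok: np.ndarray   # bool, length p
    column_means: np.ndarray
    column_moments: np.ndarray   # (1/n) sum x^2 per column

    @property
    def all_ok(self) -> bool:
        return bool(self.centered_ok.all() and self.unit_moment_ok.all())

    def failing_columns(self) -> np.ndarray:
        return np.flatnonzero(~(self.centered_ok & self.unit_moment_ok))


def _as_2d_float(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite entries")
    return a


def zscore_columns(raw_design) -> tuple[np.ndarray, ScalingReport]:
    """Z-score the columns of a raw design matrix with divisor n.

    Returns the standardized matrix (mean 0, population second moment 1
    per column) and a :class:`ScalingReport` for mapping coefficients back
    to the original predictor units.

    Raises
    ------
    ValueError
        If any column is constant (a constant column cannot be z-scored
        and would act as an intercept, which must stay out of X), or if
        the input has non-finite entries or fewer than 2 rows.
    """
    X = _as_2d_float(raw_design, "design matrix")
    n = X.shape[0]
    if n < 2:
        raise ValueError("design matrix needs at least 2 rows to z-score")
    mean = X.mean(axis=0)
    centered = X - mean
    # population sd, divisor n
    scale = np.sqrt(np.mean(centered ** 2, axis=0))
    constant = np.flatnonzero(scale == 0)
    if constant.size:
        raise ValueError(
            f"column {constant[0]} is constant and cannot be z-scored "
            "(an intercept column must not be part of the design)"
        )
    return centered / scale, ScalingReport(mean=mean, scale=scale)


def check_standardized(X) -> StandardizationReport:
    """Report, per column, whether X meets the z-scoring contract.

    Pure report; raises nothing.  Solver entry points call this through
    :func:`validate_design` and refuse non-conforming input.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    means = X.mean(axis=0)
    moments = np.mean(X ** 2, axis=0)
    centered_ok = np.abs(means * n) <= _CENTER_TOL * n
    unit_moment_ok = np.abs(moments - 1.0) <= _MOMENT_TOL
    # an intercept-like (constant) column fails both checks outright,
    # even when its raw second moment happens to be 1 (e.g. all ones)
    constant = np.var(X, axis=0) <= _MOMENT_TOL ** 2
    centered_ok &= ~constant
    unit_moment_ok &= ~constant
    return StandardizationReport(
        centered_ok=centered_ok,
        unit_moment_ok=unit_moment_ok,
        column_means=means,
        column_moments=moments,
    )


def validate_design(X) -> np.ndarray:
    """Validate X against the z-scoring contract, raising on failure."""
    X = _as_2d_float(X, "design matrix X")
    report = check_standardized(X)
    if not report.all_ok:
        j = int(report.failing_columns()[0])
        raise StandardizationError(
            "The columns of the design matrix X must be z-scored "
            "(mean 0, (1/n)*sum(x^2) = 1) and X must not contain an "
            f"intercept column; column {j} fails "
            f"(mean={report.column_means[j]:.3g}, "
            f"second moment={report.column_moments[j]:.6g})."
        )
    return X


def validate_lambda_sequence(lambda_seq) -> np.ndarray:
    """Coerce a lambda sequence; warn (not error) if it is not decreasing.

    Warm starts only pay off along a decreasing sequence, but a
    non-monotone sequence is still a valid request and is fitted in the
    given order.
    """
    lam = np.atleast_1d(np.asarray(lambda_seq, dtype=np.float64))
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("lambda sequence must be a non-empty 1-D sequence")
    if not np.isfinite(lam).all() or (lam < 0).any():
        raise ValueError("lambda values must be finite and non-negative")
    if lam.size > 1 and not (np.diff(lam) < 0).all():
        import warnings

        warnings.warn(
            "lambda sequence is not strictly decreasing; warm starts are "
            "most effective along a decreasing sequence",
            UserWarning,
            stacklevel=2,
        )
    return lam


def compute_gram(X) -> np.ndarray:
    """Gram (predictor covariance) matrix C = (1/n) X'X.

    With z-scored columns the diagonal is 1 and off-diagonal entries are
    predictor correlations.  Computed once per design and shared
    read-only across all voxel fits.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    C = (X.T @ X) / n
    # enforce exact symmetry against rounding in the BLAS product
    return (C + C.T) / 2


def compute_crossproducts(X, Y) -> np.ndarray:
    """Cross-products c = (1/n) X'Y, one column per voxel.

    These are the only statistics of Y the solvers need (covariance
    updates: no residual vectors are ever formed).  Because X is
    column-centered, c is invariant to adding a constant to any column
    of Y.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but Y has {Y.shape[0]}; the number "
            "of time points must match"
        )
    return (X.T @ Y) / X.shape[0]


def compute_intercepts(Y) -> np.ndarray:
    """Unregularized intercepts: the column means of Y (1 x v row).

    Since X is centered and the intercept is unpenalized, this is the
    exact intercept of the penalized optimum for every lambda, so it is
    computed once, independent of either solver.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y.mean(axis=0)[None, :]


def calculate_lambda_start(X, Y) -> float:
    """Smallest lambda at which every voxel's solution is all-zero.

    Equals max_{j,v} |(1/n) <X_j, Y_v>|.  For any lam >= this value the
    zero vector satisfies the subgradient optimality conditions of every
    voxel's objective.
    """
    return float(np.max(np.abs(compute_crossproducts(X, Y))))


def calculate_lambda_start_per_voxel(X, Y) -> np.ndarray:
    """Per-voxel variant of :func:`calculate_lambda_start` (length v)."""
    return np.max(np.abs(compute_crossproducts(X, Y)), axis=0)


def soft_threshold(z, t):
    """Soft-thresholding S(z, t) = sign(z) * max(|z| - t, 0).

    The proximal operator of ``t * |.|``; elementwise on arrays.
    """
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def objective_value(X, y, beta, b0, lam) -> float:
    """Evaluate (1/2n) ||y - X beta - b0 1||^2 + lam ||beta||_1."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    beta = np.asarray(beta, dtype=np.float64).ravel()
    n = X.shape[0]
    r = y - X @ beta - b0
    return float(r @ r / (2 * n) + lam * np.abs(beta).sum())
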