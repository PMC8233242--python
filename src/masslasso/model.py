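"""Model-object front end: build a :class:`MassLasso` from data, call
``fit`` to obtain :class:`~masslasso.results.LassoPathResults`.

This is the interface most users want; the solver functions in
:mod:`masslasso.cd` and :mod:`masslasso.admm` remain available for
finer control (per-voxel fits, custom batching).
"""

from __future__ import annotations

import numpy as np

from .admm import ADMMOptions, admm_solve_path
from .cd import CDOptions, cd_solve_path
from .core import (
    calculate_lambda_start,
    check_standardized,
    validate_design,
    zscore_columns,
)
from .results import LassoPathResults

__all__ = ["MassLasso"]


class MassLasso:
    """Mass-univariate L1-regularized linear model.

    Fits, for every response series (voxel) j, the lasso

        (1/2n) ||Y_j - X B_j - 1 B0_j||^2 + lam ||B_j||_1

    over a decreasing sequence of penalties, sharing the design matrix
    (and hence its Gram matrix or factorization) across all voxels.

    Parameters
    ----------
    endog : (n, v) response matrix (e.g. voxel time courses).
    exog : (n, p) design matrix.  Must be z-scored (column mean 0,
        population second moment 1) and contain no intercept column;
        pass ``standardize=True`` to have the model z-score it.
    standardize : apply z-scoring to ``exog`` instead of requiring it.

    Examples
    --------
    >>> model = MassLasso(Y, X, standardize=True)
    >>> res = model.fit(lambdas=[0.25, 0.125], method="cd")
    >>> print(res.summary())
    """

    def __init__(self, endog, exog, standardize: bool = False):
        Y = np.asarray(endog, dtype=np.float64)
        if Y.ndim == 1:
            Y = Y[:, None]
        if not np.isfinite(Y).all():
            raise ValueError("response matrix contains non-finite entries")
        if standardize:
            X, self.scaling = zscore_columns(exog)
        else:
            X = validate_design(exog)
            self.scaling = None
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"design has {X.shape[0]} time points, responses have "
                f"{Y.shape[0]}"
            )
        if Y.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        self.exog = X
        self.endog = Y
        self.n, self.p = X.shape
        self.v = Y.shape[1]

    @classmethod
    def from_dataframe(cls, data, response_columns, predictor_columns,
                       standardize: bool = True) -> "MassLasso":
        """Build from a DataFrame of time points x (responses + predictors)."""
        Y = data[list(response_columns)].to_numpy(dtype=np.float64)
        X = data[list(predictor_columns)].to_numpy(dtype=np.float64)
        return cls(Y, X, standardize=standardize)

    def lambda_start(self) -> float:
        """Smallest penalty at which every voxel's fit is all-zero."""
        return calculate_lambda_start(self.exog, self.endog)

    def lambda_grid(self, count: int = 5, log2_step: float = 1.0) -> np.ndarray:
        """Geometric penalty grid lambda_start * 2^0, 2^-step, ...

        The first value sits exactly at lambda_start, the conventional
        top of a regularization path.
        """
        start = self.lambda_start()
        return start * 2.0 ** (-log2_step * np.arange(count))

    def fit(self, lambdas, method: str = "cd", n_workers: int | None = None,
            **options) -> LassoPathResults:
        """Fit the penalty path with the chosen solver.

        method "cd" runs per-voxel cyclic coordinate descent
        (options: n_iter_max, tol_value, buffer_factor,
        cpu_load_factor); "admmbatch" runs the batched ADMM
        (options: n_iter_max, tol_value, buffer_size, rho,
        single_precision).
        """
        if method == "cd":
            opts = CDOptions(**options)
            return cd_solve_path(self.exog, self.endog, lambdas, opts,
                                 n_workers=n_workers)
        if method in ("admm", "admmbatch"):
            opts = ADMMOptions(**options)
            return admm_solve_path(self.exog, self.endog, lambdas, opts)
        raise ValueError(f"unknown method {method!r}; expected 'cd' or 'admmbatch'")
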