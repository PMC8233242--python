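"""Synthetic data generators and an independent reference solver.

Two generator families:

* white-noise benchmarks mirroring typical mass-univariate workloads —
  an overparameterized encoding-model shape ("A": n=300, p=5000,
  v=65536, lambdas 2^-2 .. 2^-6) and a well-defined single-trial/FIR
  shape ("B": n=300, p=200, v=65536, lambda 2^-4), both drawn i.i.d.
  standard normal with X z-scored afterwards, and both scalable to desk
  size for testing;
* a planted sparse linear model for recovery scoring.

Neither emulates fMRI noise structure (autocorrelation, drift,
physiological noise): the benchmarks are white by design, so passing
tests certify solver correctness, not robustness to realistic noise.

The reference solver is plain proximal gradient (ISTA) with a fixed
step 1/L: deliberately simple, no warm starts, no active sets, sharing
only the soft-thresholding primitive with the production solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    compute_crossproducts,
    compute_gram,
    soft_threshold,
    zscore_columns,
)

__all__ = [
    "BenchmarkSpec",
    "PlantedModel",
    "benchmark_spec",
    "generate_benchmark",
    "generate_planted",
    "ista_reference",
    "kkt_residual",
]

_DEFAULT_DIMS = {
    "A": dict(n=300, p=5000, v=65536, lambda_seq=tuple(2.0 ** -k for k in range(2, 7))),
    "B": dict(n=300, p=200, v=65536, lambda_seq=(2.0 ** -4,)),
}


@dataclass(frozen=True)
class BenchmarkSpec:
    """Shape and penalty sequence of a synthetic benchmark dataset."""

    n: int
    p: int
    v: int
    lambda_seq: tuple
    seed: int = 0
    label: str = "custom"


def benchmark_spec(label: str, seed: int = 0, n: int | None = None,
                   p: int | None = None, v: int | None = None,
                   lambda_seq=None) -> BenchmarkSpec:
    """Build a BenchmarkSpec for label "A", "B" or "custom".

    For A and B, any dimension left as None takes the full-size default;
    pass explicit n, p, v to scale the configuration down while keeping
    its penalty sequence.
    """
    if label in _DEFAULT_DIMS:
        d = _DEFAULT_DIMS[label]
        return BenchmarkSpec(
            n=n or d["n"], p=p or d["p"], v=v or d["v"],
            lambda_seq=tuple(lambda_seq) if lambda_seq is not None else d["lambda_seq"],
            seed=seed, label=label,
        )
    if label != "custom":
        raise ValueError(f"unknown benchmark label {label!r}")
    if None in (n, p, v) or lambda_seq is None:
        raise ValueError("custom benchmarks need explicit n, p, v and lambda_seq")
    return BenchmarkSpec(n=n, p=p, v=v, lambda_seq=tuple(lambda_seq),
                         seed=seed, label="custom")


@dataclass(frozen=True)
class PlantedModel:
    """Sparse ground truth for recovery tests.

    Exactly ``support_size`` nonzeros per voxel, each of magnitude
    ``effect_size`` with a random sign; Gaussian noise with sd
    ``noise_sd`` is added to X @ beta.
    """

    support_size: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.5
    true_beta: np.ndarray | None = None


def generate_benchmark(spec: BenchmarkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, Y) i.i.d. standard normal; X is z-scored, Y left raw.

    Pure function of the seed: two calls with equal specs return
    bitwise-identical matrices.
    """
    rng = np.random.default_rng(spec.seed)
    X_raw = rng.standard_normal((spec.n, spec.p))
    Y = rng.standard_normal((spec.n, spec.v))
    X, _ = zscore_columns(X_raw)
    return X, Y


def generate_planted(spec: BenchmarkSpec, model: PlantedModel) -> tuple[np.ndarray, np.ndarray, PlantedModel]:
    """Generate a planted sparse model: Y = X @ true_beta + noise.

    Returns (X, Y, model-with-truth); the filled-in ``true_beta`` is
    p x v with exactly ``support_size`` nonzeros of magnitude
    ``effect_size`` per voxel.
    """
    if model.support_size >= spec.n:
        raise ValueError("support_size must be smaller than n")
    rng = np.random.default_rng(spec.seed)
    X_raw = rng.standard_normal((spec.n, spec.p))
    X, _ = zscore_columns(X_raw)
    true_beta = np.zeros((spec.p, spec.v))
    for j in range(spec.v):
        support = rng.choice(spec.p, size=model.support_size, replace=False)
        signs = rng.choice([-1.0, 1.0], size=model.support_size)
        true_beta[support, j] = model.effect_size * signs
    noise = rng.standard_normal((spec.n, spec.v)) * model.noise_sd
    Y = X @ true_beta + noise
    filled = PlantedModel(
        support_size=model.support_size,
        effect_size=model.effect_size,
        noise_sd=model.noise_sd,
        true_beta=true_beta,
    )
    return X, Y, filled


def ista_reference(X, y, lam, tol: float = 1e-10, max_iter: int = 500_000) -> np.ndarray:
    """Proximal-gradient (ISTA) reference solution of the lasso objective.

    Iterates beta <- S(beta + (1/L)(1/n) X'(y - ybar - X beta), lam/L)
    with L the largest Gram eigenvalue, until the max coordinate change
    drops below ``tol``.  Used as an independent correctness oracle;
    intentionally free of warm starts, active sets and covariance
    updates.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    yc = y - y.mean()
    C = compute_gram(X)
    L = float(np.linalg.eigvalsh(C)[-1])
    beta = np.zeros(p)
    Xty = X.T @ yc / n
    for _ in range(max_iter):
        grad = Xty - C @ beta
        new = soft_threshold(beta + grad / L, lam / L)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def kkt_residual(X, y, beta, lam) -> float:
    """Maximal violation of the lasso optimality (KKT) conditions.

    With g = (1/n) X'(y - ybar - X beta), returns the max over j of
    |g_j - lam * sign(beta_j)| where beta_j != 0, and
    max(|g_j| - lam, 0) where beta_j = 0.  Zero at an exact solution.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    beta = np.asarray(beta, dtype=np.float64).ravel()
    n = X.shape[0]
    r = y - y.mean() - X @ beta
    g = X.T @ r / n
    nz = beta != 0
    res = 0.0
    if nz.any():
        res = float(np.max(np.abs(g[nz] - lam * np.sign(beta[nz]))))
    if (~nz).any():
        res = max(res, float(np.max(np.maximum(np.abs(g[~nz]) - lam, 0.0))))
    return res
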