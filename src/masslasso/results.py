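"""Fit-result container, sparse coefficient storage, on-disk formats and
memory estimation.

Coefficients are stored sparsely: for each lambda, one
:class:`SparseBetaSet` packs all voxels' nonzero values, their predictor
indexes (0-based) and per-voxel counts (N_nz).  The on-disk format is a
single HDF5 container; a secondary plain-text export writes one
delimited file per lambda with columns voxel, predictor (1-based), beta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SparseBetaSet",
    "LassoPathResults",
    "FitResult",
    "convert_betas_sparse_to_full",
    "convert_betas_full_to_sparse",
    "write_fit",
    "read_fit",
    "estimate_memory",
]

FORMAT_VERSION = "1"


@dataclass
class SparseBetaSet:
    """Packed sparse coefficients for all voxels at one lambda.

    values : concatenated nonzero coefficients
    indexes : matching predictor indexes, 0-based, strictly increasing
        within each voxel
    counts : per-voxel number of nonzeros (N_nz), length v
    offsets : per-voxel start positions into values/indexes, length v
    """

    values: np.ndarray
    indexes: np.ndarray
    counts: np.ndarray
    offsets: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.counts.shape[0]

    def voxel(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(values, indexes) slice for voxel j."""
        o, c = self.offsets[j], self.counts[j]
        return self.values[o:o + c], self.indexes[o:o + c]

    def to_dense(self, p: int) -> np.ndarray:
        return convert_betas_sparse_to_full(self, p)


def convert_betas_full_to_sparse(dense) -> SparseBetaSet:
    """Extract exact nonzeros of a dense p x v coefficient matrix.

    No thresholding is applied: both solvers produce exact zeros by
    soft-thresholding, so sparsity is structural, not approximate.
    """
    dense = np.asarray(dense)
    if dense.ndim == 1:
        dense = dense[:, None]
    p, v = dense.shape
    values, indexes, counts = [], [], np.zeros(v, dtype=np.int64)
    for j in range(v):
        nz = np.flatnonzero(dense[:, j])
        counts[j] = nz.size
        indexes.append(nz)
        values.append(dense[nz, j])
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int64)
    return SparseBetaSet(
        values=np.concatenate(values) if v else np.empty(0, dense.dtype),
        indexes=np.concatenate(indexes).astype(np.int64) if v else np.empty(0, np.int64),
        counts=counts,
        offsets=offsets,
    )


def convert_betas_sparse_to_full(sparse: SparseBetaSet, p: int) -> np.ndarray:
    """Expand a :class:`SparseBetaSet` to a dense p x v matrix.

    Raises
    ------
    ValueError
        If any stored index is out of range or a voxel lists the same
        predictor twice.
    """
    v = sparse.n_voxels
    if sparse.indexes.size and (sparse.indexes.max() >= p or sparse.indexes.min() < 0):
        raise ValueError(
            f"sparse index {int(sparse.indexes.max())} out of range for p={p}"
        )
    dense = np.zeros((p, v), dtype=sparse.values.dtype)
    for j in range(v):
        vals, idx = sparse.voxel(j)
        if np.unique(idx).size != idx.size:
            raise ValueError(f"duplicate predictor index in voxel {j}")
        dense[idx, j] = vals
    return dense


@dataclass
class LassoPathResults:
    """Results of a mass-univariate lasso path fit.

    One :class:`SparseBetaSet` per lambda, the (exact) intercept row,
    and per-voxel per-lambda convergence diagnostics.  The last-lambda
    slice reproduces the single-solution reading of the original
    estimator's return signature.
    """

    lambdas: np.ndarray
    per_lambda: list
    intercepts: np.ndarray           # 1 x v
    iterations: np.ndarray           # n_lambda x v
    converged: np.ndarray            # n_lambda x v, bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.per_lambda) != self.lambdas.shape[0]:
            raise ValueError("need one sparse coefficient set per lambda")

    @property
    def n_lambdas(self) -> int:
        return self.lambdas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.intercepts.shape[1]

    @property
    def p(self) -> int:
        return int(self.meta["p"])

    def coefficients(self, lambda_index: int = -1) -> np.ndarray:
        """Dense p x v coefficient matrix at one lambda (default: last)."""
        return self.per_lambda[lambda_index].to_dense(self.p)

    def nonzero_counts(self) -> np.ndarray:
        """N_nz per voxel, n_lambda x v."""
        return np.vstack([sb.counts for sb in self.per_lambda])

    def summary(self) -> str:
        """Human-readable per-lambda fit summary."""
        nnz = self.nonzero_counts()
        lines = [
            "Mass-univariate lasso path"
            f" (solver={self.meta.get('solver', '?')},"
            f" n={self.meta.get('n', '?')}, p={self.meta.get('p', '?')},"
            f" v={self.n_voxels})",
            f"{'lambda':>12} {'mean N_nz':>10} {'max N_nz':>9} "
            f"{'mean iters':>11} {'converged':>10}",
        ]
        for i, lam in enumerate(self.lambdas):
            lines.append(
                f"{lam:>12.6g} {nnz[i].mean():>10.2f} {nnz[i].max():>9d} "
                f"{self.iterations[i].mean():>11.1f} "
                f"{self.converged[i].mean():>9.0%}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        write_fit(self, path)

    @classmethod
    def load(cls, path) -> "LassoPathResults":
        return read_fit(path)

    def export_text(self, directory) -> list:
        """Write one delimited file per lambda (voxel, predictor, beta).

        Predictor numbering in the text export is 1-based.  Returns the
        list of written paths.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, lam in enumerate(self.lambdas):
            sb = self.per_lambda[i]
            out = directory / f"betas_lambda_{i:03d}.tsv"
            with open(out, "w") as fh:
                fh.write(f"# lambda = {lam!r}; predictor indexes are 1-based\n")
                fh.write("voxel\tpredictor\tbeta\n")
                for j in range(sb.n_voxels):
                    vals, idx = sb.voxel(j)
                    for k, b in zip(idx, vals):
                        fh.write(f"{j + 1}\t{k + 1}\t{b!r}\n")
            paths.append(out)
        return paths


# Backwards-friendly alias matching the generic name used in docs.
FitResult = LassoPathResults


def write_fit(result: LassoPathResults, path) -> None:
    """Write a fit to a single HDF5 container (lossless round trip).

    Layout: root attrs ``format_version`` and ``meta`` (JSON); datasets
    ``lambdas``, ``intercepts``, ``iterations``, ``converged``; one group
    ``lambda_000`` ... per penalty holding values/indexes/counts/offsets.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["meta"] = json.dumps(result.meta)
        f.create_dataset("lambdas", data=result.lambdas)
        f.create_dataset("intercepts", data=result.intercepts)
        f.create_dataset("iterations", data=result.iterations)
        f.create_dataset("converged", data=result.converged.astype(np.uint8))
        for i, sb in enumerate(result.per_lambda):
            g = f.create_group(f"lambda_{i:03d}")
            g.create_dataset("values", data=sb.values)
            g.create_dataset("indexes", data=sb.indexes)
            g.create_dataset("counts", data=sb.counts)
            g.create_dataset("offsets", data=sb.offsets)


def read_fit(path) -> LassoPathResults:
    """Read a fit written by :func:`write_fit`.

    Raises
    ------
    ValueError
        On a container format-version mismatch (both versions named).
    """
    import h5py

    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"fit container has format version {version!r}, this "
                f"reader supports {FORMAT_VERSION!r}"
            )
        lambdas = f["lambdas"][()]
        per_lambda = []
        for i in range(lambdas.shape[0]):
            g = f[f"lambda_{i:03d}"]
            per_lambda.append(SparseBetaSet(
                values=g["values"][()],
                indexes=g["indexes"][()],
                counts=g["counts"][()],
                offsets=g["offsets"][()],
            ))
        return LassoPathResults(
            lambdas=lambdas,
            per_lambda=per_lambda,
            intercepts=f["intercepts"][()],
            iterations=f["iterations"][()],
            converged=f["converged"][()].astype(bool),
            meta=json.loads(f.attrs["meta"]),
        )


def estimate_memory(n: int, p: int, v: int, buffer_factor: float = 3.0,
                    buffer_size: int = 8192, solver: str = "cd",
                    n_workers: int = 1, index_width: int = 8) -> dict:
    """Itemized working-memory estimate in bytes for one fit.

    CD: the p x p Gram matrix, one dense working beta per worker, and
    the preallocated sparse output (ceil(buffer_factor*n) slots per
    voxel, value + index per slot).  ADMM: the cached factorization
    (min(p, n)^2 doubles), the (B, Z, U) triple and the cross-product
    block for one batch of buffer_size voxels.
    """
    if min(n, p, v) < 1:
        raise ValueError("n, p, v must be positive")
    items: dict[str, int] = {}
    if solver == "cd":
        items["gram"] = p * p * 8
        items["working_beta"] = n_workers * p * 8
        items["sparse_output"] = int(np.ceil(buffer_factor * n)) * v * (8 + index_width)
    elif solver == "admm":
        items["factorization"] = min(p, n) ** 2 * 8
        items["bzu_triple"] = 3 * p * buffer_size * 8
        items["crossproduct_block"] = p * buffer_size * 8
    else:
        raise ValueError(f"unknown solver {solver!r}; expected 'cd' or 'admm'")
    items["total"] = sum(items.values())
    return items
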