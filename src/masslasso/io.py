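"""Input readers: delimited-text / NumPy matrix files and NIfTI volumes.

Matrix files may be whitespace- or comma-delimited text, or ``.npy``.
Responses may alternatively come from a 4-D NIfTI volume plus a 3-D
binary mask on the same spatial grid; in-mask voxels become columns in
a fixed linear order (first spatial axis fastest), and the index map is
returned so coefficient rows can be scattered back to voxel
coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import StandardizationError, check_standardized, zscore_columns

__all__ = ["load_matrix", "load_design", "load_responses",
           "extract_masked_timeseries", "scatter_to_volume"]


def load_matrix(path) -> np.ndarray:
    """Load a 2-D matrix from .npy or delimited text (comma or space)."""
    path = Path(path)
    if path.suffix == ".npy":
        a = np.load(path)
    else:
        try:
            a = np.loadtxt(path)
        except ValueError:
            a = np.loadtxt(path, delimiter=",")
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    return a


def load_design(path, standardize: bool = False):
    """Load a design matrix, validating or applying z-scoring.

    In strict mode (default) the file must already satisfy the
    z-scoring contract; with ``standardize=True`` the columns are
    z-scored and the scaling report is returned.

    Returns
    -------
    (X, scaling) where scaling is None in strict mode.
    """
    X = load_matrix(path)
    if standardize:
        return zscore_columns(X)
    report = check_standardized(X)
    if not report.all_ok:
        j = int(report.failing_columns()[0])
        raise StandardizationError(
            f"design file {path}: column {j} is not z-scored "
            f"(mean={report.column_means[j]:.3g}, second moment="
            f"{report.column_moments[j]:.6g}); rerun with --standardize "
            "or z-score the file"
        )
    return X, None


def extract_masked_timeseries(data4d: np.ndarray, mask3d: np.ndarray):
    """Turn a 4-D volume into an (n_time, n_voxel) matrix via a mask.

    Voxels are linearized with the first spatial axis fastest
    (Fortran order); the returned ``index_map`` holds each column's
    flat voxel index in that order.
    """
    data4d = np.asarray(data4d)
    mask3d = np.asarray(mask3d)
    if data4d.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data4d.shape}")
    if mask3d.shape != data4d.shape[:3]:
        raise ValueError(
            f"mask grid {mask3d.shape} does not match volume grid "
            f"{data4d.shape[:3]}"
        )
    if data4d.shape[3] < 2:
        raise ValueError("time axis must have at least 2 points")
    mask_flat = mask3d.ravel(order="F").astype(bool)
    index_map = np.flatnonzero(mask_flat)
    if index_map.size == 0:
        raise ValueError("mask selects zero voxels")
    flat = data4d.reshape(-1, data4d.shape[3], order="F")
    Y = flat[mask_flat].T.astype(np.float64)
    return Y, index_map


def scatter_to_volume(values: np.ndarray, index_map: np.ndarray, grid) -> np.ndarray:
    """Scatter a per-voxel row (length v) back to a 3-D volume."""
    out = np.zeros(int(np.prod(grid)), dtype=np.asarray(values).dtype)
    out[index_map] = np.asarray(values).ravel()
    return out.reshape(grid, order="F")


def load_responses(path, mask_path=None):
    """Load a response matrix from a matrix file or NIfTI volume + mask.

    Returns (Y, index_map, grid); index_map and grid are None for
    matrix files.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        if mask_path is None:
            raise ValueError("a 3-D binary mask is required with NIfTI input")
        img = nib.load(str(path))
        mask_img = nib.load(str(mask_path))
        data = np.asanyarray(img.dataobj)
        mask = np.asanyarray(mask_img.dataobj)
        Y, index_map = extract_masked_timeseries(data, mask != 0)
        return Y, index_map, tuple(int(s) for s in mask.shape)
    Y = load_matrix(path)
    if Y.shape[0] < 2:
        raise ValueError("time axis must have at least 2 points")
    return Y, None, None
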