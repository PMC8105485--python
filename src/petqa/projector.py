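"""Parallel-beam projector with a matched (exact-adjoint) sparse system matrix.

The acquisition model is 2D parallel-beam per axial slice: a pixel-driven
linear-interpolation projector whose geometry (rotation centre ``N // 2``,
radial bin count equal to the in-plane matrix size, angles over [0, pi))
matches ``skimage.transform.radon``.  Iterative reconstruction needs the
exact adjoint of the forward model, which a sparse matrix provides for free
(``A.T``); FBP filtering is delegated to ``skimage.transform.iradon`` on the
same geometry.

Line integrals are expressed in pixel-length units: the interpolation
weights of each pixel sum to one per angle, so the sinogram sum per angle
equals the slice activity sum exactly (for activity inside the radial
field of view).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse

from .volumes import GeometryError, ImageVolume, Sinogram

__all__ = ["system_matrix", "forward_project", "back_project", "uniform_angles"]


def uniform_angles(n_angles: int) -> np.ndarray:
    """Uniformly spaced projection angles over [0, pi), in radians."""
    return np.arange(n_angles) * (np.pi / n_angles)


@lru_cache(maxsize=8)
def system_matrix(n: int, n_angles: int) -> sparse.csr_matrix:
    """Sparse forward projector for an ``n x n`` in-plane grid.

    Rows are ordered angle-major: row ``a * n + j`` is radial bin ``j`` of
    angle ``a``.  Columns are flattened pixels (row-major, first image axis
    fastest-varying last).  Each pixel deposits its value into the two radial
    bins bracketing ``t = (col - c) cos(theta) - (row - c) sin(theta) + c``
    with linear-interpolation weights (c = n // 2, matching skimage).
    """
    angles = uniform_angles(n_angles)
    c = n // 2
    rows_px, cols_px = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    xr = (cols_px.ravel() - c).astype(np.float64)
    yr = (rows_px.ravel() - c).astype(np.float64)
    px = np.arange(n * n)

    mat_rows: list[np.ndarray] = []
    mat_cols: list[np.ndarray] = []
    mat_data: list[np.ndarray] = []
    for a, th in enumerate(angles):
        t = xr * np.cos(th) - yr * np.sin(th) + c
        i0 = np.floor(t).astype(np.int64)
        w1 = t - i0
        for bins, w in ((i0, 1.0 - w1), (i0 + 1, w1)):
            ok = (bins >= 0) & (bins < n) & (w > 0)
            mat_rows.append(a * n + bins[ok])
            mat_cols.append(px[ok])
            mat_data.append(w[ok])
    A = sparse.coo_matrix(
        (np.concatenate(mat_data), (np.concatenate(mat_rows), np.concatenate(mat_cols))),
        shape=(n_angles * n, n * n),
    )
    return A.tocsr()


def _check_inplane(vol: ImageVolume) -> tuple[int, float]:
    nx, ny, _ = vol.voxels.shape
    dx, dy, _ = vol.voxel_size
    if nx != ny:
        raise GeometryError("projector requires a square in-plane matrix")
    if abs(dx - dy) > 1e-9:
        raise GeometryError(
            f"anisotropic in-plane voxels ({dx} x {dy} mm) are unsupported"
        )
    return nx, dx


def forward_project(
    vol: ImageVolume, n_angles: int, radial_spacing_mm: float | None = None
) -> Sinogram:
    """Slice-wise parallel-beam line-integral projection of a volume.

    ``radial_spacing_mm`` defaults to the in-plane voxel size; any other
    value is a geometry error because the matched projector samples one
    radial bin per pixel column.
    """
    if n_angles < 16:
        raise ValueError("n_angles must be >= 16")
    n, dx = _check_inplane(vol)
    if radial_spacing_mm is not None and abs(radial_spacing_mm - dx) > 1e-9:
        raise GeometryError("radial_spacing_mm must equal the in-plane voxel size")
    A = system_matrix(n, n_angles)
    nz = vol.voxels.shape[2]
    flat = vol.voxels.reshape(n * n, nz)
    counts = (A @ flat).reshape(n_angles, n, nz)
    return Sinogram(
        np.maximum(counts, 0.0),
        uniform_angles(n_angles),
        radial_spacing_mm=dx,
        slice_thickness_mm=vol.voxel_size[2],
    )


def back_project(sino: Sinogram, n: int) -> np.ndarray:
    """Unfiltered adjoint backprojection onto an ``n x n x n_slices`` array."""
    A = system_matrix(n, sino.n_angles)
    flat = sino.counts.reshape(sino.n_angles * sino.n_radial, sino.n_slices)
    return (A.T @ flat).reshape(n, n, sino.n_slices)
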