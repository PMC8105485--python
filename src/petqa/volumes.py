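"""Core containers: voxel grids, image volumes, label volumes and sinograms.

The ``ImageVolume`` is the currency passed between every pipeline stage:
phantom generation, reconstruction and metric extraction all consume and
produce volumes on an explicit physical grid (voxel size in mm, axial axis
last).  Volumes round-trip through NIfTI-1 via nibabel; sinograms are stored
as flat binary with a JSON sidecar describing their geometry.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "ImageVolume",
    "LabelVolume",
    "Sinogram",
    "FormatError",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_sinogram",
    "write_sinogram",
]


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected format."""


class GeometryError(ValueError):
    """Raised when a geometric precondition is violated."""


@dataclass(frozen=True)
class Grid:
    """A regular voxel grid: ``shape`` (nx, ny, nz) and voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_size) != 3:
            raise ValueError("grid requires 3 axes")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.shape[0] < 8 or self.shape[1] < 8 or self.shape[2] < 1:
            raise ValueError("grid too small; need shape >= (8, 8, 1)")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape, self.voxel_size))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres per axis, origin at the
        grid centre (the in-plane rotation centre used by the projector,
        index ``n // 2``)."""
        out = []
        for n, d in zip(self.shape, self.voxel_size):
            out.append((np.arange(n) - n // 2) * d)
        return tuple(out)


@dataclass
class ImageVolume:
    """A 3D activity image on a physical grid.

    ``voxels`` is indexed (x, y, z) with the axial direction last; values are
    activity in arbitrary units (or kBq/mL for calibrated phantoms).
    Reconstructed FBP images may contain negative values, so non-negativity
    is only enforced for phantom (ground-truth) volumes by their generators.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    frame: str = "xyz"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def copy_with(self, voxels: np.ndarray) -> "ImageVolume":
        return ImageVolume(voxels, self.voxel_size, self.frame)


@dataclass
class LabelVolume:
    """Integer region labels on the same grid as a paired ImageVolume."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover labels {sorted(missing)}")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the region called ``name`` in the legend."""
        ids = [k for k, v in self.legend.items() if v == name]
        if not ids:
            raise KeyError(f"no label named {name!r}")
        return np.isin(self.labels, ids)

    def id_of(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(f"no label named {name!r}")


@dataclass
class Sinogram:
    """Parallel-beam projection data: counts[angle, radial_bin, slice].

    ``angles`` are strictly increasing in radians over [0, pi);
    ``radial_spacing_mm`` is the detector bin pitch (equal to the in-plane
    voxel size for the matched projector).
    """

    counts: np.ndarray
    angles: np.ndarray
    radial_spacing_mm: float
    slice_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_angles, n_radial, n_slices)")
        if self.counts.shape[0] != self.angles.size:
            raise ValueError("angles length must match counts.shape[0]")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("sinogram counts must be non-negative")

    @property
    def n_angles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_radial(self) -> int:
        return self.counts.shape[1]

    @property
    def n_slices(self) -> int:
        return self.counts.shape[2]


# ---------------------------------------------------------------------------
# NIfTI round-trip


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write an ImageVolume (or LabelVolume) as NIfTI-1 with voxel size in
    the header zooms."""
    if isinstance(vol, LabelVolume):
        data, zooms = vol.labels.astype(np.int32), vol.voxel_size
    else:
        data, zooms = vol.voxels, vol.voxel_size
    affine = np.diag(list(zooms) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(zooms)
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI-1 file into an ImageVolume."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # pragma: no cover - nibabel error paths
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel dimensions {zooms}")
    return ImageVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms))


# ---------------------------------------------------------------------------
# Sinogram flat-binary + JSON sidecar


def write_sinogram(sino: Sinogram, path: str | os.PathLike) -> None:
    """Write counts as flat float64 binary with a ``.json`` sidecar holding
    shape, angles and spacings."""
    path = os.fspath(path)
    sino.counts.astype(np.float64).tofile(path)
    sidecar = {
        "shape": list(sino.counts.shape),
        "angles_rad": sino.angles.tolist(),
        "radial_spacing_mm": sino.radial_spacing_mm,
        "slice_thickness_mm": sino.slice_thickness_mm,
        "dtype": "float64",
        "order": "C",
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_sinogram(path: str | os.PathLike) -> Sinogram:
    path = os.fspath(path)
    sidecar_path = path + ".json"
    if not os.path.exists(path) or not os.path.exists(sidecar_path):
        raise FormatError(f"sinogram file or sidecar missing for {path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    counts = np.fromfile(path, dtype=np.float64).reshape(meta["shape"])
    return Sinogram(
        counts,
        np.asarray(meta["angles_rad"]),
        meta["radial_spacing_mm"],
        meta.get("slice_thickness_mm", 1.0),
    )
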