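"""NEMA NU 2-2012 image-quality analysis: sphere/background ROIs, percentage
contrast and background variability.

Per sphere of diameter d, a circular 2D ROI of the same diameter is placed on
the sphere-centre slice, and 60 background ROIs (12 in-plane positions x 5
slices at the centre and +/-1 cm and +/-2 cm) of the same diameter are placed
in the warm background, concentric across sphere sizes.  From the ROI means:

    hot contrast (%)   = 100 * (C_H/C_B - 1) / (a_H/a_B - 1)
    cold contrast (%)  = 100 * (1 - C_C/C_B)
    SD                 = sqrt( sum_k (C_Bk - C_B)^2 / (K - 1) )
    background var (%) = 100 * SD / C_B

ROI membership is voxel-centre-inside-circle (no partial-volume weighting),
so results are bit-reproducible for a given layout.  The exact in-plane
background positions are not standardised to the millimetre; the default
layout is computed deterministically from the phantom geometry (see
:func:`default_background_positions`) and any explicit position list can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantoms import NemaIQSpec
from .volumes import GeometryError, ImageVolume, LabelVolume

__all__ = [
    "SphereRoiResult",
    "BackgroundRoiSet",
    "ContrastResult",
    "BackgroundVariabilityResult",
    "place_sphere_rois",
    "default_background_positions",
    "place_background_rois",
    "percent_contrast_hot",
    "percent_contrast_cold",
    "background_variability",
    "analyze_nema",
]


@dataclass
class SphereRoiResult:
    sphere_diameter_mm: float
    mean_counts: float
    is_cold: bool
    roi_center_mm: tuple[float, float, float]
    n_voxels: int


@dataclass
class BackgroundRoiSet:
    sphere_diameter_mm: float
    roi_means: np.ndarray
    layout: tuple[int, int]

    @property
    def C_B(self) -> float:
        return float(np.mean(self.roi_means))


@dataclass
class ContrastResult:
    sphere_diameter_mm: float
    percent_contrast: float
    is_cold: bool
    a_H: float
    a_B: float


@dataclass
class BackgroundVariabilityResult:
    sphere_diameter_mm: float | None
    sd: float
    percent_bv: float


def _disk_mask_2d(
    x_mm: np.ndarray, y_mm: np.ndarray, cx: float, cy: float, radius: float
) -> np.ndarray:
    return (x_mm[:, None] - cx) ** 2 + (y_mm[None, :] - cy) ** 2 <= radius**2


def place_sphere_rois(
    vol: ImageVolume, labels: LabelVolume, spec: NemaIQSpec
) -> list[SphereRoiResult]:
    """Circular ROIs equal in diameter to each sphere on the sphere-centre
    slice; ROI centres taken from the label-volume centroids (synthetic-mode
    ground truth)."""
    x, y, z = vol.grid.coords_mm()
    out = []
    for k, d in enumerate(spec.sphere_diameters_mm):
        mask = labels.mask(f"sphere_{k}")
        if not mask.any():
            raise GeometryError(f"sphere_{k} has no labelled voxels")
        idx = np.argwhere(mask)
        cx, cy = x[idx[:, 0]].mean(), y[idx[:, 1]].mean()
        cz = z[idx[:, 2]].mean()
        k_slice = int(np.argmin(np.abs(z - cz)))
        if not 0 <= k_slice < vol.voxels.shape[2]:
            raise GeometryError("sphere centre slice outside the volume")
        roi = _disk_mask_2d(x, y, cx, cy, d / 2.0)
        vals = vol.voxels[:, :, k_slice][roi]
        if vals.size == 0:
            raise GeometryError(f"empty ROI for sphere_{k}")
        out.append(
            SphereRoiResult(
                sphere_diameter_mm=float(d),
                mean_counts=float(vals.mean()),
                is_cold=k in spec.cold_sphere_indices,
                roi_center_mm=(float(cx), float(cy), float(z[k_slice])),
                n_voxels=int(vals.size),
            )
        )
    return out


def default_background_positions(
    spec: NemaIQSpec,
    n_positions: int = 12,
    edge_margin_mm: float = 15.0,
) -> list[tuple[float, float]]:
    """Deterministic in-plane background ROI centres.

    Candidates on concentric rings (outermost first, 15-degree steps) are
    accepted greedily when the largest-sphere ROI centred there stays
    ``edge_margin_mm`` inside the body, clears every sphere, and does not
    overlap an already accepted ROI.  Raises GeometryError listing the
    shortfall when ``n_positions`` cannot be placed.
    """
    r_roi = max(spec.sphere_diameters_mm) / 2.0
    sphere_r = np.asarray(spec.sphere_diameters_mm) / 2.0
    centers = spec.sphere_centers_mm()[:, :2]
    r_max = spec.body_radius_mm - edge_margin_mm - r_roi
    if r_max <= 0:
        raise GeometryError("phantom body too small for background ROIs")

    accepted: list[tuple[float, float]] = []
    radii = np.arange(r_max, -1.0, -r_roi)
    for r in radii:
        angles = [0.0] if r == 0 else np.deg2rad(np.arange(0.0, 360.0, 15.0))
        for a in angles:
            p = (r * np.cos(a), r * np.sin(a))
            d_sph = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
            if np.any(d_sph < r_roi + sphere_r):
                continue
            if any(np.hypot(q[0] - p[0], q[1] - p[1]) < 2 * r_roi for q in accepted):
                continue
            accepted.append(p)
            if len(accepted) == n_positions:
                return accepted
    raise GeometryError(
        f"could only place {len(accepted)} of {n_positions} background ROI "
        f"positions (body radius {spec.body_radius_mm} mm, ROI radius {r_roi} mm)"
    )


def _slice_indices(
    z_mm: np.ndarray, center_z: float, offsets_mm: tuple[float, ...]
) -> list[int]:
    """Nearest slice per axial offset; ties round toward the centre slice."""
    out = []
    for off in offsets_mm:
        target = center_z + off
        d = np.abs(z_mm - target)
        cands = np.flatnonzero(d <= d.min() + 1e-9)
        best = min(cands, key=lambda i: (abs(z_mm[i] - center_z), i))
        out.append(int(best))
    return out


def place_background_rois(
    vol: ImageVolume,
    labels: LabelVolume,
    spec: NemaIQSpec,
    positions_mm: list[tuple[float, float]] | None = None,
    slice_offsets_mm: tuple[float, ...] = (-20.0, -10.0, 0.0, 10.0, 20.0),
) -> dict[float, BackgroundRoiSet]:
    """60 background ROIs per sphere size (12 positions x 5 slices by
    default), concentric across sizes.  Verifies no ROI touches a sphere
    label."""
    if positions_mm is None:
        positions_mm = default_background_positions(spec)
    x, y, z = vol.grid.coords_mm()
    center_z = 0.0 if spec.center_slice_mm is None else spec.center_slice_mm
    slices = _slice_indices(z, center_z, slice_offsets_mm)
    bg_id = labels.id_of("background")

    result: dict[float, BackgroundRoiSet] = {}
    for d in spec.sphere_diameters_mm:
        means = []
        for px, py in positions_mm:
            roi2d = _disk_mask_2d(x, y, px, py, d / 2.0)
            for ks in slices:
                lab = labels.labels[:, :, ks][roi2d]
                if np.any((lab != bg_id) & (lab != 0)):
                    raise GeometryError(
                        f"background ROI at ({px:.1f}, {py:.1f}) mm, slice {ks} "
                        f"intersects a sphere label"
                    )
                means.append(float(vol.voxels[:, :, ks][roi2d].mean()))
        result[float(d)] = BackgroundRoiSet(
            sphere_diameter_mm=float(d),
            roi_means=np.asarray(means),
            layout=(len(positions_mm), len(slices)),
        )
    return result


def percent_contrast_hot(C_H: float, C_B: float, a_H: float, a_B: float) -> float:
    """Hot-sphere percentage contrast: 100 * (C_H/C_B - 1) / (a_H/a_B - 1)."""
    if C_B <= 0:
        raise ValueError("C_B must be > 0")
    if a_H == a_B:
        raise ValueError("contrast undefined when a_H equals a_B")
    return 100.0 * (C_H / C_B - 1.0) / (a_H / a_B - 1.0)


def percent_contrast_cold(C_C: float, C_B: float) -> float:
    """Cold-sphere percentage contrast: 100 * (1 - C_C/C_B)."""
    if C_B <= 0:
        raise ValueError("C_B must be > 0")
    return 100.0 * (1.0 - C_C / C_B)


def background_variability(
    roi_means, C_B: float | None = None, sphere_diameter_mm: float | None = None
) -> BackgroundVariabilityResult:
    """SD over the K background ROI means (K-1 denominator) and the
    percentage background variability 100 * SD / C_B."""
    means = np.asarray(roi_means, dtype=np.float64)
    if means.size < 2:
        raise ValueError("need at least 2 background ROI means")
    if C_B is None:
        C_B = float(means.mean())
    if C_B == 0:
        raise ValueError("C_B must be nonzero")
    sd = float(np.sqrt(np.sum((means - means.mean()) ** 2) / (means.size - 1)))
    return BackgroundVariabilityResult(
        sphere_diameter_mm=sphere_diameter_mm,
        sd=sd,
        percent_bv=100.0 * sd / C_B,
    )


def analyze_nema(
    vol: ImageVolume,
    labels: LabelVolume,
    spec: NemaIQSpec,
    positions_mm: list[tuple[float, float]] | None = None,
) -> tuple[list[ContrastResult], list[BackgroundVariabilityResult]]:
    """Full NEMA analysis of one reconstructed volume: per-sphere contrast
    (hot or cold) and background variability."""
    spheres = place_sphere_rois(vol, labels, spec)
    bg = place_background_rois(vol, labels, spec, positions_mm)
    a_B = spec.background_concentration
    a_H = spec.hot_to_background_ratio * a_B
    contrasts, bvs = [], []
    for s in spheres:
        C_B = bg[s.sphere_diameter_mm].C_B
        if s.is_cold:
            pc = percent_contrast_cold(s.mean_counts, C_B)
        else:
            pc = percent_contrast_hot(s.mean_counts, C_B, a_H, a_B)
        contrasts.append(
            ContrastResult(s.sphere_diameter_mm, pc, s.is_cold, a_H, a_B)
        )
        bv = background_variability(
            bg[s.sphere_diameter_mm].roi_means,
            sphere_diameter_mm=s.sphere_diameter_mm,
        )
        bvs.append(bv)
    return contrasts, bvs
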