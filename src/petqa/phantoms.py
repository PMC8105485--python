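"""Digital activity phantoms and the simulated acquisition chain.

Two phantoms are provided:

* a NEMA image-quality body phantom — six fillable spheres (four hot at a
  configurable activity ratio over a warm background, two cold) on a ring
  inside a cylindrical body;
* a procedurally generated brain-like surrogate of the Hoffman 3D phantom —
  a folded gray-matter shell over a white-matter interior, two ellipsoidal
  putamina, and a dedicated zero-activity white-matter background VOI.

The surrogate is not an anatomical atlas: it reproduces the features the
image-quality metrics depend on (GM/WM contrast, a small bright nucleus, a
cold background region, rich spatial structure at cortical-fold scale) with
seeded, reproducible geometry.

Acquisition is simulated by slice-wise parallel-beam forward projection
(:func:`petqa.projector.forward_project`, re-exported here) followed by
Poisson count noise at a prescribed expected total count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import forward_project  # noqa: F401  (re-export: acquisition op)
from .volumes import GeometryError, Grid, ImageVolume, LabelVolume, Sinogram

__all__ = [
    "NemaIQSpec",
    "HoffmanSurrogateSpec",
    "generate_nema_phantom",
    "generate_hoffman_surrogate",
    "forward_project",
    "add_poisson_noise",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NemaIQSpec:
    """Geometry and activity of the NEMA IQ phantom.

    Defaults follow the study conditions: sphere diameters 10–39 mm, the two
    largest spheres cold, background 5.6 kBq/mL and a 4:1 hot-to-background
    activity ratio (22.4 versus 5.6 kBq/mL).
    """

    sphere_diameters_mm: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 30.0, 39.0)
    cold_sphere_indices: frozenset[int] = frozenset({4, 5})
    background_concentration: float = 5.6
    hot_to_background_ratio: float = 4.0
    ring_radius_mm: float = 57.2
    center_slice_mm: float | None = None
    body_radius_mm: float = 140.0
    body_half_length_mm: float = 55.0

    def __post_init__(self) -> None:
        d = np.asarray(self.sphere_diameters_mm)
        if np.any(np.diff(d) <= 0):
            raise ValueError("sphere diameters must be strictly increasing")
        if self.hot_to_background_ratio <= 1 and self.hot_to_background_ratio != 1:
            raise ValueError("hot_to_background_ratio must be >= 1")
        if not set(self.cold_sphere_indices) <= set(range(len(d))):
            raise ValueError("cold sphere indices must index the sphere list")

    def sphere_centers_mm(self, center_z: float = 0.0) -> np.ndarray:
        """Sphere centres on the placement ring, 60 degrees apart."""
        k = np.arange(len(self.sphere_diameters_mm))
        ang = np.deg2rad(60.0 * k)
        return np.column_stack(
            [
                self.ring_radius_mm * np.cos(ang),
                self.ring_radius_mm * np.sin(ang),
                np.full_like(ang, center_z),
            ]
        )


@dataclass(frozen=True)
class HoffmanSurrogateSpec:
    """Parameters of the brain-like surrogate phantom.

    ``wm_activity_mode='devoid'`` sets white matter to zero activity (the
    background VOI assumption of the SNR metric); ``'scaled'`` fills white
    matter at ``1/gm_wm_ratio`` of gray.  The dedicated ``wm_background_voi``
    region has exactly zero activity in both modes.
    """

    gm_wm_ratio: float = 4.0
    putamen_volume_mm3: float = 2400.0
    wm_activity_mode: str = "devoid"
    seed: int = 0
    gray_activity: float = 1.0
    brain_semiaxes_frac: tuple[float, float, float] = (0.40, 0.44, 0.42)
    fold_depth: float = 0.10
    shell_inner_rho: float = 0.70

    def __post_init__(self) -> None:
        if self.gm_wm_ratio < 1:
            raise ValueError("gm_wm_ratio must be >= 1")
        if self.putamen_volume_mm3 <= 0:
            raise ValueError("putamen_volume_mm3 must be > 0")
        if self.wm_activity_mode not in ("scaled", "devoid"):
            raise ValueError("wm_activity_mode must be 'scaled' or 'devoid'")


def _sphere_mask(grid: Grid, center: np.ndarray, radius: float) -> np.ndarray:
    """Voxel-centre-inside-sphere mask (the documented membership rule)."""
    x, y, z = grid.coords_mm()
    dx2 = (x[:, None, None] - center[0]) ** 2
    dy2 = (y[None, :, None] - center[1]) ** 2
    dz2 = (z[None, None, :] - center[2]) ** 2
    return dx2 + dy2 + dz2 <= radius**2


def generate_nema_phantom(
    spec: NemaIQSpec, grid: Grid
) -> tuple[ImageVolume, LabelVolume]:
    """Voxelize the NEMA IQ phantom onto ``grid``.

    Returns the activity volume (hot spheres at ``ratio x background``, cold
    spheres at zero) and a label volume with legend ``background`` (the warm
    body) and ``sphere_k`` for k = 0..n-1 ordered by diameter.
    """
    x, y, z = grid.coords_mm()
    center_z = 0.0 if spec.center_slice_mm is None else spec.center_slice_mm
    radii = np.asarray(spec.sphere_diameters_mm) / 2.0

    half_x = (x[-1] - x[0]) / 2.0 + grid.voxel_size[0] / 2.0
    half_y = (y[-1] - y[0]) / 2.0 + grid.voxel_size[1] / 2.0
    for r, c in zip(radii, spec.sphere_centers_mm(center_z)):
        if (
            abs(c[0]) + r > half_x
            or abs(c[1]) + r > half_y
            or c[2] - r < z[0]
            or c[2] + r > z[-1]
        ):
            raise GeometryError(
                f"sphere of radius {r} mm at {c} extends outside the field of view"
            )
        if np.hypot(c[0], c[1]) + r > spec.body_radius_mm:
            raise GeometryError("sphere ring does not fit inside the phantom body")

    body = (
        (x[:, None, None] ** 2 + y[None, :, None] ** 2 <= spec.body_radius_mm**2)
        & (np.abs(z[None, None, :] - center_z) <= spec.body_half_length_mm)
    )
    labels = np.where(body, 1, 0).astype(np.int32)
    activity = np.where(body, spec.background_concentration, 0.0)

    legend = {1: "background"}
    for k, (r, c) in enumerate(zip(radii, spec.sphere_centers_mm(center_z))):
        m = _sphere_mask(grid, c, r)
        labels[m] = 2 + k
        legend[2 + k] = f"sphere_{k}"
        if k in spec.cold_sphere_indices:
            activity[m] = 0.0
        else:
            activity[m] = spec.hot_to_background_ratio * spec.background_concentration

    return (
        ImageVolume(activity, grid.voxel_size),
        LabelVolume(labels, grid.voxel_size, legend),
    )


def _putamen_semiaxes(volume_mm3: float) -> np.ndarray:
    """Ellipsoid semi-axes with anatomical-ish 1 : 1.8 : 1.1 proportions whose
    analytic volume equals ``volume_mm3``."""
    ratios = np.array([1.0, 1.8, 1.1])
    r = (volume_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    return r * ratios


def _ellipsoid_mask(grid: Grid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    x, y, z = grid.coords_mm()
    q = (
        ((x[:, None, None] - center[0]) / semi[0]) ** 2
        + ((y[None, :, None] - center[1]) / semi[1]) ** 2
        + ((z[None, None, :] - center[2]) / semi[2]) ** 2
    )
    return q <= 1.0


def generate_hoffman_surrogate(
    spec: HoffmanSurrogateSpec, grid: Grid
) -> tuple[ImageVolume, LabelVolume]:
    """Generate the brain-like surrogate phantom.

    The cortical shell is the set of voxels whose normalised ellipsoidal
    radius rho lies between a folded inner surface and 1; the fold pattern is
    a seeded sum of angular/axial harmonics, giving reproducible gyrus-scale
    structure in all three axes.
    """
    ext = grid.extent_mm
    semi = np.array([f * e for f, e in zip(spec.brain_semiaxes_frac, ext)])
    x, y, z = grid.coords_mm()
    xs = x[:, None, None] / semi[0]
    ys = y[None, :, None] / semi[1]
    zs = z[None, None, :] / semi[2]
    rho = np.sqrt(xs**2 + ys**2 + zs**2)

    rng = np.random.default_rng(spec.seed)
    p1, p2, p3, p4 = rng.uniform(0.0, 2.0 * np.pi, size=4)
    phi = np.arctan2(ys, xs)
    folds = (
        np.sin(7.0 * phi + p1) * np.cos(3.0 * np.pi * zs + p2)
        + 0.6 * np.sin(11.0 * phi + p3) * np.cos(5.0 * np.pi * zs + p4)
    )
    rho_in = spec.shell_inner_rho + spec.fold_depth * folds

    brain = rho <= 1.0
    gray = brain & (rho > rho_in)
    white = brain & ~gray

    brain_volume = brain.sum() * grid.voxel_size[0] * grid.voxel_size[1] * grid.voxel_size[2]
    if spec.putamen_volume_mm3 > 0.10 * brain_volume:
        raise ValueError(
            f"requested putamen volume {spec.putamen_volume_mm3} mm^3 exceeds "
            f"10% of the brain region ({brain_volume:.0f} mm^3)"
        )

    put_semi = _putamen_semiaxes(spec.putamen_volume_mm3)
    put_r = _ellipsoid_mask(grid, np.array([0.28 * semi[0], 0.10 * semi[1], 0.0]), put_semi)
    put_l = _ellipsoid_mask(grid, np.array([-0.28 * semi[0], 0.10 * semi[1], 0.0]), put_semi)
    wm_voi = _ellipsoid_mask(grid, np.array([0.0, -0.36 * semi[1], 0.0]), put_semi)
    if not (put_r & white).any() or not (wm_voi & white).any():
        raise GeometryError("grid too small to host the putamen / background VOIs")

    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[gray] = 1
    labels[white] = 2
    labels[put_r] = 3
    labels[put_l] = 4
    labels[wm_voi] = 5
    legend = {1: "gray", 2: "white", 3: "putamen_R", 4: "putamen_L", 5: "wm_background_voi"}

    wm_level = 0.0 if spec.wm_activity_mode == "devoid" else spec.gray_activity / spec.gm_wm_ratio
    activity = np.zeros(grid.shape)
    activity[labels == 2] = wm_level
    activity[labels == 1] = spec.gray_activity
    activity[labels == 3] = spec.gray_activity
    activity[labels == 4] = spec.gray_activity
    activity[labels == 5] = 0.0

    return (
        ImageVolume(activity, grid.voxel_size),
        LabelVolume(labels, grid.voxel_size, legend),
    )


def add_poisson_noise(
    sino: Sinogram, expected_total_counts: float, seed: int
) -> Sinogram:
    """Scale the sinogram to a prescribed expected total count and draw
    independent Poisson counts per bin (reproducible per seed)."""
    if expected_total_counts <= 0:
        raise ValueError("expected_total_counts must be > 0")
    total = sino.counts.sum()
    if total == 0:
        counts = np.zeros_like(sino.counts)
    else:
        rng = np.random.default_rng(seed)
        lam = sino.counts * (expected_total_counts / total)
        counts = rng.poisson(lam).astype(np.float64)
    return Sinogram(counts, sino.angles.copy(), sino.radial_spacing_mm, sino.slice_thickness_mm)
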