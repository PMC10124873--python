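"""Synthetic micro-CT phantoms of a double-disk mesh occluder.

Generates volumes that emulate an ex-vivo micro-CT scan of a nitinol
double-disk septal occluder with partial tissue coverage:

* a strongly attenuating wire lattice — two parallel mesh disks (two
  orthogonal families of straight wire splines plus a rim ring) joined by a
  tubular waist;
* a mid-intensity tissue cap on the outer (atrial) face of each disk whose
  footprint is controlled by a coverage fraction and pattern (annular growth
  from the rim, growth from the center, or random patches);
* an optional myocardium annulus in the inter-disk plane;
* additive Gaussian noise and an optional rigid rotation of the image.

The ground truth (wire/tissue masks, ideal solid occluder, per-disk coverage
percentages and thickness maps) is stored in the unrotated, noise-free frame;
true coverage is a direct pixel count of tissue-bearing footprint pixels over
all footprint pixels — the same definition the quantification stage uses.

The default phantom is a scaled-down device on a 128×128×96 grid (disk radius
40 voxels, mesh pitch 10, wire 4 voxels ≈ 170 μm at the 41.7 μm default voxel
size).  At this scale the mesh-bridging fill reach is 18 voxels rather than
the full-size 70 (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_io import BinaryVolume, IntensityVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "edge_coverage_pattern",
    "coverage_pattern_mask",
    "study_cohort_specs",
    "PHANTOM_FILL_REACH_VOX",
]

#: fill reach (voxels) matched to the default phantom geometry: it exceeds the
#: mesh half-gap diagonal (so gaps bridge) and stays below the outer-face z
#: margin (so the fill keeps an in-grid background complement).
PHANTOM_FILL_REACH_VOX = 18

_PATTERNS = ("full_from_edge", "full_from_center", "random_patches")


@dataclass
class PhantomSpec:
    """Generator parameters; defaults define the standard study-like phantom."""

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    voxel_size_um: float = 41.7
    disk_radius_vox: int = 40
    disk_separation_vox: int = 30
    wire_thickness_vox: int = 4
    mesh_pitch_vox: int = 10
    waist_radius_vox: int = 8
    coverage_fraction_left: float = 1.0
    coverage_fraction_right: float = 0.55
    coverage_pattern: str | tuple[str, str] = "full_from_edge"
    tissue_thickness_vox: int | tuple[int, int] = 3
    intensity_metal: int = 60000
    intensity_tissue: int = 25000
    intensity_myocardium: int = 18000
    intensity_background: int = 5000
    include_myocardium: bool = True
    noise_sd: float = 0.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx, nz = self.grid_shape
        if min(ny, nx, nz) <= 0:
            raise ValueError("grid_shape must be positive")
        if not (
            self.intensity_metal > self.intensity_tissue > 15000 > self.intensity_background >= 0
        ):
            raise ValueError(
                "intensity ordering metal > tissue > 15000 > background violated"
            )
        if self.wire_thickness_vox < 1:
            raise ValueError("wire_thickness_vox must be >= 1")
        if self.mesh_pitch_vox <= self.wire_thickness_vox:
            raise ValueError("mesh_pitch_vox must exceed wire_thickness_vox")
        if self.mesh_pitch_vox > 70:
            raise ValueError("mesh_pitch_vox must be <= 70 so the fill can bridge gaps")
        for f in (self.coverage_fraction_left, self.coverage_fraction_right):
            if not 0.0 <= f <= 1.0:
                raise ValueError("coverage fractions must lie in [0, 1]")
        for p in self.patterns:
            if p not in _PATTERNS:
                raise ValueError(f"unknown coverage pattern {p!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # geometric fit
        t_l, t_r = self.tissue_thicknesses
        z_extent = 2 * self.wire_thickness_vox + self.disk_separation_vox
        z_margin = (nz - z_extent) // 2
        if z_margin < max(t_l, t_r) + 2:
            raise ValueError("device does not fit along z (tissue caps clipped)")
        if self.disk_radius_vox + 1 > min(ny, nx) // 2:
            raise ValueError("disk radius does not fit in the grid")
        if not 0 < self.waist_radius_vox < self.disk_radius_vox:
            raise ValueError("waist radius must be positive and below the disk radius")

    @property
    def patterns(self) -> tuple[str, str]:
        p = self.coverage_pattern
        return (p, p) if isinstance(p, str) else (p[0], p[1])

    @property
    def tissue_thicknesses(self) -> tuple[int, int]:
        t = self.tissue_thickness_vox
        return (t, t) if isinstance(t, (int, np.integer)) else (int(t[0]), int(t[1]))


@dataclass
class GroundTruth:
    """True labels of a phantom in the unrotated, noise-free frame."""

    wire_mask: BinaryVolume
    tissue_mask: BinaryVolume
    solid_mask: BinaryVolume  # ideal filled occluder (solid disks + waist)
    true_coverage_percent_left: float
    true_coverage_percent_right: float
    true_thickness_map_left: np.ndarray  # mm, full XY grid
    true_thickness_map_right: np.ndarray
    z_split: int  # waist mid-plane index
    applied_rotation: np.ndarray  # 3×3 matrix on (y,x,z) voxel coords
    device_axis: np.ndarray  # unit device axis in the *image* frame


def _radii(shape2d: tuple[int, int]) -> np.ndarray:
    ny, nx = shape2d
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y, x = np.mgrid[0:ny, 0:nx]
    return np.hypot(y - cy, x - cx)


def edge_coverage_pattern(disk_radius_vox: int, fraction: float) -> np.ndarray:
    """Annular pixel mask growing inward from the disk rim.

    Covers the requested ``fraction`` of the disk's pixel area within one
    pixel ring: the inner radius solves π(R² − r²) = f·πR², i.e.
    r = R·√(1 − f).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    R = disk_radius_vox
    r = _radii((2 * R + 1, 2 * R + 1))
    disk = r <= R
    if fraction == 0.0:
        return np.zeros_like(disk)
    inner = R * np.sqrt(1.0 - fraction)
    return disk & (r >= inner)


def coverage_pattern_mask(
    shape2d: tuple[int, int],
    disk_radius_vox: int,
    fraction: float,
    pattern: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """2D covered-pixel mask over the full grid footprint of one disk."""
    r = _radii(shape2d)
    R = disk_radius_vox
    disk = r <= R
    if fraction <= 0.0:
        return np.zeros_like(disk)
    if fraction >= 1.0:
        return disk
    if pattern == "full_from_edge":
        return disk & (r >= R * np.sqrt(1.0 - fraction))
    if pattern == "full_from_center":
        return disk & (r <= R * np.sqrt(fraction))
    if pattern == "random_patches":
        fld = ndimage.gaussian_filter(rng.standard_normal(shape2d), sigma=R / 5.0)
        cut = np.quantile(fld[disk], 1.0 - fraction)
        return disk & (fld >= cut)
    raise ValueError(f"unknown coverage pattern {pattern!r}")


def _mesh_disk(
    shape: tuple[int, int, int], z0: int, spec: PhantomSpec
) -> np.ndarray:
    """Wire lattice of one disk: two orthogonal spline families plus a rim."""
    ny, nx, nz = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = _radii((ny, nx))
    R, w, pitch = spec.disk_radius_vox, spec.wire_thickness_vox, spec.mesh_pitch_vox
    y, x = np.mgrid[0:ny, 0:nx]
    bands = (np.mod(y - int(cy), pitch) < w) | (np.mod(x - int(cx), pitch) < w)
    rim = r > R - w
    plane = (bands | rim) & (r <= R)
    out = np.zeros(shape, dtype=bool)
    out[:, :, z0 : z0 + w] = plane[:, :, None]
    return out


def _device_geometry(spec: PhantomSpec) -> dict:
    ny, nx, nz = spec.grid_shape
    w, sep = spec.wire_thickness_vox, spec.disk_separation_vox
    z_left = (nz - (2 * w + sep)) // 2
    z_right = z_left + w + sep
    return {
        "z_left": z_left,  # left disk slab [z_left, z_left + w)
        "z_right": z_right,  # right disk slab [z_right, z_right + w)
        "z_split": z_left + w + sep // 2,
    }


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, GroundTruth]:
    """Render a phantom volume and its ground truth.

    The label volume (background / myocardium / tissue / metal) is built in
    the axis-aligned frame, optionally rotated (linear interpolation), and
    Gaussian noise of sd ``noise_sd`` is added afterwards in the image frame.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx, nz = spec.grid_shape
    geo = _device_geometry(spec)
    w = spec.wire_thickness_vox
    r2d = _radii((ny, nx))
    R = spec.disk_radius_vox

    wire = _mesh_disk(spec.grid_shape, geo["z_left"], spec)
    wire |= _mesh_disk(spec.grid_shape, geo["z_right"], spec)
    waist_band = (r2d <= spec.waist_radius_vox) & (
        r2d > spec.waist_radius_vox - spec.wire_thickness_vox
    )
    wire[:, :, geo["z_left"] + w : geo["z_right"]] |= waist_band[:, :, None]

    # tissue caps on the outer faces
    t_l, t_r = spec.tissue_thicknesses
    pat_l, pat_r = spec.patterns
    cov_l = coverage_pattern_mask((ny, nx), R, spec.coverage_fraction_left, pat_l, rng)
    cov_r = coverage_pattern_mask((ny, nx), R, spec.coverage_fraction_right, pat_r, rng)
    tissue = np.zeros(spec.grid_shape, dtype=bool)
    tissue[:, :, geo["z_left"] - t_l : geo["z_left"]] = cov_l[:, :, None]
    tissue[:, :, geo["z_right"] + w : geo["z_right"] + w + t_r] = cov_r[:, :, None]
    tissue &= ~wire

    # ideal solid occluder: solid disk slabs + solid waist
    solid = np.zeros(spec.grid_shape, dtype=bool)
    footprint = r2d <= R
    solid[:, :, geo["z_left"] : geo["z_left"] + w] = footprint[:, :, None]
    solid[:, :, geo["z_right"] : geo["z_right"] + w] = footprint[:, :, None]
    solid[:, :, geo["z_left"] + w : geo["z_right"]] |= (
        r2d <= spec.waist_radius_vox
    )[:, :, None]

    vol = np.full(spec.grid_shape, float(spec.intensity_background))
    if spec.include_myocardium and spec.disk_separation_vox > 6:
        myo_band = (r2d > spec.waist_radius_vox + 3) & (r2d <= R)
        z0, z1 = geo["z_left"] + w + 2, geo["z_right"] - 2
        myo = np.zeros(spec.grid_shape, dtype=bool)
        myo[:, :, z0:z1] = myo_band[:, :, None]
        myo &= ~wire
        vol[myo] = spec.intensity_myocardium
    vol[tissue] = spec.intensity_tissue
    vol[wire] = spec.intensity_metal

    rot = _rotation_matrix(spec.rotation_deg)
    if not np.allclose(rot, np.eye(3)):
        center = (np.asarray(spec.grid_shape, dtype=float) - 1) / 2.0
        inv = rot.T
        offset = center - inv @ center
        vol = ndimage.affine_transform(
            vol, inv, offset=offset, order=1, cval=float(spec.intensity_background)
        )
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    vol = np.clip(np.rint(vol), 0, 65535).astype(np.uint16)

    n_foot = int(footprint.sum())
    mm = spec.voxel_size_um / 1000.0
    truth = GroundTruth(
        wire_mask=BinaryVolume(wire, spec.voxel_size_um),
        tissue_mask=BinaryVolume(tissue, spec.voxel_size_um),
        solid_mask=BinaryVolume(solid, spec.voxel_size_um),
        true_coverage_percent_left=100.0 * int(cov_l.sum()) / n_foot,
        true_coverage_percent_right=100.0 * int(cov_r.sum()) / n_foot,
        true_thickness_map_left=np.where(cov_l, t_l * mm, 0.0),
        true_thickness_map_right=np.where(cov_r, t_r * mm, 0.0),
        z_split=geo["z_split"],
        applied_rotation=rot,
        device_axis=rot @ np.array([0.0, 0.0, 1.0]),
    )
    return IntensityVolume(vol, spec.voxel_size_um), truth


def _rotation_matrix(rotation_deg: tuple[float, float, float]) -> np.ndarray:
    """Rotation on (y, x, z) voxel coordinates from extrinsic x/y/z angles."""
    from scipy.spatial.transform import Rotation

    rx, ry, rz = rotation_deg
    m_xyz = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
    perm = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # (y,x,z)->(x,y,z)
    return perm.T @ m_xyz @ perm


def study_cohort_specs(
    base: PhantomSpec | None = None, seed: int = 0
) -> list[dict]:
    """Eight-device synthetic cohort emulating the study's reported pattern.

    Devices 1–3 form the 1-month group, 4–8 the 3-month group.  Right disks
    of devices 1–5 carry edge-only partial coverage; 6–8 are (near-)fully
    covered.  Left disks are near-complete with center-anchored coverage and
    thicker caps.  Fractions are fixed so cohort medians match the reported
    coverage distribution (left 93 %, right 55 %; 1-month right 41 %).
    """
    base = base or PhantomSpec()
    left = [0.80, 0.86, 0.88, 0.93, 0.93, 0.95, 1.0, 1.0]
    right = [0.30, 0.41, 0.50, 0.55, 0.55, 0.95, 1.0, 1.0]
    groups = ["1-month"] * 3 + ["3-month"] * 5
    cohort = []
    for i, (fl, fr, grp) in enumerate(zip(left, right, groups), start=1):
        spec = replace(
            base,
            coverage_fraction_left=fl,
            coverage_fraction_right=fr,
            coverage_pattern=("full_from_center", "full_from_edge"),
            tissue_thickness_vox=(4, 2),
            seed=seed + i,
        )
        cohort.append({"device_id": f"device_{i}", "follow_up_group": grp, "spec": spec})
    return cohort
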