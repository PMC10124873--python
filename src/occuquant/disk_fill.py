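"""Solid-disk reconstruction from a segmented wire mesh.

The occluder is a woven nitinol mesh: a plain intensity segmentation yields
wires with empty space between the splines, but coverage quantification needs
the *surface* the tissue grows over.  The mesh is therefore made solid by

1. a chamfer distance transform from the wire voxels,
2. an upper threshold on that distance map (default 70 voxels, which at the
   41.7 μm study resolution is a physical reach of 2.919 mm) — this bridges
   every inter-spline gap, and
3. an erosion/closing regime that shrinks the thick slab back to the original
   wire thickness while keeping the bridged gaps filled.

With the erosion radius equal to the fill threshold, steps 2–3 amount to a
morphological closing in the chosen distance metric: the result contains every
wire voxel and its thickness along face directions equals the wire's.

The chamfer transform uses the classic two-pass sweep with integer weights
(face, edge, corner) = (3, 4, 5)/3, augmented with the knight-type step
(2,1,1) at weight 7/3.  The augmentation bounds the worst-case deviation from
exact Euclidean distance to +5.4 % / −5.7 % (the plain (3,4,5) mask errs by up
to +10.6 % in (3,1,1)-type directions); face steps remain exact, so axial
reaches expressed in voxels keep their physical meaning.  An exact-Euclidean
backend (scipy EDT) is available with the identical downstream contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .volume_io import BinaryVolume

__all__ = [
    "DistanceVolume",
    "FillParams",
    "chamfer_distance",
    "distance_map",
    "fill_by_distance",
    "erode_and_close",
]

#: integer chamfer step weights (scaled ×3): face, edge, corner, knight(2,1,1)
CHAMFER_WEIGHTS = (3, 4, 5, 7)


def _half_neighborhood() -> tuple[np.ndarray, np.ndarray]:
    """Offsets finalized before (0,0,0) in a (y, x, z) raster scan, + weights."""
    classes = {(1, 0, 0): 3, (1, 1, 0): 4, (1, 1, 1): 5, (2, 1, 1): 7}
    offs, ws = [], []
    for base, w in classes.items():
        for perm in set(itertools.permutations(base)):
            signs = [(-1, 1) if c else (1,) for c in perm]
            for s in itertools.product(*signs):
                v = tuple(a * b for a, b in zip(perm, s))
                dy, dx, dz = v
                if dy < 0 or (dy == 0 and dx < 0) or (dy == 0 and dx == 0 and dz < 0):
                    offs.append(v)
                    ws.append(w)
    return np.asarray(offs, dtype=np.int64), np.asarray(ws, dtype=np.int32)


_FWD_OFFS, _FWD_WS = _half_neighborhood()


@njit(cache=True)
def _sweep(dist, offs, ws, forward):  # pragma: no cover - exercised via chamfer_distance
    ny, nx, nz = dist.shape
    n_off = offs.shape[0]
    ys = range(ny) if forward else range(ny - 1, -1, -1)
    for y in ys:
        xs = range(nx) if forward else range(nx - 1, -1, -1)
        for x in xs:
            zs = range(nz) if forward else range(nz - 1, -1, -1)
            for z in zs:
                d = dist[y, x, z]
                for k in range(n_off):
                    yy = y + offs[k, 0]
                    xx = x + offs[k, 1]
                    zz = z + offs[k, 2]
                    if 0 <= yy < ny and 0 <= xx < nx and 0 <= zz < nz:
                        cand = dist[yy, xx, zz] + ws[k]
                        if cand < d:
                            d = cand
                dist[y, x, z] = d


@dataclass
class DistanceVolume:
    """Distance-to-wire map in voxel units (0 exactly on wire voxels)."""

    data: np.ndarray
    voxel_size_um: float
    chamfer_weights: tuple | None = CHAMFER_WEIGHTS

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_mm(self) -> np.ndarray:
        return self.data * (self.voxel_size_um / 1000.0)


@dataclass
class FillParams:
    """Parameters of the mesh-fill regime.

    distance_threshold_vox
        Reach of the fill in voxels; the default 70 reproduces the physical
        threshold 70 × 41.7 μm = 2.919 mm at the study resolution.
    wire_thickness_vox
        Nominal wire thread thickness in voxels (170 μm ≈ 4 at 41.7 μm).
    closing_radius_vox
        Radius of the pinhole-removing closing applied after erosion;
        defaults to the wire thickness.
    erosion_radius_vox
        Radius of the slab-shrinking erosion; defaults to
        ``distance_threshold_vox`` so that fill + erode is a closing and the
        slab returns to the original wire thickness.
    distance_backend
        ``"chamfer"`` (two-pass, weights (3,4,5,7)/3) or ``"euclidean"``
        (exact EDT); also used for the erosion/closing metric.
    """

    distance_threshold_vox: float = 70.0
    wire_thickness_vox: int = 4
    closing_radius_vox: int | None = None
    erosion_radius_vox: float | None = None
    distance_backend: str = "chamfer"

    def __post_init__(self) -> None:
        if self.distance_threshold_vox <= 0:
            raise ValueError("distance_threshold_vox must be positive")
        if self.wire_thickness_vox < 1:
            raise ValueError("wire_thickness_vox must be >= 1")
        if self.distance_backend not in ("chamfer", "euclidean"):
            raise ValueError(f"unknown distance backend {self.distance_backend!r}")
        if self.closing_radius_vox is None:
            self.closing_radius_vox = self.wire_thickness_vox

    @property
    def erosion_radius(self) -> float:
        r = (
            self.erosion_radius_vox
            if self.erosion_radius_vox is not None
            else self.distance_threshold_vox
        )
        return float(r)

    @property
    def physical_reach_mm(self) -> float | None:
        return None  # reach in mm depends on voxel size; see reach_mm()

    def reach_mm(self, voxel_size_um: float) -> float:
        """Physical fill reach implied by the voxel threshold."""
        return self.distance_threshold_vox * voxel_size_um / 1000.0


def distance_map(mask: np.ndarray, backend: str = "chamfer") -> np.ndarray:
    """Distance (in voxel units) from every voxel to the nearest True voxel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: distance map is undefined")
    if backend == "euclidean":
        return ndimage.distance_transform_edt(~mask).astype(np.float32)
    if backend != "chamfer":
        raise ValueError(f"unknown distance backend {backend!r}")
    big = np.int32(3 * sum(mask.shape) + 100)
    dist = np.where(mask, np.int32(0), big).astype(np.int32)
    _sweep(dist, _FWD_OFFS, _FWD_WS, True)
    _sweep(dist, -_FWD_OFFS, _FWD_WS, False)
    return (dist / 3.0).astype(np.float32)


def chamfer_distance(wire_mask: BinaryVolume, backend: str = "chamfer") -> DistanceVolume:
    """Distance transform from the segmented wire, in voxel units."""
    data = distance_map(wire_mask.data, backend=backend)
    weights = CHAMFER_WEIGHTS if backend == "chamfer" else None
    return DistanceVolume(
        data=data, voxel_size_um=wire_mask.voxel_size_um, chamfer_weights=weights
    )


def fill_by_distance(dist: DistanceVolume, params: FillParams) -> BinaryVolume:
    """Threshold the distance map to bridge all inter-spline mesh gaps.

    The result is by construction a superset of the wire mask and fills every
    gap of pitch below twice the threshold.
    """
    if params.distance_threshold_vox <= 0:
        raise ValueError("distance threshold must be positive")
    return BinaryVolume(
        data=dist.data <= params.distance_threshold_vox,
        voxel_size_um=dist.voxel_size_um,
    )


def _erode(
    mask: np.ndarray,
    radius: float,
    backend: str,
    full_ok: bool = False,
    strict: bool = True,
) -> np.ndarray:
    # ball erosion by distance thresholding; out-of-grid counts as foreground.
    # strict=True erodes by the closed ball (keep dist > r); strict=False by
    # the open ball (keep dist >= r), which the closing uses so that face pits
    # lying at exactly the closing radius from the dilated complement fill.
    if not (~mask).any():
        if full_ok:
            return mask.copy()
        raise ValueError(
            "fill covers the whole grid: no background left to erode from "
            "(fill reach too large for this volume)"
        )
    d = distance_map(~mask, backend=backend)
    return d > radius if strict else d >= radius


def _dilate(mask: np.ndarray, radius: float, backend: str) -> np.ndarray:
    return distance_map(mask, backend=backend) <= radius


def erode_and_close(filled: BinaryVolume, params: FillParams) -> BinaryVolume:
    """Shrink the distance fill back to wire thickness, keeping gaps filled.

    Erosion by ``params.erosion_radius`` (default: the fill threshold, making
    fill + erosion a morphological closing of the wire mask) followed by a
    closing of radius ``closing_radius_vox`` to remove pinholes.  Structuring
    elements are metric balls realized by distance thresholding, in the same
    metric as the fill.
    """
    r = params.erosion_radius
    if r <= 0:
        raise ValueError("threshold smaller than wire thickness")
    backend = params.distance_backend
    eroded = _erode(filled.data, r, backend)
    if not eroded.any():
        return BinaryVolume(data=eroded, voxel_size_um=filled.voxel_size_um)
    c = params.closing_radius_vox
    if c and c > 0:
        dilated = _dilate(eroded, c, backend)
        eroded = _erode(dilated, c, backend, full_ok=True, strict=False)
    return BinaryVolume(data=eroded, voxel_size_um=filled.voxel_size_um)
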