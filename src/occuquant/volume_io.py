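"""Voxel-volume containers and TIFF stack I/O.

Volumes are stored as ``(y, x, z)`` arrays — slices of a scan are stacked on
the *last* axis, so a stack of ten 32×32 slices becomes a ``(32, 32, 10)``
volume.  The voxel size is isotropic and always carried explicitly (in μm):
micro-CT TIFF metadata conventions vary too much to trust tags, so the voxel
size comes from a sidecar metadata file or a caller argument, never from the
TIFF itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "IntensityVolume",
    "BinaryVolume",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_mask_stack",
    "write_mask_stack",
    "read_metadata",
    "write_metadata",
]

INTENSITY_MAX = 65535


@dataclass
class IntensityVolume:
    """A 3D grayscale voxel grid on the 16-bit scale with isotropic voxel size.

    Attributes
    ----------
    data : ndarray, shape (ny, nx, nz), uint16
        Reconstructed intensities in arbitrary units (AU).
    voxel_size_um : float
        Edge length of a voxel in μm, identical on all three axes.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s <= 0 for s in self.data.shape):
            raise ValueError(f"volume dimensions must be positive, got {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.data.dtype != np.uint16:
            if np.issubdtype(self.data.dtype, np.floating):
                raise TypeError("intensity volumes are integer-valued (16-bit scale)")
            if self.data.min() < 0 or self.data.max() > INTENSITY_MAX:
                raise ValueError("intensities must lie within [0, 65535]")
            self.data = self.data.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


@dataclass
class BinaryVolume:
    """A 3D boolean mask dimension-matched to the volume it derives from."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def _natural_key(name: str) -> list:
    """Sort key splitting digit runs so slice_2 orders before slice_10."""
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def _load_pages(path: Path) -> np.ndarray:
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"}),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = []
        shape = None
        for f in files:
            page = tifffile.imread(f)
            if page.ndim != 2:
                raise ValueError(f"slice {f.name} is not a single 2D page")
            if shape is None:
                shape = page.shape
            elif page.shape != shape:
                raise ValueError(
                    f"slice {f.name} has shape {page.shape}, expected {shape}"
                )
            slices.append(page)
        return np.stack(slices, axis=0)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return pages


def read_tiff_stack(path: str | Path, voxel_size_um: float) -> IntensityVolume:
    """Read a multi-page TIFF (or a directory of per-slice TIFFs) as a volume.

    Slices stack along z in file order; per-slice files are ordered by a
    natural-numeric sort of their names.  8-bit input is promoted to the
    16-bit container without rescaling the values.
    """
    pages = _load_pages(Path(path))
    if pages.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise TypeError(f"unsupported sample format {pages.dtype}; expected uint8/uint16")
    data = np.moveaxis(pages.astype(np.uint16), 0, -1)
    return IntensityVolume(data=data, voxel_size_um=voxel_size_um)


def write_tiff_stack(volume: IntensityVolume, path: str | Path) -> None:
    """Write a volume as a lossless 16-bit multi-page TIFF (z → pages)."""
    if volume.data.size == 0:
        raise ValueError("refusing to write an empty volume")
    tifffile.imwrite(Path(path), np.moveaxis(volume.data, -1, 0), photometric="minisblack")


def read_mask_stack(path: str | Path, voxel_size_um: float) -> BinaryVolume:
    """Read an 8-bit 0/255 TIFF stack back into a boolean mask."""
    pages = _load_pages(Path(path))
    return BinaryVolume(data=np.moveaxis(pages > 0, 0, -1), voxel_size_um=voxel_size_um)


def write_mask_stack(mask: BinaryVolume, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 multi-page TIFF."""
    if mask.data.size == 0:
        raise ValueError("refusing to write an empty mask")
    pages = np.moveaxis(mask.data.astype(np.uint8) * 255, -1, 0)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def write_metadata(meta: dict, path: str | Path) -> None:
    """Write sidecar metadata (voxel size, generator spec, seed) as YAML."""
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_metadata(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
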