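"""Per-disk coverage and thickness quantification.

After the device is aligned to z and made solid, the two disks are separated
at the waist — the z index of minimum occluder cross-sectional area between
the two largest-area peaks — and each disk is scanned column by column along
z, starting from its outer (atrial) face:

* the first tissue voxels encountered *before* the occluder surface are
  counted and converted to a thickness in mm (voxel count × voxel size);
* each XY pixel receives a label — 1 if the occluder was reached with no
  prior tissue (uncovered), 2 if tissue preceded the occluder (covered), and
  0 for background or tissue without any occluder in the column.

Coverage of a disk is the percentage of 2-labels among all non-zero labels.
A disk whose map holds no occluder-bearing pixel has *missing* coverage
(NaN), distinguishing "no device" from "0 % covered".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .volume_io import BinaryVolume

__all__ = [
    "DiskStack",
    "CoverageMap",
    "ThicknessMap",
    "CoverageSummary",
    "find_waist",
    "split_disks",
    "scan_column",
    "compute_maps",
    "coverage_percent",
    "thickness_stats",
    "summarize",
]


@dataclass
class DiskStack:
    """One disk's occluder and tissue masks plus its z-scan direction.

    ``scan_direction`` is "+z" when the disk's outer (atrial) face sits at
    low z (traversal from index 0 inward) and "-z" when it sits at high z.
    """

    occluder_mask: BinaryVolume
    tissue_mask: BinaryVolume
    side: str  # "left" | "right"
    scan_direction: str  # "+z" | "-z"
    voxel_size_um: float

    def __post_init__(self) -> None:
        if self.occluder_mask.shape != self.tissue_mask.shape:
            raise ValueError("occluder and tissue masks must share a shape")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.scan_direction not in ("+z", "-z"):
            raise ValueError("scan_direction must be '+z' or '-z'")


@dataclass
class CoverageMap:
    """2D XY label map: 0 background/tissue-only, 1 uncovered, 2 covered."""

    data: np.ndarray

    def counts(self) -> tuple[int, int, int]:
        return tuple(int((self.data == v).sum()) for v in (0, 1, 2))


@dataclass
class ThicknessMap:
    """2D XY tissue thickness in mm (0 where the column is not covered)."""

    data: np.ndarray
    voxel_size_um: float


def find_waist(occluder: BinaryVolume, min_peak_frac: float = 0.2) -> int:
    """z index of minimum cross-sectional area between the two disk peaks.

    The per-slice occluder area profile shows two plateaus (the disks); the
    waist is the argmin between the two highest peaks.  Ties resolve to the
    middle of the minimal plateau.  Raises if fewer than two peaks exist.
    """
    area = occluder.data.sum(axis=(0, 1)).astype(float)
    if area.max() <= 0:
        raise ValueError("empty occluder mask")
    prof = np.concatenate([[0.0], area, [0.0]])  # so edge plateaus count as peaks
    peaks, props = find_peaks(prof, height=min_peak_frac * area.max(), plateau_size=1)
    peaks -= 1
    if len(peaks) < 2:
        raise ValueError("no waist detectable: fewer than two disk area peaks")
    order = np.argsort(props["peak_heights"])[::-1]
    z1, z2 = sorted(peaks[order[:2]])
    between = area[z1 : z2 + 1]
    lo = between.min()
    idx = np.flatnonzero(between == lo)
    # middle of the minimal plateau; a symmetric waist splits into equal halves
    return int(z1 + idx[len(idx) // 2])


def split_disks(
    occluder: BinaryVolume,
    tissue: BinaryVolume,
    waist_profile: BinaryVolume | None = None,
    side_of_low_z: str = "left",
) -> tuple[DiskStack, DiskStack]:
    """Split the aligned device into left- and right-disk stacks at the waist.

    ``waist_profile`` optionally supplies the mask used for waist detection;
    the filled occluder of a real device has no area minimum (the fill reach
    far exceeds the inter-disk gap, so the closing fills the space between the
    disks), hence the pipeline passes the segmented *wire* mask here.

    The half at low z is labeled ``side_of_low_z`` ("left" by default: the
    left-atrial disk toward −z) and scans outward-in, i.e. "+z"; the other
    half scans "-z".
    """
    if occluder.shape != tissue.shape:
        raise ValueError("occluder and tissue shapes differ")
    if side_of_low_z not in ("left", "right"):
        raise ValueError("side_of_low_z must be 'left' or 'right'")
    z_split = find_waist(waist_profile if waist_profile is not None else occluder)
    vs = occluder.voxel_size_um

    def _stack(zslice: slice, side: str, direction: str) -> DiskStack:
        return DiskStack(
            occluder_mask=BinaryVolume(occluder.data[:, :, zslice].copy(), vs),
            tissue_mask=BinaryVolume(tissue.data[:, :, zslice].copy(), vs),
            side=side,
            scan_direction=direction,
            voxel_size_um=vs,
        )

    low = _stack(slice(0, z_split), side_of_low_z, "+z")
    other = "right" if side_of_low_z == "left" else "left"
    high = _stack(slice(z_split, occluder.shape[2]), other, "-z")
    if side_of_low_z == "left":
        return low, high
    return high, low


def scan_column(
    occluder_column: Sequence[bool], tissue_column: Sequence[bool]
) -> tuple[int, int]:
    """Scan one voxel column (ordered outside → inside).

    Returns ``(label, tissue_voxel_count)``: (2, n) if n ≥ 1 tissue voxels
    precede the first occluder voxel, (1, 0) if the occluder is reached with
    no prior tissue, (0, 0) if the column holds no occluder at all.
    """
    if len(occluder_column) != len(tissue_column):
        raise ValueError("columns must have equal length")
    count = 0
    for occ, tis in zip(occluder_column, tissue_column):
        if occ:
            return (2, count) if count > 0 else (1, 0)
        if tis:
            count += 1
    return (0, 0)


def compute_maps(disk: DiskStack) -> tuple[CoverageMap, ThicknessMap]:
    """Apply the column scan to every XY position of a disk stack."""
    occ = disk.occluder_mask.data
    tis = disk.tissue_mask.data
    if disk.scan_direction == "-z":
        occ = occ[:, :, ::-1]
        tis = tis[:, :, ::-1]

    has_occ = occ.any(axis=2)
    first_occ = np.argmax(occ, axis=2)  # 0 where has_occ is False; masked below
    cum = np.cumsum(tis, axis=2)
    # tissue voxels strictly before the first occluder voxel
    idx = np.clip(first_occ - 1, 0, occ.shape[2] - 1)
    counts = np.take_along_axis(cum, idx[:, :, None], axis=2)[:, :, 0]
    counts = np.where(first_occ > 0, counts, 0)
    counts = np.where(has_occ, counts, 0)

    labels = np.zeros(occ.shape[:2], dtype=np.uint8)
    labels[has_occ & (counts > 0)] = 2
    labels[has_occ & (counts == 0)] = 1

    mm = disk.voxel_size_um / 1000.0
    thickness = np.where(labels == 2, counts * mm, 0.0)
    return CoverageMap(labels), ThicknessMap(thickness, disk.voxel_size_um)


def coverage_percent(cov: CoverageMap) -> float:
    """100 · #(label 2) / #(labels 1 or 2); NaN when no occluder pixel exists."""
    _, n1, n2 = cov.counts()
    if n1 + n2 == 0:
        return float("nan")
    return 100.0 * n2 / (n1 + n2)


def thickness_stats(thick: ThicknessMap, cov: CoverageMap) -> dict:
    """Mean/median/max thickness in mm over covered pixels (NaN if none)."""
    vals = thick.data[cov.data == 2]
    if vals.size == 0:
        return {"thickness_mean_mm": float("nan"), "thickness_median_mm": float("nan"),
                "thickness_max_mm": float("nan")}
    return {
        "thickness_mean_mm": float(vals.mean()),
        "thickness_median_mm": float(np.median(vals)),
        "thickness_max_mm": float(vals.max()),
    }


@dataclass
class CoverageSummary:
    """Per-device, per-side result row."""

    device_id: str
    side: str
    follow_up_group: str
    coverage_percent: float
    thickness_mean_mm: float = float("nan")
    thickness_median_mm: float = float("nan")
    thickness_max_mm: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "device_id": self.device_id,
            "side": self.side,
            "follow_up_group": self.follow_up_group,
            "coverage_percent": self.coverage_percent,
            "thickness_mean_mm": self.thickness_mean_mm,
            "thickness_median_mm": self.thickness_median_mm,
            "thickness_max_mm": self.thickness_max_mm,
        }


def summarize(rows: Iterable[CoverageSummary]) -> pd.DataFrame:
    """Cohort table: median, mean and SD of coverage per side and per group.

    SD is the population standard deviation (ddof 0), so a single-device
    group reports 0 rather than NaN.  An "all" group aggregates every device
    of a side.  Mirrors the reporting convention median ± SD; both mean and
    median are emitted so either convention can be read.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("summarize needs at least one device")
    df = pd.DataFrame([r.as_dict() for r in rows])

    def _agg(sub: pd.DataFrame) -> dict:
        v = sub["coverage_percent"].dropna().to_numpy()
        if v.size == 0:
            return {"n": 0, "median": np.nan, "mean": np.nan, "sd": np.nan}
        return {
            "n": int(v.size),
            "median": float(np.median(v)),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=0)),
        }

    out = []
    groups = ["all"] + sorted(df["follow_up_group"].unique())
    for side in sorted(df["side"].unique()):
        for grp in groups:
            sub = df[df["side"] == side]
            if grp != "all":
                sub = sub[sub["follow_up_group"] == grp]
            if sub.empty:
                continue
            out.append({"side": side, "follow_up_group": grp, **_agg(sub)})
    return pd.DataFrame(out)
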