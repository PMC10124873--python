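"""Result export: three-tone coverage images, thickness heat maps, CSVs,
and a plain axis-aligned virtual-section extractor.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import PipelineResult
from .quantification import CoverageMap, ThicknessMap
from .volume_io import IntensityVolume

__all__ = [
    "three_tone_image",
    "save_three_tone_png",
    "save_thickness_png",
    "extract_slice",
    "save_map_csv",
    "save_device_outputs",
]

_AXES = {"y": 0, "x": 1, "z": 2}


def three_tone_image(cov: CoverageMap) -> np.ndarray:
    """uint8 rendering: covered = white (255), uncovered = grey (128),
    background = black (0)."""
    lut = np.array([0, 128, 255], dtype=np.uint8)
    return lut[cov.data]


def save_three_tone_png(cov: CoverageMap, path: str | Path) -> None:
    plt.imsave(Path(path), three_tone_image(cov), cmap="gray", vmin=0, vmax=255)


def save_thickness_png(
    thick: ThicknessMap, path: str | Path, vmax_mm: float | None = None
) -> None:
    """Thickness heat map (blue = thin, red = thick); pass a shared
    ``vmax_mm`` to keep one color scale across devices."""
    vmax = vmax_mm if vmax_mm else max(float(thick.data.max()), 1e-9)
    plt.imsave(Path(path), thick.data, cmap="jet", vmin=0.0, vmax=vmax)


def extract_slice(volume: IntensityVolume, axis: str, index: int) -> np.ndarray:
    """Axis-aligned virtual section through the volume (axis ∈ {x, y, z})."""
    if axis not in _AXES:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    ax = _AXES[axis]
    if not 0 <= index < volume.shape[ax]:
        raise IndexError(f"slice index {index} out of range for axis {axis}")
    return np.take(volume.data, index, axis=ax)


def save_map_csv(arr2d: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(arr2d).to_csv(Path(path), header=False, index=False)


def save_device_outputs(
    result: PipelineResult, out_dir: str | Path, vmax_mm: float | None = None
) -> dict:
    """Write per-device maps (CSV + PNG) and the summary CSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for side in ("left", "right"):
        cov = result.coverage_maps[side]
        thick = result.thickness_maps[side]
        base = f"{result.device_id}_{side}"
        save_map_csv(cov.data, out / f"{base}_coverage_map.csv")
        save_map_csv(np.round(thick.data, 6), out / f"{base}_thickness_map_mm.csv")
        save_three_tone_png(cov, out / f"{base}_coverage.png")
        save_thickness_png(thick, out / f"{base}_thickness.png", vmax_mm=vmax_mm)
        paths[side] = out / f"{base}_coverage_map.csv"
    summary = pd.DataFrame([r.as_dict() for r in result.summaries])
    summary_path = out / f"{result.device_id}_summary.csv"
    summary.to_csv(summary_path, index=False)
    paths["summary"] = summary_path
    return paths
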