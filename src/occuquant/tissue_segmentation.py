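"""Covering-tissue segmentation.

The filled occluder is deleted from the grayscale volume (its voxels set to
0), then a lower intensity threshold — 15000 AU on the 16-bit reconstruction
scale by default — separates covering tissue from residual background.  The
threshold is applied inclusively (≥) so results are bit-reproducible.

Myocardium far from the device can exceed the threshold too; by default the
tissue mask is additionally restricted to the fill-reach envelope (voxels
within the fill distance of the wire), so distant myocardium cannot inflate
coverage.  This restriction and an optional minimum-component-size despeckler
are configurable and off-by-default choices documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BinaryVolume, IntensityVolume

__all__ = ["TissueParams", "remove_occluder", "segment_tissue"]


@dataclass
class TissueParams:
    """Tissue segmentation parameters (threshold in AU, 16-bit scale)."""

    tissue_threshold_au: float = 15000.0
    restrict_to_fill_envelope: bool = True
    min_component_vox: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tissue_threshold_au < 65535:
            raise ValueError("tissue threshold must lie strictly within (0, 65535)")
        if self.min_component_vox < 0:
            raise ValueError("min_component_vox must be non-negative")


def remove_occluder(
    volume: IntensityVolume, filled_occluder: BinaryVolume
) -> IntensityVolume:
    """Zero out every voxel inside the filled occluder; others unchanged."""
    if volume.shape != filled_occluder.shape:
        raise ValueError(
            f"shape mismatch: volume {volume.shape} vs occluder {filled_occluder.shape}"
        )
    data = volume.data.copy()
    data[filled_occluder.data] = 0
    return IntensityVolume(data=data, voxel_size_um=volume.voxel_size_um)


def segment_tissue(
    volume: IntensityVolume,
    params: TissueParams | None = None,
    fill_envelope: BinaryVolume | None = None,
) -> BinaryVolume:
    """Threshold the occluder-removed volume into a binary tissue mask.

    Parameters
    ----------
    volume
        Grayscale volume with the filled occluder already removed.
    params
        Threshold and post-filter settings (default: 15000 AU, envelope
        restriction on, no despeckling).
    fill_envelope
        Mask of voxels within the fill reach of the wire; applied when
        ``params.restrict_to_fill_envelope`` is true and the mask is given.
    """
    params = params or TissueParams()
    mask = volume.data >= params.tissue_threshold_au
    if params.restrict_to_fill_envelope and fill_envelope is not None:
        if fill_envelope.shape != volume.shape:
            raise ValueError("fill envelope shape mismatch")
        mask &= fill_envelope.data
    if params.min_component_vox > 0 and mask.any():
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        counts = np.bincount(labels.ravel())
        keep = counts >= params.min_component_vox
        keep[0] = False
        mask = keep[labels]
    return BinaryVolume(data=mask, voxel_size_um=volume.voxel_size_um)
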