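import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from occuquant import (
    BinaryVolume,
    FillParams,
    chamfer_distance,
    erode_and_close,
    fill_by_distance,
)
from occuquant.disk_fill import distance_map

from conftest import brute_force_edt

VS = 41.7


def _single_voxel_grid(n=5):
    mask = np.zeros((n, n, n), dtype=bool)
    mask[n // 2, n // 2, n // 2] = True
    return BinaryVolume(mask, VS)


def test_chamfer_is_zero_on_wire_and_one_at_face_neighbor():
    dist = chamfer_distance(_single_voxel_grid())
    c = 2
    assert dist.data[c, c, c] == 0.0
    assert dist.data[c + 1, c, c] == pytest.approx(1.0)


def test_chamfer_corner_neighbor_uses_corner_weight():
    """Corner step costs 5/3 ≈ 1.667 (vs Euclidean √3 ≈ 1.732)."""
    dist = chamfer_distance(_single_voxel_grid())
    c = 2
    assert dist.data[c + 1, c + 1, c + 1] == pytest.approx(5.0 / 3.0)
    # brute-force check that this is the minimum over all wire voxels
    bf = brute_force_edt(_single_voxel_grid().data)
    assert bf[c + 1, c + 1, c + 1] == pytest.approx(np.sqrt(3.0))


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        chamfer_distance(BinaryVolume(np.zeros((4, 4, 4), dtype=bool), VS))


def test_euclidean_backend_matches_brute_force_exactly():
    rng = np.random.default_rng(1)
    mask = rng.random((9, 9, 9)) > 0.93
    mask[4, 4, 4] = True
    d = distance_map(mask, backend="euclidean")
    np.testing.assert_allclose(d, brute_force_edt(mask), atol=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(4, 16), st.floats(0.01, 0.3))
def test_chamfer_within_10pct_of_euclidean_oracle(seed, n, density):
    """Property: on random masks in volumes up to 16³, chamfer distances stay
    within 10% relative error of brute-force Euclidean distances."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n, n)) < density
    if not mask.any():
        mask[rng.integers(n), rng.integers(n), rng.integers(n)] = True
    cd = distance_map(mask, backend="chamfer")
    bf = brute_force_edt(mask)
    off = ~mask
    rel = np.abs(cd[off] - bf[off]) / bf[off]
    assert rel.size == 0 or rel.max() <= 0.10
    assert (cd[mask] == 0).all()


def test_fill_monotone_in_threshold(default_phantom):
    _, truth = default_phantom
    dist = chamfer_distance(truth.wire_mask)
    prev = None
    for t in (2.0, 5.0, 10.0, 18.0):
        cur = fill_by_distance(
            dist, FillParams(distance_threshold_vox=t, wire_thickness_vox=1)
        ).data
        if prev is not None:
            assert (prev <= cur).all()  # set inclusion
        prev = cur


def test_subvoxel_threshold_fill_equals_wire(default_phantom):
    _, truth = default_phantom
    dist = chamfer_distance(truth.wire_mask)
    fill = fill_by_distance(dist, FillParams(distance_threshold_vox=0.5, wire_thickness_vox=1))
    np.testing.assert_array_equal(fill.data, truth.wire_mask.data)


def test_fill_bridges_mesh_into_single_component(default_phantom, phantom_cfg):
    _, truth = default_phantom
    dist = chamfer_distance(truth.wire_mask)
    fill = fill_by_distance(dist, phantom_cfg.fill_params())
    _, n = ndimage.label(fill.data, structure=np.ones((3, 3, 3), dtype=bool))
    assert n == 1


def test_default_threshold_reproduces_printed_physical_reach():
    """70 voxels at 41.7 μm is a physical reach of exactly 2.919 mm."""
    assert FillParams().reach_mm(41.7) == pytest.approx(2.919, abs=1e-12)


def test_planar_sheet_fill_reduces_to_original_thickness():
    """The fill of an isolated wire sheet is a slab of thickness w + 2T;
    the erosion/closing regime must bring it back to w (± 2 voxels)."""
    T, w = 12, 4
    ny, nx, nz = 24, 24, 2 * T + w + 8
    wire = np.zeros((ny, nx, nz), dtype=bool)
    z0 = (nz - w) // 2
    wire[:, :, z0 : z0 + w] = True
    params = FillParams(distance_threshold_vox=T, wire_thickness_vox=w)
    dist = chamfer_distance(BinaryVolume(wire, VS))
    fill = fill_by_distance(dist, params)
    assert fill.data[ny // 2, nx // 2, :].sum() == 2 * T + w
    red = erode_and_close(fill, params)
    thickness = red.data[ny // 2, nx // 2, :].sum()
    assert abs(thickness - w) <= 2
    assert (wire & ~red.data).sum() == 0  # contains the wire sheet


def test_erosion_radius_guard():
    """A non-positive erosion radius would annihilate nothing and defeat the
    slab reduction; it is rejected before any morphology runs."""
    params = FillParams(distance_threshold_vox=10, erosion_radius_vox=0.0)
    fill = BinaryVolume(np.ones((4, 4, 4), dtype=bool), VS)
    with pytest.raises(ValueError, match="wire thickness"):
        erode_and_close(fill, params)
    with pytest.raises(ValueError, match="positive"):
        FillParams(distance_threshold_vox=0.0)


def test_containment_chain_on_phantom(pipeline_result):
    wire, fill, occ = (
        pipeline_result.wire_mask,
        pipeline_result.filled_mask,
        pipeline_result.occluder_mask,
    )
    assert (wire.data & ~occ.data).sum() == 0  # wire ⊆ reduced
    assert (occ.data & ~fill.data).sum() == 0  # reduced ⊆ filled


def test_reduced_occluder_slices_have_no_holes(pipeline_result):
    occ = pipeline_result.occluder_mask.data
    for z in range(occ.shape[2]):
        sl = occ[:, :, z]
        if sl.any():
            assert (ndimage.binary_fill_holes(sl) != sl).sum() == 0


def test_disk_thickness_near_rim_matches_wire(pipeline_result, default_spec):
    """Along the device axis, the reduced occluder crossing of the left disk
    (at a rim-adjacent wire pixel, where the inter-disk space is open) is
    within 2 voxels of the wire thickness."""
    occ = pipeline_result.occluder_mask.data
    wire = pipeline_result.wire_mask.data
    ny, nx, _ = occ.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - (ny - 1) / 2, xx - (nx - 1) / 2)
    z_left = np.flatnonzero(wire.sum(axis=(0, 1))).min()
    R = default_spec.disk_radius_vox
    cand = wire[:, :, z_left] & (r > R - 5) & (r < R - 2)
    y, x = np.argwhere(cand)[0]
    col = occ[y, x, :].astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], col, [0]))))
    first_run = edges[1] - edges[0]
    assert abs(int(first_run) - default_spec.wire_thickness_vox) <= 2
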