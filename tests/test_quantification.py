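import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from occuquant import (
    BinaryVolume,
    CoverageSummary,
    DiskStack,
    compute_maps,
    coverage_percent,
    find_waist,
    scan_column,
    split_disks,
    summarize,
)
from occuquant.quantification import CoverageMap

VS = 41.7


# --- scan_column -----------------------------------------------------------

@pytest.mark.parametrize(
    "tissue,occluder,expected",
    [
        # tissue seen, then the occluder: covered, two tissue voxels counted
        ([1, 1, 0, 0], [0, 0, 1, 0], (2, 2)),
        # occluder reached with no prior tissue: uncovered
        ([0, 0, 0, 0], [0, 1, 0, 0], (1, 0)),
        # tissue without any occluder in the column: background label
        ([1, 0, 0, 0], [0, 0, 0, 0], (0, 0)),
        # tissue only behind the occluder does not count
        ([0, 0, 1, 1], [0, 1, 0, 0], (1, 0)),
        # non-contiguous tissue before the surface is still all counted
        ([1, 0, 1, 0, 0], [0, 0, 0, 1, 0], (2, 2)),
        ([], [], (0, 0)),
    ],
)
def test_scan_column_label_rules(tissue, occluder, expected):
    assert scan_column([bool(v) for v in occluder], [bool(v) for v in tissue]) == expected


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_vectorized_maps_agree_with_scalar_scan(seed):
    """compute_maps is an exact vectorization of scan_column."""
    rng = np.random.default_rng(seed)
    occ = rng.random((6, 5, 9)) < 0.2
    tis = rng.random((6, 5, 9)) < 0.3
    tis &= ~occ
    disk = DiskStack(BinaryVolume(occ, VS), BinaryVolume(tis, VS), "left", "+z", VS)
    cov, thick = compute_maps(disk)
    for y in range(6):
        for x in range(5):
            label, count = scan_column(occ[y, x], tis[y, x])
            assert cov.data[y, x] == label
            assert thick.data[y, x] == pytest.approx(count * VS / 1000 if label == 2 else 0.0)


def test_scan_direction_reversal_flips_capped_columns():
    occ = np.zeros((3, 3, 8), dtype=bool)
    occ[:, :, 3:5] = True
    tis = np.zeros((3, 3, 8), dtype=bool)
    tis[:, :, 1:3] = True  # cap on the low-z side only
    fwd = DiskStack(BinaryVolume(occ, VS), BinaryVolume(tis, VS), "left", "+z", VS)
    rev = DiskStack(BinaryVolume(occ, VS), BinaryVolume(tis, VS), "left", "-z", VS)
    cov_f, _ = compute_maps(fwd)
    cov_r, _ = compute_maps(rev)
    assert (cov_f.data == 2).all()
    assert (cov_r.data == 1).all()


def test_partition_conservation_and_monotonicity():
    rng = np.random.default_rng(7)
    occ = rng.random((8, 8, 10)) < 0.15
    tis = rng.random((8, 8, 10)) < 0.25
    tis &= ~occ
    disk = DiskStack(BinaryVolume(occ, VS), BinaryVolume(tis, VS), "left", "+z", VS)
    cov, _ = compute_maps(disk)
    assert sum(cov.counts()) == 64
    # adding tissue on the outer side of occluder-bearing columns never
    # decreases coverage and never touches occluder-free columns
    tis2 = tis.copy()
    tis2[:, :, 0] = ~occ[:, :, 0]
    disk2 = DiskStack(BinaryVolume(occ, VS), BinaryVolume(tis2, VS), "left", "+z", VS)
    cov2, _ = compute_maps(disk2)
    p1, p2 = coverage_percent(cov), coverage_percent(cov2)
    assert p2 >= p1
    assert ((cov.data == 0) == (cov2.data == 0)).all()


# --- coverage_percent ------------------------------------------------------

def test_coverage_percent_by_direct_count():
    m = CoverageMap(np.array([[1, 2, 2], [2, 0, 0], [1, 1, 2]], dtype=np.uint8))
    assert coverage_percent(m) == pytest.approx(100 * 4 / 7)
    assert coverage_percent(CoverageMap(np.full((3, 3), 2, dtype=np.uint8))) == 100.0
    assert np.isnan(coverage_percent(CoverageMap(np.zeros((3, 3), dtype=np.uint8))))


# --- split_disks -----------------------------------------------------------

def _two_disk_mask():
    occ = np.zeros((20, 20, 40), dtype=bool)
    occ[4:16, 4:16, 10:14] = True  # left disk
    occ[4:16, 4:16, 30:34] = True  # right disk
    occ[9:11, 9:11, 14:30] = True  # waist
    return occ


def test_split_plane_falls_in_the_waist():
    occ = _two_disk_mask()
    z = find_waist(BinaryVolume(occ, VS))
    assert 14 < z < 30
    left, right = split_disks(BinaryVolume(occ, VS), BinaryVolume(np.zeros_like(occ), VS))
    assert left.side == "left" and left.scan_direction == "+z"
    assert right.side == "right" and right.scan_direction == "-z"
    # each half holds exactly one disk
    assert left.occluder_mask.data[:, :, 10:14].sum() == 12 * 12 * 4
    assert right.occluder_mask.data.any()


def test_symmetric_device_splits_into_equal_halves():
    occ = _two_disk_mask()
    left, right = split_disks(BinaryVolume(occ, VS), BinaryVolume(np.zeros_like(occ), VS))
    assert left.occluder_mask.count() == right.occluder_mask.count()


def test_single_disk_has_no_waist():
    occ = np.zeros((16, 16, 20), dtype=bool)
    occ[4:12, 4:12, 8:12] = True
    with pytest.raises(ValueError, match="waist"):
        find_waist(BinaryVolume(occ, VS))


def test_flip_z_swaps_side_labels():
    occ = _two_disk_mask()
    left, right = split_disks(
        BinaryVolume(occ, VS), BinaryVolume(np.zeros_like(occ), VS), side_of_low_z="right"
    )
    assert left.side == "left" and left.scan_direction == "-z"
    assert right.side == "right" and right.scan_direction == "+z"


def test_split_on_phantom_uses_wire_waist(pipeline_result, default_phantom):
    _, truth = default_phantom
    z = find_waist(pipeline_result.wire_mask)
    zs = np.flatnonzero(truth.wire_mask.data.sum(axis=(0, 1)))
    # between the two disk slabs
    assert zs.min() + 4 < z < zs.max() - 4


# --- thickness arithmetic --------------------------------------------------

def test_uniform_cap_thickness_in_mm():
    """A 3-voxel cap at 41.7 μm reads 0.1251 mm everywhere it covers."""
    occ = np.zeros((4, 4, 10), dtype=bool)
    occ[:, :, 5:7] = True
    tis = np.zeros((4, 4, 10), dtype=bool)
    tis[:, :, 2:5] = True
    disk = DiskStack(BinaryVolume(occ, VS), BinaryVolume(tis, VS), "left", "+z", VS)
    cov, thick = compute_maps(disk)
    assert (cov.data == 2).all()
    np.testing.assert_allclose(thick.data, 3 * 41.7 / 1000)


def test_empty_masks_give_all_zero_maps():
    z = np.zeros((4, 4, 6), dtype=bool)
    disk = DiskStack(BinaryVolume(z, VS), BinaryVolume(z, VS), "left", "+z", VS)
    cov, thick = compute_maps(disk)
    assert not cov.data.any() and not thick.data.any()
    assert np.isnan(coverage_percent(cov))


# --- summarize -------------------------------------------------------------

def _row(dev, side, grp, pct):
    return CoverageSummary(dev, side, grp, pct)


def test_single_device_summary_has_zero_sd():
    tab = summarize([_row("d1", "left", "1-month", 100.0)])
    row = tab[(tab.side == "left") & (tab.follow_up_group == "all")].iloc[0]
    assert row["median"] == 100.0 and row["sd"] == 0.0


def test_median_and_mean_of_symmetric_values():
    rows = [_row(f"d{i}", "right", "3-month", v) for i, v in enumerate((41, 55, 69))]
    tab = summarize(rows)
    row = tab[(tab.side == "right") & (tab.follow_up_group == "all")].iloc[0]
    assert row["median"] == 55.0 and row["mean"] == 55.0


def test_summarize_requires_devices():
    with pytest.raises(ValueError):
        summarize([])
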