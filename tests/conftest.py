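import numpy as np
import pytest

from occuquant import PhantomSpec, generate_phantom
from occuquant.pipeline import phantom_config


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=2, coverage_fraction_left=1.0, coverage_fraction_right=0.55)

@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Standard noise-free phantom: fully covered left disk, 55% edge-covered right."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def phantom_cfg():
    return phantom_config()


@pytest.fixture(scope="session")
def unaligned_cfg():
    """Pipeline config that skips alignment/cropping so outputs stay in the
    generator's frame (for exact comparisons against ground truth)."""
    return phantom_config(align=False, pad_vox=10**9)


@pytest.fixture(scope="session")
def pipeline_result(default_phantom, unaligned_cfg):
    from occuquant.pipeline import run_pipeline

    vol, _ = default_phantom
    return run_pipeline(vol, unaligned_cfg)


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: exact Euclidean distance of every voxel to the
    nearest True voxel, by direct minimization over all mask voxels."""
    pts = np.argwhere(mask).astype(float)
    grid = np.indices(mask.shape).reshape(3, -1).T.astype(float)
    d2 = ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1)).reshape(mask.shape)
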