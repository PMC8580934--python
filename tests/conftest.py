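import numpy as np
import pytest

from segrel import SyntheticConfig, generate_cohort, generate_cohort_records
from segrel.mask_io import LabelMask

#: Small, fast study conditions used across the unit tests (6 femurs).
TINY_CONFIG = SyntheticConfig(
    n_per_type=(2, 2, 2),
    grid_shape=(48, 48, 40),
    spacing=(1.2, 1.2, 2.5),
    volume_mean_sd={
        "osteolytic": (4.0, 2.0),
        "osteoblastic": (8.0, 4.0),
        "mixed": (8.0, 4.0),
    },
    max_volume_cm3=20.0,
    seed=42,
)


def ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    """Solid ellipsoidal ball in voxel units (radius in voxels per axis)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.zeros(shape)
    for g, c in zip(grids, center):
        r = r + (g - c) ** 2
    return LabelMask(voxels=r <= radius**2, spacing=spacing)


def mask_from_count(shape, n, spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    """Mask with exactly the first ``n`` voxels (C order) in-set."""
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    flat[:n] = True
    return LabelMask(voxels=flat.reshape(shape), spacing=spacing)


@pytest.fixture(scope="session")
def tiny_cohort():
    """In-memory synthetic cohort of 6 femurs (records, truth table)."""
    return generate_cohort_records(TINY_CONFIG)


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """The tiny cohort written to disk; returns (manifest path, truth path)."""
    out = tmp_path_factory.mktemp("cohort")
    return generate_cohort(TINY_CONFIG, out)
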