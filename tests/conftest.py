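import numpy as np
import pytest

from vlsmkit.grid import VolumeGrid
from vlsmkit.lesions import DysfunctionMasks


@pytest.fixture
def grid8():
    return VolumeGrid((8, 8, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(20240825)


@pytest.fixture
def random_masks(grid8, rng):
    """Random per-patient lesion masks biased to the left hemisphere."""
    n = 40
    hemi = grid8.analysis_side()
    masks = np.zeros((n, *grid8.shape), dtype=bool)
    for i in range(n):
        masks[i] = (rng.random(grid8.shape) < 0.35) & hemi
    vols = masks.reshape(n, -1).sum(axis=1)
    ids = [f"R{i:03d}" for i in range(n)]
    return DysfunctionMasks(grid8, ids, masks, vols)
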