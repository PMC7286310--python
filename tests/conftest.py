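import numpy as np
import pytest

from mouec import CohortSpec, MouParameters, StructuralMask, make_ground_truth


@pytest.fixture(scope="session")
def small_truth():
    """Stable N=8 ground-truth network with its structural mask."""
    mask, params = make_ground_truth(CohortSpec(n_rois=8, density=0.3, seed=7))
    return mask, params


@pytest.fixture(scope="session")
def two_block_params():
    """Two disconnected 5-ROI blocks with strong within-block coupling."""
    n = 10
    rng = np.random.default_rng(11)
    c = np.zeros((n, n))
    for block in (range(0, 5), range(5, 10)):
        for i in block:
            for j in block:
                if i != j:
                    c[i, j] = 0.4 + 0.1 * rng.random()
    c *= 0.12  # keep the Jacobian comfortably stable at tau = 2
    return MouParameters(C=c, Sigma=np.eye(n), tau=2.0)


@pytest.fixture
def uncoupled_params():
    """Five independent OU nodes, tau = 2 s, unit input variance."""
    return MouParameters(C=np.zeros((5, 5)), Sigma=np.eye(5), tau=2.0)
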