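import numpy as np
import pytest

from stimnet import synthetic
from stimnet.containers import CONNECTIVITY_ROIS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def motor_subnetwork():
    """The 5-ROI connectivity subnetwork (all edges live within it),
    without local source-gain modulation: coupling changes only."""
    net = synthetic.default_motor_network(modulate_source_gain=False)
    return synthetic.NetworkSpec(
        roi_labels=CONNECTIVITY_ROIS,
        oscillators={r: net.oscillators[r] for r in CONNECTIVITY_ROIS},
        edges=net.edges,
        fs_hz=net.fs_hz,
    )


@pytest.fixture(scope="session")
def random_stable_mvar():
    """A K=5, p=3 stable MVAR model with dense random coefficients."""
    rng = np.random.default_rng(7)
    k, p = 5, 3
    from stimnet.containers import MVARModel

    for _ in range(100):
        a = rng.normal(0, 0.12, size=(p, k, k))
        a[0] += 0.3 * np.eye(k)
        model = MVARModel(A=a, Sigma=np.eye(k), fs_hz=500.0)
        if model.spectral_radius() < 0.95:
            return model
    raise RuntimeError("could not draw a stable model")
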