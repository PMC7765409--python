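import numpy as np
import pytest

from steatoscreen.synthetic import FieldParams


@pytest.fixture
def small_field_params():
    """A compact noiseless field: 8 cells in 256x256 px, full droplet load."""
    return FieldParams(shape=(256, 256), n_nuclei=8, noise_sigma=(0.0, 0.0))


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
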