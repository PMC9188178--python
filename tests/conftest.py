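import numpy as np
import pandas as pd
import pytest

from seedscreen.hsi import Hypercube


@pytest.fixture
def small_cube():
    """10x10x5 cube: background 0.05 with two bright 3x3 blocks."""
    wavelengths = np.array([400.0, 500.0, 600.0, 700.0, 800.0])
    data = np.full((10, 10, 5), 0.05)
    data[1:4, 1:4, :] = 0.5
    data[6:9, 6:9, :] = 0.6
    return Hypercube(data, wavelengths)


@pytest.fixture
def two_class_meta():
    def make(n_target, n_other):
        return pd.DataFrame(
            {
                "category": ["target"] * n_target + ["non-target"] * n_other,
                "variety": ["t"] * n_target + ["o"] * n_other,
                "lot": ["l1"] * (n_target + n_other),
                "surface": ["unknown"] * (n_target + n_other),
            }
        )

    return make
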