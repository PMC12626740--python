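import numpy as np
import pytest

from ntcpkit.dvh import CumulativeDVH, make_differential
from ntcpkit.models import RS_PRESETS


@pytest.fixture
def parotid_params():
    return RS_PRESETS["parotid_xerostomia_rs"]


@pytest.fixture
def lacrimal_params():
    return RS_PRESETS["lacrimal_dryeye_rs"]


@pytest.fixture
def staircase_cum():
    """The worked cumulative example: {0: 1.0, 10: 1.0, 20: 0.5, 30: 0.0}."""
    return CumulativeDVH(
        np.array([0.0, 10.0, 20.0, 30.0]),
        np.array([1.0, 1.0, 0.5, 0.0]),
        structure_label="example",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_differential(rng, n_bins=None, max_dose=60.0, label="rand"):
    """A valid random differential DVH for property tests."""
    n = int(n_bins or rng.integers(1, 25))
    doses = np.sort(rng.uniform(0.0, max_dose, size=n))
    doses = np.unique(np.round(doses, 3))
    vols = rng.uniform(0.05, 1.0, size=doses.size)
    vols /= vols.sum()
    return make_differential(doses, vols, label=label)
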