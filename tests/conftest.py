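import numpy as np
import pytest

from minimst import MiniMSTOutlierDetector
from minimst.synthetic import fig1_default, make_scenario

#: Configuration used for continuous 2-D scenes: the fixed MEW1 = 1.0 the
#: method documents for such data, and a sqrt(N) cluster-size floor since
#: round(N/n) exceeds every cluster in two dimensions (see docs/methods.md).
SCENE_2D = dict(mew1=1.0, least_number=11)


@pytest.fixture
def fig1_points():
    """The canonical 121-point four-cluster scene with 6 planted outliers."""
    return make_scenario(fig1_default(seed=7))


@pytest.fixture
def scene_detector():
    return MiniMSTOutlierDetector(**SCENE_2D)


def unit_lattice(rows: int, cols: int) -> np.ndarray:
    """Exact integer lattice: the fully homogeneous cluster (tied weights)."""
    grid = np.stack(np.meshgrid(np.arange(float(cols)), np.arange(float(rows))), -1)
    return grid.reshape(-1, 2)
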