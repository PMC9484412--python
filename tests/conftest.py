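import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from coda import (GridSpec, make_absorbing_spheres, make_point_sources,
                  make_vessel)
from coda.metrics import evaluate_all

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_spec():
    """20 mm field at 0.2 mm pitch: big enough for sub-mm features, cheap."""
    return GridSpec(size_mm=20.0, pitch=0.2)


@pytest.fixture(scope="session")
def study():
    """The full simulation study at reduced grid scale.

    Three phantoms x five reconstruction variants x three noise seeds on a
    250 x 250 grid (0.2 mm pitch), using the stated scan protocol
    (360 angles at 23 mm, 2.5 MHz / 75% bandwidth, 2226 samples at 21 ns,
    40 dB SNR).  Shared session-wide because it is the expensive part of
    the acceptance checks.
    """
    spec = GridSpec(size_mm=50.0, pitch=0.2)
    phantoms = {
        "points": make_point_sources(spec),
        "vessel": make_vessel(spec, seed=0),
        "spheres": make_absorbing_spheres(spec),
    }
    seeds = (1, 2, 3)
    table, images = evaluate_all(phantoms, seeds=seeds, return_images=True)
    return SimpleNamespace(spec=spec, phantoms=phantoms, seeds=seeds,
                           table=table, images=images)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
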