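import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from irllc import AcquisitionSpec, PhantomSpec, render_phantom


@pytest.fixture
def noise_free_acq():
    return AcquisitionSpec(noise_sigma=0.0)


@pytest.fixture
def small_phantom():
    """64x64 phantom: 30 mm lesion (T1 1187 ms) in 654 ms parenchyma."""
    spec = PhantomSpec(
        matrix=(64, 64),
        liver_radius_mm=45.0,
        lesion_diameter_mm=30.0,
        t1_liver_ms=654.0,
        t1_lesion_ms=1187.0,
    )
    return render_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
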