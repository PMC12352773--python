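import numpy as np
import pytest

from conedose import ScanCurve, ScanMeta
from conedose.synth import gen_applicator_pair


@pytest.fixture(scope="session")
def study_dataset():
    """Noiseless paired study dataset at the benchmark conditions (seed 0)."""
    return gen_applicator_pair(seed=0)


@pytest.fixture
def simple_pdd():
    """Minimal hand-made depth-dose curve: buildup, peak at 14 mm, falloff."""
    z = np.array([0.0, 5.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0, 38.0])
    d = np.array([80.0, 92.0, 98.0, 100.0, 96.0, 75.0, 40.0, 10.0, 2.0, 1.5])
    return ScanCurve(z, d, axis="depth")


@pytest.fixture
def rect_profile():
    """Ideal rectangular profile: 100% for |x| <= 10 mm, 0 outside, 0.1 mm grid."""
    x = np.round(np.arange(-30.0, 30.0 + 0.05, 0.1), 10)
    d = np.where(np.abs(x) <= 10.0, 100.0, 0.0)
    return ScanCurve(x, d, axis="crossplane", meta=ScanMeta(depth_mm=14.0))
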