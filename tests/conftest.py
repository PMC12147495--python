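import numpy as np
import pytest

from bonevar import MaterialDataset, MaterialSample, SyntheticConfig, generate_synthetic_dataset


@pytest.fixture
def tiny_dataset() -> MaterialDataset:
    """Five hand-built materials with 1..5 measurements each."""
    specs = [
        ("m1", 1.0, [50.0]),
        ("m2", 2.0, [40.0, 44.0]),
        ("m3", 3.0, [30.0, 35.0, 40.0]),
        ("m4", 4.0, [60.0, 62.0, 64.0, 66.0]),
        ("m5", 5.0, [20.0, 25.0, 30.0, 35.0, 40.0]),
    ]
    samples = [
        MaterialSample(mid, {"x1": x, "x2": 2.0 * x}, list(meas)) for mid, x, meas in specs
    ]
    return MaterialDataset(samples=samples, feature_names=["x1", "x2"])


@pytest.fixture(scope="session")
def synth():
    """Default synthetic study (38 materials, 17 measured once), seed 1."""
    dataset, truth = generate_synthetic_dataset(SyntheticConfig(seed=1))
    return dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
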