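import numpy as np
import pytest

from psqakit import (
    ComplexityVector,
    FluenceMap,
    PSQASample,
    QATargets,
    SimConfig,
    generate_dataset,
)
from psqakit.nn import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_sample(sample_id: str = "s0", site: str = "C", h: int = 64,
                w: int = 64, seed: int = 0) -> PSQASample:
    r = np.random.default_rng(seed)
    fluence = FluenceMap(r.random((h, w)))
    dd = r.normal(0.0, 0.01, (h, w))
    return PSQASample(
        sample_id=sample_id,
        lesion_site=site,
        fluence=fluence,
        complexity=ComplexityVector(r.random(33)),
        targets=QATargets(np.array([90.0, 95.0, 97.0]), dd),
    )


@pytest.fixture
def sample():
    return make_sample()


@pytest.fixture(scope="session")
def small_dataset():
    """40 simulated samples, shared across the session (read-only)."""
    return generate_dataset(SimConfig(n_samples=40, seed=7))


@pytest.fixture(scope="session")
def desk_net_cfg():
    return NetworkConfig(
        grid=(64, 64), encoder_channels=(8, 16, 24, 32), n_tab_channels=2,
        fused_width=64, decoder_channels=(24, 16, 12, 8, 6), dropout=0.1,
    )
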