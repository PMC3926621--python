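import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dict512():
    from eegcs.gabor import build_dictionary

    return build_dictionary(512)


@pytest.fixture(scope="session")
def dict128():
    from eegcs.gabor import build_dictionary

    return build_dictionary(128)


@pytest.fixture(scope="session")
def synth_epochs(dict512):
    """Eight default-condition synthetic epochs (C=8 channels, N=512)."""
    from eegcs.io_core import epoch_stream
    from eegcs.synthetic import SynthConfig, generate_recording

    cfg = SynthConfig(n_epochs=8, seed=42, dictionary=dict512)
    rec = generate_recording(cfg)
    return list(epoch_stream(rec, cfg.N))


@pytest.fixture(scope="session")
def small_epochs(dict128):
    """Cheap epochs (C=4, N=128) for pipeline tests that do not need N=512."""
    from eegcs.io_core import epoch_stream
    from eegcs.synthetic import SynthConfig, generate_recording

    cfg = SynthConfig(
        C=4, n_sources=3, N=128, n_epochs=6, seed=7, dictionary=dict128
    )
    rec = generate_recording(cfg)
    return list(epoch_stream(rec, cfg.N))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
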