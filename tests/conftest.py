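import numpy as np
import pytest

from emgpipe.features import extract_features
from emgpipe.preprocess import PreprocessConfig, segment_recording
from emgpipe.synth import SynthConfig, default_activation_profile, generate_recording


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(class_counts={c: 10 for c in range(1, 8)}, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_recording(small_cfg)


@pytest.fixture(scope="session")
def small_segments(small_recording):
    return segment_recording(small_recording, PreprocessConfig())


@pytest.fixture(scope="session")
def small_features(small_segments):
    return extract_features(small_segments)


@pytest.fixture(scope="session")
def separable_features():
    """~350 segments with well-separated activation profiles, moderate noise."""
    cfg = SynthConfig(
        class_counts={c: 50 for c in range(1, 8)},
        activation_profile=default_activation_profile(gain=1.5),
        baseline_sd=0.5,
        seed=11,
    )
    rec = generate_recording(cfg)
    return extract_features(segment_recording(rec, PreprocessConfig()))


def rng_vectors(seed, n_vectors, length, scale=1.0):
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((n_vectors, length))
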