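import numpy as np
import pytest

from mlec import PSSMProfile, SynthSpec, generate_multilabel_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_profile(rng):
    """A seed-fixed 12×20 real-valued profile."""
    return PSSMProfile(sequence_id="p0", scores=rng.normal(size=(12, 20)))


@pytest.fixture(scope="session")
def separable_dataset():
    """Strong class signal: every downstream classifier should ace this."""
    return generate_multilabel_dataset(
        SynthSpec(seed=7, n_samples=120, class_shift=5.0, noise_sd=1.0)
    )


@pytest.fixture(scope="session")
def noise_dataset():
    """No class signal at all."""
    return generate_multilabel_dataset(
        SynthSpec(seed=7, n_samples=120, class_shift=0.0, noise_sd=1.0)
    )
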