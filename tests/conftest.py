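import numpy as np
import pytest

from eeghotspot import (
    ModelConfig,
    SyntheticConfig,
    generate_subject,
    load_montage,
)


@pytest.fixture(scope="session")
def healthy_montage():
    return load_montage("healthy63")


@pytest.fixture(scope="session")
def stroke_montage():
    return load_montage("stroke29")


@pytest.fixture(scope="session")
def tiny_model_config():
    """A very small CNN for fast mechanical tests (not the study model)."""
    return ModelConfig(
        conv_blocks=((1, 4),), dense_hidden=(8,), max_epochs=3, patience=3,
        seed=0,
    )


@pytest.fixture(scope="session")
def healthy_subject(healthy_montage):
    """One healthy synthetic subject (right hand only) shared across tests."""
    cfg = SyntheticConfig(cohort="healthy", n_subjects=1, n_trials=12, seed=42)
    rng = np.random.default_rng(np.random.SeedSequence(42))
    return generate_subject(healthy_montage, cfg, rng, "s01", hands=("right",))


@pytest.fixture(scope="session")
def stroke_subject(stroke_montage):
    """One stroke synthetic subject with a high blink rate (for ICA tests)."""
    cfg = SyntheticConfig(
        cohort="stroke", n_subjects=1, n_trials=6, seed=7, artifact_rate=120.0
    )
    rng = np.random.default_rng(np.random.SeedSequence(7))
    return generate_subject(stroke_montage, cfg, rng, "p01", hands=("left",))
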