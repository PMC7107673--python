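"""Shared fixtures. The expensive ones (phantom patch sets, the trained tiny
segmenter) are session-scoped and reused across test modules."""

import numpy as np
import pytest

from strokehier import preprocess, segnet, synthetic


@pytest.fixture(scope="session")
def cohort300():
    return synthetic.generate_cohort(synthetic.CohortConfig(n_patients=300, seed=1))


@pytest.fixture(scope="session")
def phantom_study():
    """One sign-positive phantom with its truth mask."""
    cfg = synthetic.PhantomConfig(seed=3)
    rng = synthetic.substream(3, "phantom-fixture")
    return cfg, synthetic.generate_phantom(cfg, True, rng, patient_id="FIX", has_sign=True)


@pytest.fixture(scope="session")
def train_patches():
    """60 pre-processed phantom patches (20 lesion-positive)."""
    return synthetic.phantom_training_patches(20, synthetic.PhantomConfig(seed=100))


@pytest.fixture(scope="session")
def heldout_patches():
    """Held-out phantom patches from an independent seed."""
    return synthetic.phantom_training_patches(8, synthetic.PhantomConfig(seed=200))


@pytest.fixture(scope="session")
def tiny_net(train_patches):
    """Desk-scale segmenter trained on the 60-patch phantom set."""
    patches, masks = train_patches
    return segnet.train_segmenter(
        patches, masks,
        segnet.SegNetConfig(**segnet.TINY_PROFILE),
        segnet.SegTrainConfig(learning_rate=1e-3, epochs=30, batch_size=16, seed=0))


@pytest.fixture(scope="session")
def processed_stack(phantom_study):
    _, study = phantom_study
    return preprocess.preprocess_volume(study.volume)
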