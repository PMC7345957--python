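"""Shared fixtures: phantoms and trained synthesis models.

Training is expensive on one CPU, so the two canonical training runs (the
pipeline model and the smoke-test run) are session-scoped and shared by the
unit and acceptance tests that examine them.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sctmorph.caegan import TrainConfig, build_model, train
from sctmorph.phantom import PhantomSpec, generate_phantom
from sctmorph.pipeline import training_patches

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TRAIN_SEEDS = (101, 102, 103, 104, 105)
TEST_CASE_SEED = 202
PIPELINE_SEED = 7
SMOKE_SEED = 11


@pytest.fixture(scope="session")
def clean_phantom():
    """Undeformed, noise-free case used as a simple anatomy image."""
    return generate_phantom(PhantomSpec(shape=(64, 64), seed=0, deform_amplitude=0, sp_noise_fraction=0))


@pytest.fixture(scope="session")
def test_case():
    """The held-out corrupted case the pipeline is evaluated on."""
    return generate_phantom(PhantomSpec(shape=(64, 64), seed=TEST_CASE_SEED))


@pytest.fixture(scope="session")
def pipeline_model():
    """Synthesis model trained on aligned clean phantoms from other seeds,
    emulating leave-one-out training on healthy subjects."""
    data = []
    for s in TRAIN_SEEDS:
        c = generate_phantom(PhantomSpec(shape=(64, 64), seed=s, deform_amplitude=0, sp_noise_fraction=0))
        data += training_patches(c.mr, c.ct, c.labels, 16, 8)
    model = build_model(seed=PIPELINE_SEED)
    train(model, data, TrainConfig(steps=800, seed=PIPELINE_SEED))
    return model


@pytest.fixture(scope="session")
def smoke_run():
    """200 seeded steps on 32 phantom patch pairs (base 16, depth 3)."""
    case = generate_phantom(PhantomSpec(shape=(64, 64), seed=SMOKE_SEED, deform_amplitude=0, sp_noise_fraction=0))
    patches = training_patches(case.mr, case.ct, case.labels, 16, 8)
    rng = np.random.default_rng(SMOKE_SEED)
    idx = rng.choice(len(patches), 32, replace=False)
    data = [patches[i] for i in idx]
    model = build_model(base_channels=16, depth=3, seed=SMOKE_SEED)
    history = train(model, data, TrainConfig(steps=200, seed=SMOKE_SEED))
    return model, history
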