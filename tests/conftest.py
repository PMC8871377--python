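"""Shared fixtures: small synthetic datasets and a trained compact pipeline.

Session scope keeps the expensive pieces (embedding training) to one run.
All fixtures are seeded; nothing here depends on wall-clock or host state.
"""

from __future__ import annotations

import numpy as np
import pytest

from octanomaly import (
    BackboneSpec,
    LOFParams,
    PipelineConfig,
    SynthConfig,
    TrainConfig,
    generate_dataset,
)
from octanomaly.pipeline import fit

# compact 64x64 study conditions used by unit/property tests (fast);
# the acceptance tests run the full-size configuration separately
SMALL = dict(height=64, width=64, n_layers=4, drusen_amplitude=9.0, drusen_width=11.0,
             fluid_depth=15.0, fluid_width=30.0, tilt_jitter=2.0)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(speckle_sd=0.02, seed=7, **SMALL)


@pytest.fixture(scope="session")
def noiseless_config() -> SynthConfig:
    return SynthConfig(speckle_sd=0.0, tilt_jitter=0.0, seed=7,
                       **{**SMALL, "tilt_jitter": 0.0})


@pytest.fixture(scope="session")
def small_train_set(small_config):
    return generate_dataset(small_config, (60, 30, 30), seed=101)


@pytest.fixture(scope="session")
def small_test_set(small_config):
    return generate_dataset(small_config, (30, 15, 15), seed=909)


@pytest.fixture(scope="session")
def small_pipeline(small_train_set):
    cfg = PipelineConfig(
        train=TrainConfig(epochs=5, input_size=(64, 64, 3), seed=5),
        lof=LOFParams(k=10),
        backbone=BackboneSpec(),
        seed=5,
    )
    return fit(small_train_set, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
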