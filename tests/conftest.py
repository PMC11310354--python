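"""Shared fixtures.

The expensive fixtures (the trained tiny-profile model and the benchmark
suites) are session-scoped: they are built once and shared by the
end-to-end and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import strainkit.synthetic as syn
from strainkit.training import TrainingConfig, train_all

#: Study conditions of the desk-scale ("tiny") experiment: 64 x 64
#: frames, 300 synthetic pairs, 30 epochs, fixed seed.
TINY_SEED = 11
TINY_N_PAIRS = 300
TINY_EPOCHS = 30


@pytest.fixture(scope="session")
def speckle():
    return syn.generate_speckle_image(64, 64, seed=5)


@pytest.fixture(scope="session")
def geometry():
    return syn.default_geometry((64, 64))


@pytest.fixture(scope="session")
def trained_tiny():
    """Tiny-profile model trained on the seeded 300-pair synthetic set."""
    dataset = syn.generate_training_set(n_pairs=TINY_N_PAIRS, seed=TINY_SEED)
    models, report = train_all(
        dataset, TrainingConfig.tiny(seed=TINY_SEED, epochs=TINY_EPOCHS)
    )
    return models, report


@pytest.fixture(scope="session")
def benchmark_reduced_noise():
    """The five benchmark cases with noise reduced to a quarter strength."""
    return syn.generate_test_cases(
        seed=TINY_SEED + 1, noise_ranges=syn.NoiseParams().scaled(0.25)
    )


@pytest.fixture(scope="session")
def benchmark_noisy():
    """The five benchmark cases at full default noise."""
    return syn.generate_test_cases(seed=TINY_SEED + 1)
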