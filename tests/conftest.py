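"""Shared fixtures: a miniature architecture, grid and synthetic dataset.

The miniature objects keep unit tests fast; the full-scale study conditions
live in test_acceptance.py.
"""

import numpy as np
import pytest

from fmridecoder import (
    ArchitectureConfig,
    TrainConfig,
    VolumeGrid,
    build_model,
    default_design,
    generate_dataset,
)

TINY_GRID = (10, 12, 10)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchitectureConfig(
        input_frames=4,
        n_ch1=2,
        conv2_channels=4,
        block_channels=(4, 6, 6, 8),
        block_strides=(1, 2, 2, 2),
        final_conv_channels=8,
        fc_width=8,
        n_classes=2,
    )


@pytest.fixture(scope="session")
def tiny_grid():
    return VolumeGrid(shape=TINY_GRID)


@pytest.fixture()
def tiny_model(tiny_arch, tiny_grid):
    return build_model(tiny_arch, tiny_grid, seed=7)


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return TrainConfig(k=4, batch_size=8, max_epochs=4, seed=3)


@pytest.fixture(scope="session")
def tiny_design():
    return default_design(
        n_conditions=2,
        grid_shape=TINY_GRID,
        n_subjects=6,
        amplitude=5.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_samples(tiny_design):
    return generate_dataset(tiny_design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
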