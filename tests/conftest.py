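"""Shared fixtures: desk-scale scene parameters and a session-trained model.

The desk configuration (128x128 scenes, depth-3 network) exercises every
pipeline stage in seconds on a CPU; the network-size scenes make the
preprocessing step an identity transform so end-to-end tests isolate the
segmentation behavior.
"""

import numpy as np
import pytest

from nodulepipe import segnet, synth

# Desk-scale study conditions: small scenes matching the network input so
# the full loop (generate -> train -> predict -> postprocess -> measure)
# runs in seconds.
DESK_PARAMS = synth.SceneParams(
    image_height=128,
    image_width=128,
    n_roots=2,
    root_width_range=(2, 4),
    n_nodules=6,
    nodule_radius_range=(4.0, 9.0),
    overlap_fraction=0.3,
    background_noise_sd=8.0,
    mm_per_pixel=0.5,
)

# Same geometry with disjoint, well-separated nodules above the
# size-filter threshold: instances stay distinct components even after
# closing (separation > 2*closing_radius + 1), so counting and sizing
# are exactly recoverable in principle.
DISJOINT_PARAMS = synth.SceneParams(
    image_height=128,
    image_width=128,
    n_roots=2,
    root_width_range=(2, 4),
    n_nodules=4,
    nodule_radius_range=(5.0, 9.0),
    overlap_fraction=0.0,
    min_separation=6.0,
    background_noise_sd=8.0,
    mm_per_pixel=0.5,
)

DESK_CONFIG = segnet.SegModelConfig(
    input_size=128, depth=3, base_channels=16, epochs=30
)


@pytest.fixture(scope="session")
def desk_params():
    return DESK_PARAMS


@pytest.fixture(scope="session")
def disjoint_params():
    return DISJOINT_PARAMS


@pytest.fixture(scope="session")
def desk_config():
    return DESK_CONFIG


@pytest.fixture(scope="session")
def desk_scenes():
    """A small fixed batch of desk scenes with ground truth."""
    return synth.generate_dataset(4, DESK_PARAMS, seed=11)


@pytest.fixture(scope="session")
def trained_model():
    """One model trained on a few desk scenes, reused across tests.

    Tests must not mutate it; anything that calls ``update`` should train
    its own copy.
    """
    scenes = synth.generate_dataset(4, DESK_PARAMS, seed=21)
    model = segnet.build_model(DESK_CONFIG)
    model, _ = segnet.train(
        model, [(s.image.pixels, s.mask) for s in scenes], DESK_CONFIG
    )
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
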