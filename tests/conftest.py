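"""Shared fixtures.

The expensive fixtures (trained reference model, adapted models) are
session-scoped and shared between the unit tests and the acceptance tests.
The reference model is a scaled-down shapes model (14x14 images, shape sides
5/8, hidden layers 196/144/100) chosen so the full suite trains and adapts
within the CI budget; geometry constants live here, not in the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from homeodbm.core import LayeredNetwork
from homeodbm.data import blank_provider, enumerate_instances, sample_dataset
from homeodbm.homeostasis import HomeostasisConfig, measure_target_activity, run_adaptation
from homeodbm.quality import TemplateBank, train_classifier
from homeodbm.training import RFSpec, TrainConfig, layerwise_pretrain

IMAGE_SIZE = (14, 14)
SIDES = {"small": 5, "large": 8}
LAYER_SIZES = [196, 196, 144, 100]
PATCH_SIDES = [5, 7, None]
TRAIN_SEED = 0
N_TRAIN_IMAGES = 5000
N_PIXELS = IMAGE_SIZE[0] * IMAGE_SIZE[1]


def make_small_net(
    layer_sizes, seed=0, weight_scale=0.5, bias_scale=0.5
) -> LayeredNetwork:
    """A fully connected random network for oracle-sized tests."""
    rng = np.random.default_rng(seed)
    weights, masks = [], []
    for lo, hi in zip(layer_sizes[:-1], layer_sizes[1:]):
        masks.append(np.ones((lo, hi)))
        weights.append(rng.normal(0.0, weight_scale, (lo, hi)))
    biases = [rng.normal(0.0, bias_scale, n) for n in layer_sizes]
    return LayeredNetwork(list(layer_sizes), weights, biases, masks)


@pytest.fixture(scope="session")
def shapes_dataset():
    return enumerate_instances(IMAGE_SIZE, SIDES)


@pytest.fixture(scope="session")
def template_bank(shapes_dataset):
    return TemplateBank.for_dataset(shapes_dataset)


@pytest.fixture(scope="session")
def trained_net(shapes_dataset):
    train = sample_dataset(N_TRAIN_IMAGES, TRAIN_SEED, IMAGE_SIZE, SIDES)
    cfg = TrainConfig(
        epochs=150,
        cd_steps=1,
        learning_rate=0.1,
        minibatch_size=50,
        weight_decay=2e-4,
        init_bias=-4.0,
        rng_seed=TRAIN_SEED,
    )
    net, logs = layerwise_pretrain(train.images, LAYER_SIZES, RFSpec(PATCH_SIDES), cfg)
    net.metadata["recon_logs"] = logs
    return net


@pytest.fixture(scope="session")
def target_activities(trained_net, shapes_dataset):
    return measure_target_activity(
        trained_net, shapes_dataset.images, 50, np.random.default_rng(TRAIN_SEED)
    )


@pytest.fixture(scope="session")
def shapes_classifier(trained_net, shapes_dataset):
    return train_classifier(
        shapes_dataset,
        trained_net,
        TrainConfig(epochs=3000, learning_rate=0.3, minibatch_size=50, init_bias=0.0),
    )


@pytest.fixture(scope="session")
def blindness_run(trained_net, target_activities, template_bank):
    """Long blank-input adaptation shared by several acceptance criteria."""
    cfg = HomeostasisConfig(rate=0.1, max_iterations=650, rng_seed=42)
    adapted, trace = run_adaptation(
        trained_net, blank_provider(N_PIXELS), target_activities, cfg,
        bank=template_bank,
    )
    return adapted, trace
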