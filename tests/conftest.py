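"""Shared fixtures: a miniature microzone that trains in seconds.

The miniature circuit keeps the full architecture (all seven groups, same
wiring, signs and strength ratios) but scales the three large interneuron
populations down so a training run takes a few seconds instead of minutes.
"""

import numpy as np
import pytest

from microzone import (
    build_microzone, default_config, generate_training_set, scale_group,
    train_to_criterion,
)


def make_micro_config():
    cfg = default_config()
    cfg = scale_group(cfg, "granule", 80 / 3300)
    cfg = scale_group(cfg, "golgi", 20 / 300)
    cfg = scale_group(cfg, "basket", 10 / 130)
    return cfg


@pytest.fixture(scope="session")
def micro_config():
    return make_micro_config()


@pytest.fixture(scope="session")
def trained_micro(micro_config):
    """A miniature network trained to criterion, with its training set."""
    net = build_microzone(micro_config, seed=1)
    tset = generate_training_set(micro_config, seed=101)
    result = train_to_criterion(net, tset, max_epochs=400)
    assert result.converged, "miniature circuit failed to train to criterion"
    return result, tset


@pytest.fixture()
def trained_micro_copy(trained_micro):
    result, tset = trained_micro
    return result.network.copy(), tset
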