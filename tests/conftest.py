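"""Shared fixtures.

Expensive artifacts (the trained classifiers and the 10-class image set)
are session-scoped and shared across test modules; everything is generated
programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

import neuroiface as ni


@pytest.fixture(scope="session")
def images10() -> ni.ImageSet:
    """The 10-class, 200-per-class synthetic stimulus set."""
    return ni.generate_images(10, 200, size=(32, 32), seed=11)


@pytest.fixture(scope="session")
def net10(images10) -> ni.TrainedNet:
    """The desk-scale classifier trained on the 10-class set."""
    return ni.train_net(ni.NetSpec(), images10, ni.Hyper(max_epochs=10), seed=7)


@pytest.fixture(scope="session")
def tiny_images() -> ni.ImageSet:
    """A small 4-class set for fast unit tests."""
    return ni.generate_images(4, 30, size=(16, 16), seed=5)


@pytest.fixture(scope="session")
def tiny_net(tiny_images) -> ni.TrainedNet:
    """A briefly trained miniature on 16x16 images (seconds to fit)."""
    spec = ni.NetSpec(blocks=((8,), (16,)), dense=(24,), n_classes=4,
                      input_size=(16, 16, 3))
    return ni.train_net(spec, tiny_images, ni.Hyper(max_epochs=12), seed=3)


@pytest.fixture(scope="session")
def untrained_tiny_net() -> ni.TrainedNet:
    spec = ni.NetSpec(blocks=((8,), (16,)), dense=(24,), n_classes=4,
                      input_size=(16, 16, 3))
    return ni.TrainedNet(spec, seed=9)


@pytest.fixture(scope="session")
def images144() -> ni.ImageSet:
    """The many-class (144 x 40) training set; the net does not saturate on it."""
    return ni.generate_images(144, 40, seed=41)


@pytest.fixture(scope="session")
def net_vgg144(images144) -> ni.TrainedNet:
    """VGG-like miniature trained on the many-class set.

    Serves the perturbation analysis (which needs the full-size block
    structure and genuinely trained intermediate layers) and the sparse
    MVPA comparison.
    """
    return ni.train_net(ni.NetSpec.vgg_miniature(n_classes=144), images144,
                        ni.Hyper(max_epochs=12), seed=42)
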