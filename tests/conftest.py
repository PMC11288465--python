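"""Shared fixtures: synthetic tables and toy image sets, generated once."""

import numpy as np
import pytest

from swarmfs import (
    SyntheticConfig,
    extract_descriptor_features,
    generate_feature_table,
    generate_toy_images,
)


@pytest.fixture(scope="session")
def default_synthetic():
    """The desk-scale problem: n=400, D=64, k=8 informative, 5 classes."""
    return generate_feature_table(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_synthetic():
    """A cheap problem for unit tests of the search machinery."""
    return generate_feature_table(
        SyntheticConfig(n_samples=100, n_features=16, n_informative=4, seed=3)
    )


@pytest.fixture(scope="session")
def toy_image_set():
    """5 classes x 40 toy images, the shipped end-to-end seed."""
    return generate_toy_images(40, 5, seed=7)


@pytest.fixture(scope="session")
def toy_table(toy_image_set):
    images, labels = toy_image_set
    return extract_descriptor_features(images, labels)


class ScriptedRng:
    """A fake random generator replaying scripted draws, for hand-arithmetic
    checks of the update rules."""

    def __init__(self, draws):
        self._draws = list(draws)

    def _pop(self, size=None):
        if size is None:
            return float(self._draws.pop(0))
        out = np.full(int(size), float(self._draws.pop(0)))
        return out

    def random(self, size=None):
        return self._pop(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        u = self._pop(size)
        return low + (high - low) * u

    def integers(self, n):
        return int(self._draws.pop(0)) % int(n)


@pytest.fixture
def scripted_rng():
    return ScriptedRng
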