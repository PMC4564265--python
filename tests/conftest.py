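import numpy as np
import pytest

from leafsignal import CANONICAL_GRID, Spectrum, build_receptor_set
from leafsignal.simulate import ARCHETYPES, generate_leaf_spectrum


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pieris_set():
    return build_receptor_set("pieris")


@pytest.fixture(scope="session")
def aphid_set():
    return build_receptor_set("aphid")


@pytest.fixture(scope="session")
def archetype_panel():
    """30 synthetic spectra per archetype from a fixed stream."""
    rng = np.random.default_rng(777)
    return {
        arch: [generate_leaf_spectrum(arch, rng, f"{arch}{i}") for i in range(30)]
        for arch in ARCHETYPES
    }


@pytest.fixture()
def flat_spectrum():
    return Spectrum(CANONICAL_GRID, np.full(CANONICAL_GRID.size, 0.5), sample_id="flat")
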