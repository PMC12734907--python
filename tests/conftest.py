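import numpy as np
import pytest

from pascdx.synth import SynthConfig, generate_descriptor_table, generate_library


def make_table(n_per_class=40, n_descriptors=12, n_informative=3, shift=1.5, seed=0):
    """A small labeled descriptor table with a planted class signal."""
    cfg = SynthConfig(
        n_descriptors=n_descriptors,
        n_informative=n_informative,
        descriptor_shift=shift,
        seed=seed,
    )
    lib = generate_library(2 * n_per_class, seed=seed)
    labels = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return generate_descriptor_table(lib, labels, cfg)


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def separable_table():
    """Strong signal: descriptor shift 5 SD — essentially separable."""
    return make_table(n_per_class=60, n_descriptors=10, n_informative=4, shift=5.0, seed=1)


@pytest.fixture
def null_table():
    """No class signal at all."""
    return make_table(n_per_class=60, n_descriptors=10, n_informative=0, shift=0.0, seed=2)
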