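import pytest

from rootslope import synthetic


@pytest.fixture
def taproot_archetype():
    """A deep-taproot archetype with strong, diameter-sensitive fine roots."""
    return synthetic.DEFAULT_ARCHETYPES["Pueraria stricta"]


@pytest.fixture
def creeper_archetype():
    """A linear-layout (underground stem) archetype."""
    return synthetic.DEFAULT_ARCHETYPES["Agave americana"]


@pytest.fixture
def noiseless_config():
    return synthetic.GeneratorConfig(seed=11, n_tensile=25, n_bending=10, noise_cv=0.0)
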