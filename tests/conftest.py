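import numpy as np
import pytest

from amyquant import SectionSpec, generate_section


@pytest.fixture(scope="session")
def default_section():
    """One default synthetic section shared across tests (read-only)."""
    spec = SectionSpec(seed=11)
    images, truth = generate_section(spec, section_id="s11", animal_id="A001")
    return spec, images, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
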