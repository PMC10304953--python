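import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from photoferro import (RedoxScenario, TitrationScenario, gen_titration_pair,
                        gen_toy_structure)


@pytest.fixture(scope="session")
def pioa_fixture():
    """Zero-noise titration pair planting the PioA-binding signature."""
    return gen_titration_pair(TitrationScenario.pioa_interface())


@pytest.fixture(scope="session")
def lhrc_fixture():
    """Zero-noise titration pair planting the LH-RC-binding signature."""
    return gen_titration_pair(TitrationScenario.lhrc_interface())


@pytest.fixture(scope="session")
def toy_structure():
    """30-residue toy helix with the SF4 cluster against residues 5-8."""
    return gen_toy_structure(30, [5, 6, 7, 8], seed=0)


@pytest.fixture(scope="session")
def pioc_like_scenario():
    return RedoxScenario.pioc_like(noise_sigma=0.0)
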