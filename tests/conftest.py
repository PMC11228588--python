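import numpy as np
import pytest

from sonocryst.constants import MolecularParams, molecular_volume_from_density


@pytest.fixture(scope="session")
def fdp_mol() -> MolecularParams:
    """Solute molecular parameters: trisodium salt of a 340.12 g/mol diphosphate.

    The crystal density is not published; 1.8 g/cm^3 is a representative
    value for a hydrated organophosphate sodium salt and only enters tests
    through v, never through an asserted absolute gamma.
    """
    mw_salt = 340.12 - 3 * 1.008 + 3 * 22.99
    v = molecular_volume_from_density(mw_salt, 1.8)
    return MolecularParams(molecular_volume=v)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
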