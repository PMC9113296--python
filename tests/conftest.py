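import sys
from pathlib import Path

import pytest
from hypothesis import settings

from naworm.fixtures import write_fixture_set
from naworm.pseudotorsion import compute_pseudotorsions
from naworm.structure_io import read_structure

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """Directory holding the standard synthetic structures."""
    d = tmp_path_factory.mktemp("fixtures")
    write_fixture_set(d)
    return d


@pytest.fixture(scope="session")
def aform_chain(fixture_dir):
    (chain,) = read_structure(fixture_dir / "aform12.pdb")
    return chain


@pytest.fixture(scope="session")
def bform_chains(fixture_dir):
    return read_structure(fixture_dir / "bduplex10.pdb")


@pytest.fixture(scope="session")
def aform_records(aform_chain):
    return compute_pseudotorsions(aform_chain, mode="both")
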