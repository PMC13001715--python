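import numpy as np
import pytest

from cuepr.structure import (
    Atom,
    DistanceTable,
    Structure,
    detect_metal_sites,
    pairwise_distances,
)
from cuepr.synthetic import DecoySpec, make_decoy_structure


@pytest.fixture(scope="session")
def decoy_structure() -> Structure:
    return make_decoy_structure(DecoySpec(seed=1))


@pytest.fixture(scope="session")
def decoy_table(decoy_structure) -> DistanceTable:
    sites = detect_metal_sites(decoy_structure)
    return pairwise_distances(sites)


def make_atom(serial, x, y, z, name="CU", element="Cu", resname="CU",
              resnum=1, chain="A", occ=1.0, b=20.0):
    """Terse Atom constructor for hand-built geometries."""
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain_id=chain, position=(x, y, z),
        occupancy=occ, b_factor=b,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
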