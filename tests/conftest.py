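import numpy as np
import pytest

from coatmap.structures import Atom, Chain, Residue, Structure
from coatmap.synthetic import ComplexScenario, generate_complex


def make_residue(chain_id, seq_id, res_type, coords, radius=1.87, names=None):
    atoms = [
        Atom(names[i] if names else ("CA" if i == 0 else f"X{i}"), "C",
             np.asarray(c, dtype=float), radius)
        for i, c in enumerate(coords)
    ]
    return Residue(chain_id=chain_id, seq_id=seq_id, icode="",
                   res_type=res_type, atoms=atoms)


def make_ca_chain(chain_id, ca_coords, res_type="ALA", radius=1.87):
    residues = [
        make_residue(chain_id, i + 1, res_type, [c], radius=radius, names=["CA"])
        for i, c in enumerate(ca_coords)
    ]
    return Chain(chain_id=chain_id, residues=residues)


@pytest.fixture(scope="session")
def helix_complex():
    """One deterministic two-chain helix complex with ground-truth labels."""
    return generate_complex(ComplexScenario(seed=11))


@pytest.fixture(scope="session")
def small_structure():
    """Three CA-only chains: A touches B, B touches C, A far from C."""
    a = make_ca_chain("A", [[0, 0, 0], [3.8, 0, 0]])
    b = make_ca_chain("B", [[3.8 + 4.5, 0, 0], [3.8 + 8.3, 0, 0]])
    c = make_ca_chain("C", [[3.8 + 8.3 + 4.9, 0, 0], [3.8 + 8.3 + 8.7, 0, 0]])
    return Structure(chains=[a, b, c], source_id="toy")
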