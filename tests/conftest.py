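import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # tests/oracles.py

from multimeralign.structures import ChainStructure, ComplexStructure


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_placed_complex(complex_id, chain_specs):
    """Assemble a complex from (chain_id, coords) pairs with ALA residues."""
    chains = []
    for chain_id, coords in chain_specs:
        n = len(coords)
        chains.append(
            ChainStructure(chain_id, coords, ["ALA"] * n, [(i + 1, "") for i in range(n)])
        )
    return ComplexStructure(complex_id, chains)
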