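import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from miniclust import synth
from miniclust.align import STANDARD_AA, blosum62


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture(scope="session")
def canonical_families():
    """The canonical planted-family fixture: 3 families x 5 members,
    length 200, within-family identity 0.95, seed 42."""
    spec = synth.FamilySpec(
        n_families=3, members_per_family=5, seq_len=200,
        within_identity=0.95, fragment_prob=0.1, seed=42,
    )
    return synth.generate_families(spec)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))
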