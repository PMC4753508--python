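import numpy as np
import pytest

from colchain import ProCollagenChain
from colchain.reference import CANDIDATE_TRIMERS, zebrafish_like_compositions


@pytest.fixture(scope="session")
def zebra_comps():
    """Zebrafish-like triple-helix composition vectors for the three chains."""
    return zebrafish_like_compositions()


@pytest.fixture(scope="session")
def candidates():
    """The canonical single-alpha2 candidate stoichiometries."""
    return CANDIDATE_TRIMERS


@pytest.fixture
def random_chain_pair():
    """Factory for short random chain pairs (seeded)."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"

    def make(seed: int, max_len: int = 8):
        rng = np.random.default_rng(seed)
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        a = "".join(rng.choice(list(alphabet), size=la))
        b = "".join(rng.choice(list(alphabet), size=lb))
        return (
            ProCollagenChain(id=f"ra{seed}", sequence=a),
            ProCollagenChain(id=f"rb{seed}", sequence=b),
        )

    return make
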