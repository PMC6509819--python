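import random

import pytest
from hypothesis import settings

from gmcnet.simulate import SyntheticConfig, simulate_superfamily

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic superfamily (5 families x 30, length 550, seed 1)."""
    return simulate_superfamily(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A cheap superfamily for graph/identity tests (3 families x 6, length 160)."""
    return simulate_superfamily(SyntheticConfig(
        seed=7, n_families=3, seqs_per_family=6, length=160,
        accessory_domains=(None, None, None),
        pts_tripeptides=(None, None, None),
        indel_rate=0.5,
    ))


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))
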