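import random
import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # listings / oracles helpers

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")

from recphylo.io import read_recphylo  # noqa: E402
from recphylo.model import SpeciesNode  # noqa: E402
from recphylo.simulate import DatedSpeciesTree, SimParams, simulate_dataset  # noqa: E402

import listings  # noqa: E402


@pytest.fixture(scope="session")
def listing_documents():
    """Parsed canonical example documents, one per event tag."""
    return {name: read_recphylo(xml)[0] for name, xml in listings.EVENT_TAG_DOCUMENTS.items()}


@pytest.fixture(scope="session")
def species_bca() -> SpeciesNode:
    """Species tree (B,C)A used throughout the canonical examples."""
    return SpeciesNode(
        name="A", children=(SpeciesNode(name="B"), SpeciesNode(name="C"))
    )


@pytest.fixture(scope="session")
def dated_tree() -> DatedSpeciesTree:
    return DatedSpeciesTree.from_newick("((A:1,B:1)AB:1,C:2)R:0.5;")


@pytest.fixture(scope="session")
def simulated_corpus(dated_tree):
    """A mixed corpus of simulated documents exercising every event tag."""
    docs = []
    for seed in range(30):
        params = SimParams(
            dup_rate=0.3,
            transfer_rate=0.4,
            loss_rate=0.3,
            unsampled_bifurcation_prob=0.3,
            n_families=2,
            seed=seed,
        )
        docs.append(simulate_dataset(dated_tree, params))
    return docs


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240901)
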