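import itertools
import random

import pytest

from ddiverify import (
    CandidateComplex,
    DDICatalog,
    DomainAnnotation,
    InteractionNetwork,
    build_model,
    worked_example,
)


@pytest.fixture
def example_model():
    """The three-protein worked example: 2 potential PPIs, 4 potential DDIs."""
    network, domains, catalog = worked_example()
    return build_model({"p1", "p2", "p3"}, network, domains, catalog)


def random_model(rng: random.Random, max_ddi_vars: int = 20):
    """Draw a random small candidate model for oracle-equivalence checks.

    Proteins get 1-3 instances over a small domain-type pool, a random
    subset of type pairs is cataloged, and a random subset of protein pairs
    is in the potential-PPI set. Redrawn until the DDI variable count fits.
    """
    while True:
        n_prot = rng.randint(3, 6)
        proteins = [f"P{i}" for i in range(n_prot)]
        types = [f"T{i}" for i in range(rng.randint(2, 5))]
        counts = {
            p: {t: rng.randint(1, 2) for t in rng.sample(types, rng.randint(1, min(3, len(types))))}
            for p in proteins
        }
        all_type_pairs = [
            (a, b) for i, a in enumerate(types) for b in types[i:]
        ]
        catalog = DDICatalog.from_pairs(
            rng.sample(all_type_pairs, rng.randint(1, len(all_type_pairs)))
        )
        all_pairs = list(itertools.combinations(proteins, 2))
        edges = rng.sample(all_pairs, rng.randint(1, len(all_pairs)))
        network = InteractionNetwork.from_edges(edges, extra_proteins=proteins)
        model = build_model(proteins, network, DomainAnnotation.from_counts(counts), catalog)
        if 0 < model.n_ddi_vars <= max_ddi_vars:
            return model


@pytest.fixture
def triangle_network():
    return InteractionNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


def make_candidate(members, source="imported"):
    return CandidateComplex(frozenset(members), source)
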