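import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from conceptnorm.ontology import Concept, Ontology, build_concept_vectors
from conceptnorm.text import EmbeddingTable
from conceptnorm import synthetic


@pytest.fixture
def chain_ontology() -> Ontology:
    """C is_a B is_a A."""
    return Ontology(
        [
            Concept(id="A", preferred_label="a thing"),
            Concept(id="B", preferred_label="b thing", parents={"A"}),
            Concept(id="C", preferred_label="c thing", parents={"B"}),
        ]
    )


@pytest.fixture
def diamond_ontology() -> Ontology:
    """D is_a {B, C}; B, C is_a A."""
    return Ontology(
        [
            Concept(id="A", preferred_label="top"),
            Concept(id="B", preferred_label="left", parents={"A"}),
            Concept(id="C", preferred_label="right", parents={"A"}),
            Concept(id="D", preferred_label="bottom", parents={"B", "C"}),
        ]
    )


@pytest.fixture
def toy_table() -> EmbeddingTable:
    return EmbeddingTable(
        dimension=3,
        vectors={
            "a": np.array([1.0, 0.0, 0.0]),
            "b": np.array([0.0, 1.0, 0.0]),
            "c": np.array([0.0, 0.0, 1.0]),
        },
    )


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One mid-size synthetic world shared by the slower tests."""
    spec = synthetic.SyntheticSpec(
        n_concepts=30,
        embedding_dim=20,
        n_mentions=150,
        examples_per_concept_dist=(4.0, 1.0),
        parent_token_prob=0.1,
        seed=11,
    )
    ontology = synthetic.generate_ontology(spec)
    table = synthetic.generate_embeddings(ontology, spec.embedding_dim, spec.seed)
    corpus = synthetic.generate_corpus(ontology, spec)
    space = build_concept_vectors(ontology, 0.6)
    return spec, ontology, table, corpus, space
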