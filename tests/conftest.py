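import numpy as np
import pytest

from kgenfm.kg import KnowledgeGraph, Triple
from kgenfm.synth import SynthConfig, generate


@pytest.fixture
def path_kg():
    """Path graph a-b-c-d as three triples."""
    return KnowledgeGraph(
        triples=[Triple("a", "r", "b"), Triple("b", "r", "c"), Triple("c", "r", "d")]
    )


@pytest.fixture
def star_kg():
    """Star K1,4: hub h with 4 leaves."""
    return KnowledgeGraph(
        triples=[Triple("h", "r", f"l{i}") for i in range(4)]
    )


def random_kg(rng: np.random.Generator, n_nodes: int, p: float) -> KnowledgeGraph:
    """Erdos-Renyi undirected graph encoded as triples."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    triples = [
        Triple(nodes[i], "e", nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return KnowledgeGraph(triples=triples), nodes


@pytest.fixture(scope="session")
def small_bench():
    """Small planted benchmark shared by pipeline-level tests."""
    return generate(
        SynthConfig(
            n_drugs=40, n_proteins=30, n_diseases=12, n_pathways=8,
            n_positives=150, n_hetero_edges=800, seq_length_range=(40, 80),
            fingerprint_bits=32, fingerprint_signal_bits=8, seed=7,
        )
    )
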