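import numpy as np
import pytest

from multidiff import (
    DiseaseSignature,
    CompoundRecord,
    Node,
    TypedEdge,
    build_network,
    build_transition_matrix,
)


def random_typed_network(rng, max_nodes=100, allow_isolated=True):
    """A random multiscale network for property tests.

    Mixes proteins and functions, draws ppi/annotation edges at random and a
    hierarchy whose child index always exceeds the parent index (acyclic by
    construction). Isolated nodes (dangling rows) are left in on purpose.
    """
    n_prot = int(rng.integers(2, max(3, max_nodes * 2 // 3)))
    n_func = int(rng.integers(1, max(2, max_nodes - n_prot)))
    prot = [f"P{i:03d}" for i in range(n_prot)]
    func = [f"F{i:03d}" for i in range(n_func)]
    nodes = [Node(p, "protein") for p in prot] + [Node(f, "function") for f in func]

    edges = []
    for _ in range(int(rng.integers(1, 3 * n_prot))):
        a, b = rng.choice(n_prot, size=2, replace=False)
        edges.append(TypedEdge(prot[a], prot[b], "ppi"))
    for _ in range(int(rng.integers(0, 2 * n_prot))):
        a = int(rng.integers(n_prot))
        f = int(rng.integers(n_func))
        edges.append(TypedEdge(prot[a], func[f], "annotation"))
    for child in range(1, n_func):
        if rng.random() < 0.8:
            parent = int(rng.integers(child))
            edges.append(TypedEdge(func[child], func[parent], "hierarchy"))
    if not allow_isolated:
        touched = {e.source for e in edges} | {e.target for e in edges}
        nodes = [n for n in nodes if n.id in touched]
        if len(nodes) < 2:
            nodes = [Node(prot[0], "protein"), Node(prot[1], "protein")]
            edges = [TypedEdge(prot[0], prot[1], "ppi")]
    # deduplication of repeats is the builder's job
    return build_network(nodes, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20240402)


@pytest.fixture
def tiny_net():
    """Two proteins, one function; one ppi and one annotation edge from P1."""
    nodes = [Node("P1", "protein"), Node("P2", "protein"), Node("F1", "function")]
    edges = [TypedEdge("P1", "P2", "ppi"), TypedEdge("P1", "F1", "annotation")]
    return build_network(nodes, edges)


@pytest.fixture
def two_protein_net():
    nodes = [Node("A", "protein"), Node("B", "protein")]
    return build_network(nodes, [TypedEdge("A", "B", "ppi")])


@pytest.fixture
def chain_net():
    """Protein chain T1–M1–D1 plus a function annotated to M1."""
    nodes = [
        Node("D1", "protein"),
        Node("M1", "protein"),
        Node("T1", "protein"),
        Node("F1", "function"),
    ]
    edges = [
        TypedEdge("T1", "M1", "ppi"),
        TypedEdge("M1", "D1", "ppi"),
        TypedEdge("M1", "F1", "annotation"),
    ]
    return build_network(nodes, edges)


@pytest.fixture
def small_benchmark():
    from multidiff import SyntheticConfig, generate_benchmark

    cfg = SyntheticConfig(
        n_proteins=120, n_functions=40, n_compounds=14, n_planted_positives=5,
        disease_module_size=12, targets_min=3, targets_max=12, seed=7,
    )
    return generate_benchmark(cfg)
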