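import numpy as np
import pytest

from lakebbn.core import CPT, NetworkSpec, NodeSpec
from lakebbn.maninjau import build_default_network


def make_node(name, states, parents=(), rows=None):
    cpt = CPT(np.asarray(rows, dtype=float)) if rows is not None else None
    return NodeSpec(name=name, states=tuple(states), parents=tuple(parents), cpt=cpt)


@pytest.fixture(scope="session")
def lake_network():
    """The shipped 35-node Lake Maninjau network (expensive-ish; share it)."""
    return build_default_network()


@pytest.fixture
def chain_abc():
    """A -> B -> C with simple binary CPTs."""
    return NetworkSpec(
        [
            make_node("A", ["a1", "a2"], rows=[[0.3, 0.7]]),
            make_node("B", ["b1", "b2"], ["A"], rows=[[0.5, 0.5], [0.9, 0.1]]),
            make_node("C", ["c1", "c2"], ["B"], rows=[[0.2, 0.8], [0.6, 0.4]]),
        ]
    )


@pytest.fixture
def collider():
    """A -> C <- B (classic v-structure)."""
    return NetworkSpec(
        [
            make_node("A", ["y", "n"], rows=[[0.4, 0.6]]),
            make_node("B", ["y", "n"], rows=[[0.7, 0.3]]),
            make_node(
                "C",
                ["y", "n"],
                ["A", "B"],
                rows=[[0.9, 0.1], [0.5, 0.5], [0.3, 0.7], [0.05, 0.95]],
            ),
        ]
    )


def random_network(rng: np.random.Generator, n_nodes=None, max_states=4) -> NetworkSpec:
    """Random DAG over lexicographic order with Dirichlet CPT rows."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 9))
    names = [f"N{i:02d}" for i in range(n_nodes)]
    cards = rng.integers(2, max_states + 1, size=n_nodes)
    nodes = []
    for i, name in enumerate(names):
        k = int(cards[i])
        candidates = names[:i]
        n_parents = int(rng.integers(0, min(3, len(candidates)) + 1))
        parents = sorted(
            rng.choice(candidates, size=n_parents, replace=False).tolist()
        )
        n_rows = int(np.prod([cards[names.index(p)] for p in parents])) if parents else 1
        rows = rng.dirichlet(np.ones(k), size=n_rows)
        nodes.append(
            NodeSpec(
                name=name,
                states=tuple(f"s{j}" for j in range(k)),
                parents=tuple(parents),
                cpt=CPT(rows),
            )
        )
    return NetworkSpec(nodes)


def random_evidence(rng: np.random.Generator, spec: NetworkSpec, max_nodes=2) -> dict:
    names = list(spec.nodes)
    n = int(rng.integers(0, max_nodes + 1))
    picked = rng.choice(names, size=min(n, len(names)), replace=False)
    return {
        name: spec.node(name).states[int(rng.integers(spec.card(name)))]
        for name in picked
    }
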