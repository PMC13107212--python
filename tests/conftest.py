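import numpy as np
import pytest

from pathkin import NetworkKinetics, benchmark_spec, build_rate_matrix, generate_network
from pathkin.network import NetworkNode, PathEdge, ReactionPathNetwork


def random_reversible_network(rng, n, temperature=333.15,
                              node_spread=(0.0, 60.0), barrier=(5.0, 150.0)):
    """Connected random network: spanning tree plus extra reversible paths."""
    nodes = {f"N{i:02d}": NetworkNode(float(rng.uniform(*node_spread)))
             for i in range(n)}
    ids = list(nodes)
    edges = []
    for k in range(1, n):
        a, b = ids[k], ids[int(rng.integers(0, k))]
        ts = max(nodes[a].gibbs, nodes[b].gibbs) + rng.uniform(*barrier)
        edges.append(PathEdge(f"E{k}", a, b, ts))
    for k in range(n):
        a, b = ids[int(rng.integers(n))], ids[int(rng.integers(n))]
        if a == b:
            continue
        ts = max(nodes[a].gibbs, nodes[b].gibbs) + rng.uniform(*barrier)
        edges.append(PathEdge(f"X{k}", a, b, ts))
    return ReactionPathNetwork(nodes, edges, temperature)


@pytest.fixture(scope="session")
def benchmark_run():
    """One fitted benchmark model (programmed 11.6 kJ/mol gap), shared."""
    spec = benchmark_spec(programmed_ddg=11.6, seed=3)
    network, truth = generate_network(spec)
    model = NetworkKinetics(network, reactant_nodes=truth["reactant_nodes"])
    return model.fit(), truth


@pytest.fixture
def two_state():
    """Symmetric two-state network A <-> B with a 30 kJ/mol barrier."""
    net = ReactionPathNetwork(
        {"A": NetworkNode(0.0), "B": NetworkNode(0.0)},
        [PathEdge("e1", "A", "B", 30.0)],
        333.15,
    )
    return build_rate_matrix(net)
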