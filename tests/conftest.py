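import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bigrehab.network import CPT, BayesNet, Node, default_network

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture
def default_net() -> BayesNet:
    return default_network()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_net(rng: np.random.Generator, n_nodes: int = 5, max_states: int = 3,
               p_edge: float = 0.5) -> BayesNet:
    """Random small DAG with Dirichlet-ish CPTs, for oracle cross-checks."""
    nodes = [
        Node(f"X{i}", tuple(range(int(rng.integers(2, max_states + 1)))))
        for i in range(n_nodes)
    ]
    edges = [
        (f"X{i}", f"X{j}")
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    net = BayesNet(nodes, edges)
    for nid in net.nodes:
        parents = net.parents(nid)
        shape = tuple(net.cardinality(p) for p in parents) + (net.cardinality(nid),)
        t = rng.gamma(1.0, size=shape) + 0.05
        net.set_cpt(CPT(nid, parents, t / t.sum(-1, keepdims=True)))
    return net


def brute_force_joint(net: BayesNet, evidence=None) -> dict[tuple, float]:
    """Independent joint-table oracle: explicit loop over all state tuples."""
    evidence = evidence or {}
    order = list(net.nodes)
    out = {}
    for combo in itertools.product(*(net.nodes[n].states for n in order)):
        assign = dict(zip(order, combo))
        if any(assign[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for nid in order:
            cpt = net.cpts[nid]
            idx = tuple(net.state_index(par, assign[par]) for par in cpt.parents)
            p *= cpt.table[idx + (net.state_index(nid, assign[nid]),)]
        out[combo] = p
    total = sum(out.values())
    return {k: v / total for k, v in out.items()} if total > 0 else out


def brute_force_marginal(net: BayesNet, node: str, evidence=None) -> np.ndarray:
    joint = brute_force_joint(net, evidence)
    order = list(net.nodes)
    k = order.index(node)
    vec = np.zeros(net.cardinality(node))
    for combo, p in joint.items():
        vec[net.state_index(node, combo[k])] += p
    return vec
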