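"""Discrete Bayesian network: structure, MLE/Dirichlet parameter learning,
and exact inference.

The clinical network has eleven nodes: the injury grade P1 (Levels I-III,
coded 0/1/2), two joint-repair nodes R1 (talocrural) and R2 (subtalar,
recovered=0 / impaired=1), four functional-state nodes B1-B4 (normal=0 /
mildly=1 / severely restricted=2), and four rehabilitation-goal nodes G1-G4
(achieved=0 / not achieved=1).  Edges run P1 -> {R1, R2}, each B node hangs
off a single repair node, and every G node has parents {R1, R2}.

Two exact-inference routes are provided -- full joint enumeration and
variable elimination -- and are required to agree; tests exercise both.
All distributions are kept in linear space: with at most eleven nodes and
no probability below ~1e-3 in the shipped tables, float64 products cannot
underflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateEvidenceError, StructureError, ValidationError

__all__ = [
    "Node",
    "CPT",
    "BayesNet",
    "PosteriorState",
    "build_network",
    "default_network_config",
    "default_network",
    "learn_parameters",
    "update_observation_nodes",
    "posterior_intermediate",
    "posterior_target",
    "exact_inference",
    "train_validation_split",
]

_ATOL = 1e-6


@dataclass(frozen=True)
class Node:
    id: str
    states: tuple[Hashable, ...]

    @property
    def cardinality(self) -> int:
        return len(self.states)


@dataclass
class CPT:
    """Conditional probability table: one row per parent configuration.

    ``table`` has shape ``(*parent_cardinalities, child_cardinality)``;
    every slice along the last axis sums to one.
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray
    pseudocount: float = 0.0

    def validate(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
            raise ValidationError(f"CPT for {self.node}: entries outside [0, 1]")
        sums = t.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError(
                f"CPT for {self.node}: rows must sum to 1 (max deviation "
                f"{np.abs(sums - 1).max():.3g})"
            )


@dataclass
class PosteriorState:
    """Marginals over every node together with the evidence that produced
    them and a tag naming the update route."""

    marginals: dict[str, np.ndarray]
    evidence: dict[str, Hashable] = field(default_factory=dict)
    update_order: str = "exact"

    def entropy(self, node: str) -> float:
        """Shannon entropy (bits) of one marginal."""
        p = self.marginals[node]
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


class BayesNet:
    """A DAG over discrete nodes plus one CPT per node."""

    def __init__(self, nodes: Sequence[Node], edges: Iterable[tuple[str, str]],
                 cpts: Mapping[str, CPT] | None = None):
        self.nodes: dict[str, Node] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise StructureError("duplicate node ids")
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.nodes)
        for u, v in edges:
            if u not in self.nodes or v not in self.nodes:
                raise StructureError(f"edge ({u}, {v}) references unknown node")
            self.graph.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise StructureError(f"graph contains a cycle: {cycle}")
        self.cpts: dict[str, CPT] = {}
        for nid in self.nodes:
            if cpts is not None and nid in cpts:
                self.set_cpt(cpts[nid])
            else:
                self.set_cpt(self._uniform_cpt(nid))

    # -- structure ---------------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self.graph.predecessors(node)))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self.graph.successors(node)))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def cardinality(self, node: str) -> int:
        return self.nodes[node].cardinality

    def state_index(self, node: str, state: Hashable) -> int:
        try:
            return self.nodes[node].states.index(state)
        except ValueError:
            raise ValidationError(
                f"state {state!r} not in {node}'s states "
                f"{self.nodes[node].states}"
            ) from None

    def _uniform_cpt(self, node: str) -> CPT:
        parents = self.parents(node)
        shape = tuple(self.cardinality(p) for p in parents) + (self.cardinality(node),)
        table = np.full(shape, 1.0 / self.cardinality(node))
        return CPT(node, parents, table)

    def set_cpt(self, cpt: CPT) -> None:
        if cpt.node not in self.nodes:
            raise StructureError(f"CPT references unknown node {cpt.node}")
        if tuple(cpt.parents) != self.parents(cpt.node):
            raise StructureError(
                f"CPT parents {cpt.parents} do not match in-edges "
                f"{self.parents(cpt.node)} of {cpt.node}"
            )
        cpt.table = np.asarray(cpt.table, dtype=float)
        expected = tuple(self.cardinality(p) for p in cpt.parents) + (
            self.cardinality(cpt.node),
        )
        if cpt.table.shape != expected:
            raise StructureError(
                f"CPT for {cpt.node}: shape {cpt.table.shape} != {expected}"
            )
        cpt.validate()
        self.cpts[cpt.node] = cpt

    def copy(self) -> "BayesNet":
        return BayesNet(
            list(self.nodes.values()),
            list(self.graph.edges),
            {
                nid: CPT(c.node, c.parents, c.table.copy(), c.pseudocount)
                for nid, c in self.cpts.items()
            },
        )

    # -- serialization -----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "nodes": [
                {
                    "id": nid,
                    "states": list(node.states),
                    "parents": list(self.parents(nid)),
                }
                for nid, node in self.nodes.items()
            ],
            "cpts": {
                nid: {
                    "parents": list(c.parents),
                    "table": np.asarray(c.table).tolist(),
                }
                for nid, c in self.cpts.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_config(), fh, indent=1)


def build_network(structure_config: Mapping) -> BayesNet:
    """Build and validate a network from a config mapping.

    The config lists ``nodes`` (id, states, parents) and optionally
    ``cpts`` (nested lists shaped like :class:`CPT` tables).  Nodes
    without a supplied table get a uniform prior/CPT.
    """
    if "nodes" not in structure_config:
        raise ValidationError("structure config missing 'nodes'")
    nodes = []
    edges = []
    for spec in structure_config["nodes"]:
        try:
            nid, states = spec["id"], tuple(spec["states"])
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed node spec {spec!r}") from exc
        if not states:
            raise ValidationError(f"node {nid}: empty state set")
        nodes.append(Node(nid, states))
        for p in spec.get("parents", []):
            edges.append((p, nid))
    net = BayesNet(nodes, edges)
    for nid, cspec in structure_config.get("cpts", {}).items():
        table = np.asarray(cspec["table"] if isinstance(cspec, Mapping) else cspec,
                           dtype=float)
        net.set_cpt(CPT(nid, net.parents(nid), table))
    return net


def default_network_config() -> dict:
    """Packaged default clinical network (structure + tables)."""
    text = resources.files("bigrehab.data").joinpath("network_default.json").read_text()
    return json.loads(text)


def default_network() -> BayesNet:
    return build_network(default_network_config())


# -- parameter learning ----------------------------------------------------


def _state_codes(net: BayesNet, cohort: pd.DataFrame, node: str) -> np.ndarray:
    col = cohort[node]
    states = net.nodes[node].states
    codes = pd.Categorical(col, categories=list(states)).codes
    if (codes < 0).any():
        bad = sorted(set(col[codes < 0]))
        raise ValidationError(f"column {node}: values {bad} outside states {states}")
    return np.asarray(codes, dtype=np.int64)


def learn_parameters(net: BayesNet, cohort: pd.DataFrame,
                     pseudocount: float = 0.0) -> BayesNet:
    """Fit every CPT by maximum likelihood with optional Dirichlet smoothing.

    Root priors are state frequencies; child rows are conditional
    frequencies within each parent stratum.  ``pseudocount`` is added to
    every cell before normalising (0 reproduces the pure MLE).  A parent
    stratum with zero observations and zero pseudocount is filled uniform
    and a warning is emitted.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    missing = [nid for nid in net.nodes if nid not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort is missing node columns {missing}")
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")

    fitted = net.copy()
    for nid in net.nodes:
        parents = net.parents(nid)
        card = net.cardinality(nid)
        shape = tuple(net.cardinality(p) for p in parents) + (card,)
        counts = np.zeros(shape)
        idx = tuple(_state_codes(net, cohort, p) for p in parents) + (
            _state_codes(net, cohort, nid),
        )
        np.add.at(counts, idx, 1.0)
        counts += pseudocount
        totals = counts.sum(axis=-1, keepdims=True)
        empty = totals[..., 0] == 0
        if empty.any():
            warnings.warn(
                f"{nid}: {int(empty.sum())} parent stratum(s) with zero count "
                "at pseudocount 0 filled uniform",
                stacklevel=2,
            )
            counts[empty] = 1.0
            totals = counts.sum(axis=-1, keepdims=True)
        fitted.set_cpt(CPT(nid, parents, counts / totals, pseudocount))
    return fitted


# -- inference -------------------------------------------------------------


def _check_evidence(net: BayesNet, evidence: Mapping[str, Hashable]) -> dict[str, int]:
    out = {}
    for node, state in evidence.items():
        if node not in net.nodes:
            raise ValidationError(f"evidence on unknown node {node}")
        out[node] = net.state_index(node, state)
    return out


def _expand(table: np.ndarray, dims: Sequence[int], n_axes: int) -> np.ndarray:
    """Broadcast a factor table whose axes live at positions ``dims``
    into an ``n_axes``-dimensional array (singleton elsewhere)."""
    order = np.argsort(dims)
    t = np.transpose(table, order)
    shape = [1] * n_axes
    for d, size in zip((dims[i] for i in order), t.shape):
        shape[d] = size
    return t.reshape(shape)


def _joint(net: BayesNet, evidence_idx: Mapping[str, int]) -> tuple[list[str], np.ndarray]:
    """Full joint table over all nodes with evidence zeroed out."""
    order = list(net.nodes)
    axis = {nid: k for k, nid in enumerate(order)}
    joint = np.ones(tuple(net.cardinality(n) for n in order))
    for nid in order:
        cpt = net.cpts[nid]
        dims = [axis[p] for p in cpt.parents] + [axis[nid]]
        joint = joint * _expand(cpt.table, dims, len(order))
    for nid, sidx in evidence_idx.items():
        mask = np.zeros(net.cardinality(nid))
        mask[sidx] = 1.0
        shape = [1] * len(order)
        shape[axis[nid]] = net.cardinality(nid)
        joint = joint * mask.reshape(shape)
    return order, joint


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[str, ...], table: np.ndarray):
        self.vars = vars
        self.table = table

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self.table.reshape(self.table.shape + (1,) * (len(out_vars) - len(self.vars)))
        b_axes = [v for v in out_vars if v in other.vars]
        b = np.transpose(other.table, [other.vars.index(v) for v in b_axes])
        shape = [1] * len(out_vars)
        for k, v in enumerate(b_axes):
            shape[out_vars.index(v)] = b.shape[k]
        b = b.reshape(shape)
        return _Factor(out_vars, a * b)

    def marginalize(self, var: str) -> "_Factor":
        k = self.vars.index(var)
        return _Factor(self.vars[:k] + self.vars[k + 1:], self.table.sum(axis=k))


def _variable_elimination(net: BayesNet, evidence_idx: Mapping[str, int],
                          query: str) -> np.ndarray:
    factors = []
    for nid in net.nodes:
        cpt = net.cpts[nid]
        factors.append(_Factor(cpt.parents + (nid,), cpt.table))
    for nid, sidx in evidence_idx.items():
        mask = np.zeros(net.cardinality(nid))
        mask[sidx] = 1.0
        factors.append(_Factor((nid,), mask))
    hidden = [n for n in net.topological_order() if n != query and n not in evidence_idx]
    # eliminate cheapest-first by current factor-join size
    for var in hidden:
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(var)]
    prod = factors[0]
    for f in factors[1:]:
        prod = prod.multiply(f)
    for nid in list(prod.vars):
        if nid != query:
            prod = prod.marginalize(nid)
    vec = prod.table if prod.vars == (query,) else prod.table.reshape(-1)
    total = vec.sum()
    if total <= 0:
        raise DegenerateEvidenceError("evidence has zero probability mass")
    return vec / total


def exact_inference(net: BayesNet, evidence: Mapping[str, Hashable] | None = None,
                    method: str = "auto") -> PosteriorState:
    """Posterior marginals of every node given hard evidence.

    ``method`` selects the algorithm: ``"enumeration"`` (full joint
    table), ``"elimination"`` (variable elimination), or ``"auto"``
    (enumeration while the joint stays small, elimination beyond that).
    The two algorithms must agree to float precision; tests assert this.
    """
    evidence = dict(evidence or {})
    evidence_idx = _check_evidence(net, evidence)
    marginals: dict[str, np.ndarray] = {}
    if method == "auto":
        joint_size = float(np.prod([net.cardinality(n) for n in net.nodes]))
        method = "enumeration" if joint_size <= 2e5 else "elimination"
    if method == "enumeration":
        order, joint = _joint(net, evidence_idx)
        total = joint.sum()
        if total <= 0:
            raise DegenerateEvidenceError("evidence has zero probability mass")
        joint = joint / total
        for k, nid in enumerate(order):
            marginals[nid] = joint.sum(axis=tuple(a for a in range(len(order)) if a != k))
    elif method == "elimination":
        for nid in net.nodes:
            if nid in evidence_idx:
                vec = np.zeros(net.cardinality(nid))
                vec[evidence_idx[nid]] = 1.0
                marginals[nid] = vec
            else:
                marginals[nid] = _variable_elimination(net, evidence_idx, nid)
    else:
        raise ValidationError(f"unknown inference method {method!r}")
    return PosteriorState(marginals, evidence, update_order=f"exact/{method}")


# -- hierarchical update steps --------------------------------------------


def update_observation_nodes(net: BayesNet, session_batch: pd.DataFrame,
                             nodes: Sequence[str] = ("B1", "B2", "B3", "B4"),
                             ) -> dict[str, np.ndarray]:
    """Replace observation-node marginals by batch frequencies.

    The functional-state nodes are observed directly each session; their
    updated marginal is simply the empirical frequency vector of the batch.
    """
    if len(session_batch) == 0:
        raise ValidationError("session batch is empty")
    out = {}
    for nid in nodes:
        if nid not in session_batch.columns:
            raise ValidationError(f"batch is missing column {nid}")
        codes = _state_codes(net, session_batch, nid)
        out[nid] = np.bincount(codes, minlength=net.cardinality(nid)) / len(session_batch)
    return out


def _prior_marginal(net: BayesNet, node: str) -> np.ndarray:
    return exact_inference(net, {}, method="elimination").marginals[node]


def posterior_intermediate(net: BayesNet, b_evidence: Mapping[str, Hashable],
                           r_nodes: Sequence[str] | None = None,
                           r_priors: Mapping[str, np.ndarray] | None = None,
                           ) -> dict[str, np.ndarray]:
    """Posterior over each repair node given observed functional states.

    Uses the Bayes-rule inversion P(R=r | b) ∝ P(R=r) · Π_j P(Bj=bj | R=r)
    over the evidenced children of R, which is exact when each B node has
    that single R parent (the default structure).  ``r_priors`` may supply
    precomputed prior marginals (e.g. when updating many records against
    one network).
    """
    evidence_idx = _check_evidence(net, b_evidence)
    if r_nodes is None:
        r_nodes = sorted({p for b in b_evidence for p in net.parents(b)})
    out = {}
    for rid in r_nodes:
        if r_priors is not None and rid in r_priors:
            post = np.asarray(r_priors[rid], dtype=float).copy()
        else:
            post = _prior_marginal(net, rid).copy()
        for bid, bidx in evidence_idx.items():
            if rid not in net.parents(bid):
                continue
            if net.parents(bid) != (rid,):
                raise ValidationError(
                    f"{bid} has parents {net.parents(bid)}; the product-form "
                    f"update requires the single parent {rid}"
                )
            post = post * net.cpts[bid].table[:, bidx]
        total = post.sum()
        if total <= 0:
            raise DegenerateEvidenceError(f"zero posterior mass for {rid}")
        out[rid] = post / total
    return out


def posterior_target(net: BayesNet, r_marginals: Mapping[str, np.ndarray],
                     g_nodes: Sequence[str] | None = None,
                     ) -> dict[str, np.ndarray]:
    """Goal-node distributions from repair-node marginals.

    P(G=g) = Σ_{r1,r2} P(G=g | r1, r2) · P(r1) · P(r2): the repair nodes
    are treated as independent marginals at this stage (the reading under
    which the study's printed goal posteriors are reproducible); the exact
    joint route is available through :func:`exact_inference`.
    """
    margs = {}
    for rid, vec in r_marginals.items():
        v = np.asarray(vec, dtype=float)
        if rid not in net.nodes:
            raise ValidationError(f"unknown node {rid}")
        if v.shape != (net.cardinality(rid),):
            raise ValidationError(f"marginal for {rid} has wrong length")
        if abs(v.sum() - 1.0) > _ATOL or (v < -1e-12).any():
            raise ValidationError(f"marginal for {rid} is not a distribution")
        margs[rid] = v
    if g_nodes is None:
        g_nodes = sorted(
            nid for nid in net.nodes
            if net.parents(nid) and set(net.parents(nid)) <= set(margs)
        )
    out = {}
    for gid in g_nodes:
        parents = net.parents(gid)
        if not set(parents) <= set(margs):
            raise ValidationError(f"missing marginals for parents of {gid}")
        weight = np.ones(())
        table = net.cpts[gid].table
        for k, p in enumerate(parents):
            shape = [1] * len(parents) + [1]
            shape[k] = len(margs[p])
            weight = weight * margs[p].reshape(shape)
        out[gid] = (table * weight).sum(axis=tuple(range(len(parents))))
    return out


# -- overfitting control ---------------------------------------------------


def train_validation_split(cohort: pd.DataFrame, fraction: float, seed: int,
                           net: BayesNet | None = None,
                           pseudocount: float = 1.0,
                           patient_col: str = "patient_id",
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Disjoint patient-level split plus a parameter-stability report.

    Returns ``(train, validation, report)`` where the report carries the
    largest absolute difference between train-fitted and full-fitted CPT
    cells (per node and overall) and the validation log-likelihood under
    the train-fitted network.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    patients = np.asarray(sorted(cohort[patient_col].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n_train = int(round(fraction * len(patients)))
    if n_train == 0 or n_train == len(patients):
        raise ValidationError(
            f"fraction {fraction} leaves an empty side for {len(patients)} patients"
        )
    train_ids = set(patients[:n_train])
    mask = cohort[patient_col].isin(train_ids)
    train, val = cohort[mask], cohort[~mask]

    report: dict = {
        "n_train_patients": n_train,
        "n_validation_patients": len(patients) - n_train,
    }
    if net is not None:
        full = learn_parameters(net, cohort, pseudocount)
        part = learn_parameters(net, train, pseudocount)
        per_node = {
            nid: float(np.abs(full.cpts[nid].table - part.cpts[nid].table).max())
            for nid in net.nodes
        }
        report["per_node_max_cpt_diff"] = per_node
        report["max_cpt_cell_diff"] = max(per_node.values())
        loglik = 0.0
        for nid in net.nodes:
            cpt = part.cpts[nid]
            idx = tuple(_state_codes(net, val, p) for p in cpt.parents) + (
                _state_codes(net, val, nid),
            )
            loglik += float(np.log(cpt.table[idx]).sum())
        report["validation_loglik"] = loglik
    return train, val, report
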