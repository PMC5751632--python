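"""Exact posterior inference on the modular tree.

Each submodule independently propagates likelihood messages from its evidence
leaves up to its shared root; the main module combines the four root messages
with the query prior — so modules exchange information only through shared
nodes, and the result is independent of the order submodules are processed.
Unobserved evidence is marginalized out (its message is uninformative), which
is what lets the recognizer keep answering when a sensor goes missing.

Messages are renormalized at every node (the tree analogue of log-space
stabilization), so products over the 64 leaves cannot underflow.  A
brute-force joint-enumeration oracle over small networks certifies the
message-passing posterior in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .cpt import CPTBank
from .structure import ModularBNStructure


@dataclass
class PosteriorReport:
    """Posterior of the query node plus per-submodule shared-node posteriors."""

    query_posterior: float  # P(query = first state | evidence); "eating" by default
    shared_node_posteriors: dict[str, float]
    decision: str  # "eating" or "non-eating"
    threshold: float


def classify(posterior: float, threshold: float) -> str:
    """Threshold the eating posterior; a tie at the threshold is 'eating'."""
    if not (0.0 <= posterior <= 1.0 and 0.0 <= threshold <= 1.0):
        raise ValueError("posterior and threshold must lie in [0, 1]")
    return "eating" if posterior >= threshold else "non-eating"


def _check_evidence(structure: ModularBNStructure, ev: dict[str, str]) -> None:
    for node, state in ev.items():
        if node not in structure.nodes:
            raise ValueError(f"evidence on unknown node {node!r}")
        spec = structure.nodes[node]
        if state not in spec.states:
            raise ValueError(
                f"state {state!r} invalid for node {node!r} (states {spec.states})"
            )


def _lambda(
    structure: ModularBNStructure,
    cpts: CPTBank,
    node: str,
    ev: dict[str, str],
    children: dict[str, list[str]],
) -> np.ndarray:
    """Normalized likelihood vector lambda(node) over the node's states."""
    states = structure.nodes[node].states
    lam = np.ones(len(states))
    if node in ev:
        lam = np.array([1.0 if s == ev[node] else 0.0 for s in states])
    for child in sorted(children[node]):
        lam_child = _lambda(structure, cpts, child, ev, children)
        table = cpts.tables[child]
        # message to parent: sum_c P(c | parent state) * lambda(c)
        msg = np.array(
            [float(table.row((s,)) @ lam_child) for s in states]
        )
        lam = lam * msg
        total = lam.sum()
        if total > 0:
            lam = lam / total  # rescale: stabilizes long products
    return lam


def infer_posterior(
    structure: ModularBNStructure,
    cpts: CPTBank,
    ev: dict[str, str],
    threshold: float = 0.6,
) -> PosteriorReport:
    """Exact query posterior given (possibly partial) evidence.

    ``ev`` maps evidence node ids to observed states; absent evidence is
    simply omitted and marginalized out.  Returns the posterior probability
    of the query node's first state (``true`` = eating in the default
    structure), the posterior of each submodule's shared root, and the
    thresholded decision.
    """
    _check_evidence(structure, ev)
    children: dict[str, list[str]] = {n: [] for n in structure.nodes}
    for e in structure.edges:
        children[e.parent].append(e.child)

    query = structure.query_node
    q_states = structure.nodes[query].states
    prior = cpts.tables[query].row(())

    # per-child lambda messages into the query node
    child_msgs: dict[str, np.ndarray] = {}
    for child in sorted(children[query]):
        lam_child = _lambda(structure, cpts, child, ev, children)
        table = cpts.tables[child]
        child_msgs[child] = np.array(
            [float(table.row((s,)) @ lam_child) for s in q_states]
        )

    belief = prior.copy()
    if query in ev:
        belief = belief * np.array([1.0 if s == ev[query] else 0.0 for s in q_states])
    for msg in child_msgs.values():
        belief = belief * msg
        total = belief.sum()
        if total > 0:
            belief = belief / total
    total = belief.sum()
    if total == 0:
        raise ValueError("evidence has zero probability under the model")
    belief = belief / total
    query_posterior = float(belief[0])

    # shared-node posteriors: combine the top-down message from the query
    # (prior x messages from the *other* children) with the node's own
    # bottom-up likelihood
    shared: dict[str, float] = {}
    for sub in structure.submodules:
        root = sub.root
        if root not in child_msgs:
            continue
        pi = prior.copy()
        if query in ev:
            pi = pi * np.array([1.0 if s == ev[query] else 0.0 for s in q_states])
        for child, msg in child_msgs.items():
            if child != root:
                pi = pi * msg
                t = pi.sum()
                if t > 0:
                    pi = pi / t
        lam_root = _lambda(structure, cpts, root, ev, children)
        table = cpts.tables[root]
        root_states = structure.nodes[root].states
        bel = np.array(
            [
                lam_root[i] * float(sum(table.row((q,))[i] * pi[j] for j, q in enumerate(q_states)))
                for i in range(len(root_states))
            ]
        )
        t = bel.sum()
        shared[root] = float(bel[0] / t) if t > 0 else float("nan")

    return PosteriorReport(
        query_posterior=query_posterior,
        shared_node_posteriors=shared,
        decision=classify(query_posterior, threshold),
        threshold=threshold,
    )


def brute_force_posterior(
    structure: ModularBNStructure,
    cpts: CPTBank,
    ev: dict[str, str],
) -> float:
    """Query posterior by full joint enumeration — the testing oracle.

    Multiplies ``P(N | Pa(N))`` over every node for every joint configuration
    consistent with the evidence, sums and normalizes.  Refuses joint state
    spaces beyond 2**20 configurations.
    """
    _check_evidence(structure, ev)
    nodes = structure.topological_order()
    sizes = [len(structure.nodes[n].states) for n in nodes]
    space = 1
    for s in sizes:
        space *= s
        if space > 2**20:
            raise ValueError("joint state space exceeds 2^20; refusing to enumerate")

    parent = {n: structure.parent_of(n) for n in nodes}
    query = structure.query_node
    q_first = structure.nodes[query].states[0]

    if all(s == 2 for s in sizes):
        return _brute_force_binary(structure, cpts, ev, nodes, parent, query)

    num = 0.0
    den = 0.0
    state_lists = [structure.nodes[n].states for n in nodes]
    for config in itertools.product(*state_lists):
        assign = dict(zip(nodes, config))
        if any(assign[n] != s for n, s in ev.items()):
            continue
        p = 1.0
        for n in nodes:
            table = cpts.tables[n]
            combo = () if parent[n] is None else (assign[parent[n]],)
            idx = table.states.index(assign[n])
            p *= float(table.row(combo)[idx])
        den += p
        if assign[query] == q_first:
            num += p
    if den == 0:
        raise ValueError("evidence has zero probability under the model")
    return num / den


def _brute_force_binary(structure, cpts, ev, nodes, parent, query) -> float:
    """Vectorized enumeration for all-binary networks: one bit per node."""
    n = len(nodes)
    pos = {node: i for i, node in enumerate(nodes)}
    idx = np.arange(1 << n, dtype=np.int64)
    bits = [(idx >> i) & 1 for i in range(n)]  # bit i = state index of node i

    joint = np.ones(1 << n)
    for node in nodes:
        table = cpts.tables[node]
        states = structure.nodes[node].states
        child_bit = bits[pos[node]]
        if parent[node] is None:
            row = np.asarray(table.row(()))
            joint = joint * row[child_bit]
        else:
            pstates = structure.nodes[parent[node]].states
            mat = np.array([np.asarray(table.row((ps,))) for ps in pstates])
            joint = joint * mat[bits[pos[parent[node]]], child_bit]
        if node in ev:
            joint = joint * (child_bit == states.index(ev[node]))

    den = joint.sum()
    if den == 0:
        raise ValueError("evidence has zero probability under the model")
    num = joint[bits[pos[query]] == 0].sum()  # state index 0 = first state
    return float(num / den)
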