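"""Conditional probability table learning by counting, with Laplace smoothing.

Every node's CPT is estimated from fully annotated windows: one pass over the
data increments, per node, the cell matching the observed (parent states,
child state) combination — the counting rule of the recognizer's training
algorithm, applied uniformly to every parent-child link of the tree (for a
depth-1 link child := context, parent := query, this is exactly
``P(I_i | Q) = num(I_i ∩ Q) / num(Q)``).  Learning cost is one increment per
node per window, hence linear in the number of windows.

Finalization turns counts into distributions with additive (Laplace)
smoothing ``alpha`` (default 1), keeping every probability strictly positive
so downstream products never vanish.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure import ModularBNStructure


@dataclass
class CountTable:
    """Raw co-occurrence counts for one node: (parent states, child state) -> n."""

    node_id: str
    parents: tuple[str, ...]
    states: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    counts: dict = field(default_factory=dict)  # (parent combo, child state) -> int

    def increment(self, parent_combo: tuple[str, ...], child_state: str) -> None:
        key = (parent_combo, child_state)
        self.counts[key] = self.counts.get(key, 0) + 1

    def row_counts(self, parent_combo: tuple[str, ...]) -> np.ndarray:
        return np.array(
            [self.counts.get((parent_combo, s), 0) for s in self.states], dtype=float
        )

    def parent_combos(self) -> list[tuple[str, ...]]:
        return [tuple(c) for c in itertools.product(*self.parent_states)]


@dataclass
class CountBank:
    """One CountTable per node plus the global window counter ``num_data``."""

    tables: dict[str, CountTable]
    num_data: int = 0

    # number of accumulate-driven increments, for the linear-cost contract
    n_increments: int = 0

    @classmethod
    def for_structure(cls, structure: ModularBNStructure) -> "CountBank":
        tables = {}
        for node_id, spec in structure.nodes.items():
            parent = structure.parent_of(node_id)
            parents = () if parent is None else (parent,)
            parent_states = tuple(structure.nodes[p].states for p in parents)
            tables[node_id] = CountTable(node_id, parents, spec.states, parent_states)
        return cls(tables=tables)

    def merge(self, other: "CountBank") -> "CountBank":
        """Bank equivalent to accumulating both banks' data jointly."""
        if set(self.tables) != set(other.tables):
            raise ValueError("banks cover different node sets")
        merged = CountBank(
            tables={
                nid: CountTable(t.node_id, t.parents, t.states, t.parent_states, dict(t.counts))
                for nid, t in self.tables.items()
            },
            num_data=self.num_data + other.num_data,
            n_increments=self.n_increments + other.n_increments,
        )
        for nid, t in other.tables.items():
            target = merged.tables[nid]
            for key, n in t.counts.items():
                target.counts[key] = target.counts.get(key, 0) + n
        return merged


def accumulate(bank: CountBank, assignment: dict[str, str]) -> CountBank:
    """Fold one fully annotated window into the bank (in place; returns it).

    ``assignment`` maps every node id to its observed state for the window.
    Increments ``num_data`` once and, per node, the single cell matching the
    node's state under its parents' states.  Order-independent: any
    permutation of the same windows yields the same bank.
    """
    for node_id in bank.tables:
        if node_id not in assignment:
            raise ValueError(f"assignment missing node {node_id!r}")
    bank.num_data += 1
    for node_id, table in bank.tables.items():
        child_state = assignment[node_id]
        if child_state not in table.states:
            raise ValueError(
                f"state {child_state!r} invalid for node {node_id!r} (states {table.states})"
            )
        combo = tuple(assignment[p] for p in table.parents)
        table.increment(combo, child_state)
        bank.n_increments += 1
    return bank


@dataclass
class CPTTable:
    """Finalized conditional distribution of one node given its parents."""

    node_id: str
    parents: tuple[str, ...]
    states: tuple[str, ...]
    probs: dict  # parent combo (tuple of states) -> np.ndarray over child states

    def row(self, parent_combo: tuple[str, ...]) -> np.ndarray:
        return self.probs[tuple(parent_combo)]


@dataclass
class CPTBank:
    """One CPTTable per node; ``alpha`` records the smoothing used."""

    tables: dict[str, CPTTable]
    alpha: float

    def to_json(self) -> dict:
        return {
            "alpha": self.alpha,
            "tables": {
                nid: {
                    "parents": list(t.parents),
                    "states": list(t.states),
                    "rows": [
                        {"parent_states": list(combo), "probs": [float(p) for p in dist]}
                        for combo, dist in t.probs.items()
                    ],
                }
                for nid, t in self.tables.items()
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CPTBank":
        tables = {}
        for nid, t in obj["tables"].items():
            probs = {
                tuple(r["parent_states"]): np.array(r["probs"], dtype=float)
                for r in t["rows"]
            }
            tables[nid] = CPTTable(nid, tuple(t["parents"]), tuple(t["states"]), probs)
        return cls(tables=tables, alpha=float(obj["alpha"]))


def finalize(bank: CountBank, alpha: float = 1.0) -> CPTBank:
    """Counts -> smoothed conditional distributions.

    Each row becomes ``(count + alpha) / (row_total + alpha * n_states)``.
    The root's single row is the smoothed empirical class frequency.  With
    ``alpha = 0`` an all-zero row has no defined distribution and raises.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    tables: dict[str, CPTTable] = {}
    for node_id, ct in bank.tables.items():
        probs = {}
        n_states = len(ct.states)
        for combo in ct.parent_combos():
            row = ct.row_counts(combo)
            total = row.sum()
            if total == 0 and alpha == 0:
                raise ValueError(
                    f"node {node_id!r}, parent states {combo}: no data and alpha=0 "
                    "leave the distribution undefined"
                )
            probs[combo] = (row + alpha) / (total + alpha * n_states)
        tables[node_id] = CPTTable(node_id, ct.parents, ct.states, probs)
    return CPTBank(tables=tables, alpha=alpha)
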