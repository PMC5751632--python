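"""Modular tree-structured network definition, validation and serialization.

The recognizer's network is a rooted tree oriented generatively from the
query node ("eating") down through intermediate context nodes to sensor-driven
evidence leaves.  It is partitioned into one *main module* (the query node plus
the four top-level context classes: subject, object, spatial and temporal
property) and four *submodules*, one per context class.  Each submodule is a
tree whose root is *shared* with the main module: the root is a leaf of the
main module and the sole communication channel between the submodule and the
rest of the network.

The default structure has 88 nodes: 1 query node, 23 intermediate (inference)
nodes mirroring the activity-theory / Five-W's context hierarchy, and 64
evidence nodes wired to per-window features of the nine sensor channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

QUERY_NODE = "eating"

#: The four shared nodes: submodule roots that appear as main-module leaves.
SHARED_NODES = (
    "subject_property",
    "object_property",
    "spatial_property",
    "temporal_property",
)

# Context hierarchy inside each submodule: parent -> children.  Leaf entries
# of this mapping are the low-level context properties that receive evidence.
_SUBMODULE_HIERARCHY: dict[str, dict[str, tuple[str, ...]]] = {
    "subject_property": {
        "subject_property": ("activity", "body", "operation"),
        "activity": ("wrist",),
        "wrist": ("position_of_hand", "dinnerware", "movement_of_hand"),
        "body": ("posture_body", "move_stop_body", "movement_of_body"),
        "operation": ("body_temperature", "posture_operation", "humidity_of_hand"),
    },
    "object_property": {
        "object_property": ("existence_of_food",),
    },
    "spatial_property": {
        "spatial_property": (
            "eating_place",
            "indoor_outdoor",
            "move_stop_spatial",
            "illuminance_of_space",
        ),
    },
    "temporal_property": {
        "temporal_property": ("eating_time",),
    },
}

# Evidence wiring: low-level context property -> window features observed by
# its evidence nodes.  One evidence node per (property, feature) pair; 64 in
# total.  The allocation is this package's own design (see docs/methods.md):
# wrist contexts watch the wrist accelerometer, body contexts the phone
# accelerometer, environmental contexts the wrist environmental channels.
DEFAULT_EVIDENCE_WIRING: dict[str, tuple[str, ...]] = {
    "position_of_hand": (
        "h_acc_x_mean", "h_acc_y_mean", "h_acc_z_mean",
        "h_acc_x_range", "h_acc_y_range", "h_acc_z_range",
    ),
    "dinnerware": (
        "h_acc_x_sd", "h_acc_y_sd", "h_acc_z_sd",
        "h_acc_x_range", "h_acc_y_range", "h_acc_z_range",
    ),
    "movement_of_hand": (
        "h_acc_x_sd", "h_acc_y_sd", "h_acc_z_sd",
        "h_acc_x_mean", "h_acc_y_mean", "h_acc_z_mean",
    ),
    "posture_body": (
        "acc_x_mean", "acc_y_mean", "acc_z_mean",
        "acc_x_range", "acc_y_range", "acc_z_range",
    ),
    "move_stop_body": (
        "acc_x_sd", "acc_y_sd", "acc_z_sd",
        "acc_x_range", "acc_y_range", "acc_z_range",
    ),
    "movement_of_body": (
        "acc_x_sd", "acc_y_sd", "acc_z_sd",
        "acc_x_mean", "acc_y_mean", "acc_z_mean",
    ),
    "body_temperature": ("h_temp_mean", "h_hum_mean"),
    "posture_operation": (
        "h_acc_x_mean", "h_acc_y_mean", "h_acc_z_mean",
        "acc_x_mean", "acc_y_mean", "acc_z_mean",
    ),
    "humidity_of_hand": ("h_hum_mean", "h_temp_mean"),
    "existence_of_food": (
        "h_temp_mean", "h_hum_mean", "h_acc_y_mean", "h_acc_y_sd",
    ),
    "eating_place": ("h_lux_mean", "h_temp_mean", "h_hum_mean"),
    "indoor_outdoor": ("h_lux_mean", "h_temp_mean"),
    "move_stop_spatial": (
        "acc_x_sd", "acc_y_sd", "acc_z_sd",
        "acc_x_mean", "acc_y_mean", "acc_z_mean",
    ),
    "illuminance_of_space": ("h_lux_mean",),
    "eating_time": ("h_lux_mean", "h_temp_mean"),
}

BINARY_STATES = ("true", "false")


@dataclass(frozen=True)
class NodeSpec:
    """One network node: its role, discrete states and owning module."""

    id: str
    role: str  # "query" | "inference" | "evidence"
    states: tuple[str, ...] = BINARY_STATES
    module_id: str = "main"


@dataclass(frozen=True)
class EdgeSpec:
    """A directed edge parent -> child (generative orientation)."""

    parent: str
    child: str


@dataclass(frozen=True)
class SubmoduleSpec:
    """A tree-shaped module; ``root`` is the node shared with the main module."""

    id: str
    root: str
    member_nodes: frozenset[str]
    member_edges: frozenset[EdgeSpec]


@dataclass
class ModularBNStructure:
    """The full modular network: node bank, edges and module partition."""

    nodes: dict[str, NodeSpec] = field(default_factory=dict)
    edges: list[EdgeSpec] = field(default_factory=list)
    main_module: SubmoduleSpec | None = None
    submodules: list[SubmoduleSpec] = field(default_factory=list)
    max_parents: int = 2

    # -- convenience accessors -------------------------------------------------

    @property
    def query_node(self) -> str:
        for spec in self.nodes.values():
            if spec.role == "query":
                return spec.id
        raise ValueError("structure has no query node")

    def nodes_with_role(self, role: str) -> list[str]:
        return [s.id for s in self.nodes.values() if s.role == role]

    @property
    def evidence_nodes(self) -> list[str]:
        return self.nodes_with_role("evidence")

    @property
    def inference_nodes(self) -> list[str]:
        return self.nodes_with_role("inference")

    def parent_of(self, node: str) -> str | None:
        parents = [e.parent for e in self.edges if e.child == node]
        if not parents:
            return None
        if len(parents) > 1:
            raise ValueError(f"node {node!r} has {len(parents)} parents")
        return parents[0]

    def children_of(self, node: str) -> list[str]:
        return [e.child for e in self.edges if e.parent == node]

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return list(nx.topological_sort(g))

    def copy(self) -> "ModularBNStructure":
        return ModularBNStructure(
            nodes=dict(self.nodes),
            edges=list(self.edges),
            main_module=self.main_module,
            submodules=list(self.submodules),
            max_parents=self.max_parents,
        )


def evidence_feature(node_id: str) -> str:
    """Feature name observed by an evidence node (``context/feature`` ids)."""
    if "/" not in node_id:
        raise ValueError(f"not an evidence node id: {node_id!r}")
    return node_id.split("/", 1)[1]


def build_default_structure() -> ModularBNStructure:
    """Build the default 88-node eating-activity network.

    Returns a structure with one query node (``eating``), 23 inference nodes
    following the subject/object/spatial/temporal context hierarchy, and 64
    evidence nodes allocated across the low-level context properties by
    :data:`DEFAULT_EVIDENCE_WIRING`.  Deterministic: repeated calls produce
    identical structures.
    """
    nodes: dict[str, NodeSpec] = {}
    edges: list[EdgeSpec] = []

    nodes[QUERY_NODE] = NodeSpec(QUERY_NODE, "query", BINARY_STATES, "main")
    main_nodes = {QUERY_NODE}
    main_edges = set()
    for shared in SHARED_NODES:
        nodes[shared] = NodeSpec(shared, "inference", BINARY_STATES, "main")
        edges.append(EdgeSpec(QUERY_NODE, shared))
        main_nodes.add(shared)
        main_edges.add(EdgeSpec(QUERY_NODE, shared))

    submodules: list[SubmoduleSpec] = []
    for shared in SHARED_NODES:
        module_id = shared.replace("_property", "")
        member_nodes = {shared}
        member_edges: set[EdgeSpec] = set()
        hierarchy = _SUBMODULE_HIERARCHY[shared]
        for parent, children in hierarchy.items():
            for child in children:
                nodes[child] = NodeSpec(child, "inference", BINARY_STATES, module_id)
                edge = EdgeSpec(parent, child)
                edges.append(edge)
                member_nodes.add(child)
                member_edges.add(edge)
        # attach evidence leaves to the low-level context properties
        properties = [
            c for cs in hierarchy.values() for c in cs if c not in hierarchy
        ]
        for prop in properties:
            for feat in DEFAULT_EVIDENCE_WIRING[prop]:
                vid = f"{prop}/{feat}"
                nodes[vid] = NodeSpec(vid, "evidence", BINARY_STATES, module_id)
                edge = EdgeSpec(prop, vid)
                edges.append(edge)
                member_nodes.add(vid)
                member_edges.add(edge)
        submodules.append(
            SubmoduleSpec(module_id, shared, frozenset(member_nodes), frozenset(member_edges))
        )

    main = SubmoduleSpec("main", QUERY_NODE, frozenset(main_nodes), frozenset(main_edges))
    return ModularBNStructure(
        nodes=nodes,
        edges=edges,
        main_module=main,
        submodules=submodules,
        max_parents=2,
    )


def validate_structure(s: ModularBNStructure) -> list[str]:
    """Check all structural invariants; return a list of violation messages.

    An empty list means the structure is valid.  Checked: state lists, DAG
    acyclicity, the parent-count bound, a single query node housed in the main
    module, per-submodule tree shape, shared-node joins (each submodule root is
    a main-module leaf), module disjointness up to shared roots, and
    reachability of every node from the query root.
    """
    violations: list[str] = []

    for spec in s.nodes.values():
        if len(set(spec.states)) < 2:
            violations.append(f"node {spec.id!r} has fewer than 2 distinct states")
        if spec.role not in ("query", "inference", "evidence"):
            violations.append(f"node {spec.id!r} has unknown role {spec.role!r}")

    known = set(s.nodes)
    for e in s.edges:
        if e.parent == e.child:
            violations.append(f"self-loop on {e.parent!r}")
        for end in (e.parent, e.child):
            if end not in known:
                violations.append(f"edge references unknown node {end!r}")

    g = nx.DiGraph()
    g.add_nodes_from(known)
    g.add_edges_from((e.parent, e.child) for e in s.edges if e.parent != e.child)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        members = sorted({u for u, _ in cycle})
        violations.append(f"cycle involving nodes {members}")
        return violations  # tree checks below assume a DAG

    for node in known:
        k = g.in_degree(node)
        if k > s.max_parents:
            violations.append(
                f"node {node!r} has {k} parents, exceeding max_parents={s.max_parents}"
            )

    queries = s.nodes_with_role("query")
    if len(queries) != 1:
        violations.append(f"expected exactly 1 query node, found {len(queries)}")
    for q in queries:
        if s.nodes[q].module_id != "main":
            violations.append(f"query node {q!r} lies outside the main module")

    modules = ([s.main_module] if s.main_module else []) + list(s.submodules)
    for mod in modules:
        if mod.root not in mod.member_nodes:
            violations.append(f"module {mod.id!r}: root {mod.root!r} is not a member")
            continue
        in_deg = {n: 0 for n in mod.member_nodes}
        for e in mod.member_edges:
            if e.child in in_deg:
                in_deg[e.child] += 1
        roots = sorted(n for n, d in in_deg.items() if d == 0)
        if roots != [mod.root]:
            violations.append(
                f"module {mod.id!r}: expected single root {mod.root!r}, "
                f"parentless nodes are {roots}"
            )
        multi = sorted(n for n, d in in_deg.items() if d > 1)
        if multi:
            violations.append(
                f"module {mod.id!r}: nodes with more than one in-module parent: {multi}"
            )
        if len(mod.member_edges) != len(mod.member_nodes) - 1:
            violations.append(
                f"module {mod.id!r}: {len(mod.member_edges)} edges for "
                f"{len(mod.member_nodes)} nodes is not a tree"
            )

    if s.main_module is not None:
        for sub in s.submodules:
            if sub.root not in s.main_module.member_nodes:
                violations.append(
                    f"submodule {sub.id!r} root {sub.root!r} is not shared with the main module"
                )
            elif any(e.parent == sub.root for e in s.main_module.member_edges):
                violations.append(
                    f"shared node {sub.root!r} is not a leaf of the main module"
                )
        # non-shared members of distinct submodules must be disjoint
        for i, a in enumerate(s.submodules):
            for b in s.submodules[i + 1:]:
                overlap = (a.member_nodes - {a.root}) & (b.member_nodes - {b.root})
                if overlap:
                    violations.append(
                        f"submodules {a.id!r} and {b.id!r} share non-root nodes "
                        f"{sorted(overlap)}"
                    )

    if queries and not violations:
        reachable = nx.descendants(g, queries[0]) | {queries[0]}
        unreachable = sorted(known - reachable)
        if unreachable:
            violations.append(f"nodes unreachable from the query root: {unreachable}")

    return violations


# -- serialization -------------------------------------------------------------


def _module_to_json(mod: SubmoduleSpec) -> dict:
    return {
        "id": mod.id,
        "root": mod.root,
        "nodes": sorted(mod.member_nodes),
        "edges": sorted([e.parent, e.child] for e in mod.member_edges),
    }


def _module_from_json(obj: dict) -> SubmoduleSpec:
    for key in ("id", "root", "nodes", "edges"):
        if key not in obj:
            raise ValueError(f"module object missing key {key!r}")
    return SubmoduleSpec(
        id=obj["id"],
        root=obj["root"],
        member_nodes=frozenset(obj["nodes"]),
        member_edges=frozenset(EdgeSpec(p, c) for p, c in obj["edges"]),
    )


def structure_to_json(s: ModularBNStructure) -> dict:
    """JSON-serializable dict with top-level keys nodes, edges, modules."""
    return {
        "max_parents": s.max_parents,
        "nodes": [
            {"id": n.id, "role": n.role, "states": list(n.states), "module": n.module_id}
            for n in s.nodes.values()
        ],
        "edges": [[e.parent, e.child] for e in s.edges],
        "modules": {
            "main": _module_to_json(s.main_module) if s.main_module else None,
            "submodules": [_module_to_json(m) for m in s.submodules],
        },
    }


def structure_from_json(obj: dict) -> ModularBNStructure:
    for key in ("nodes", "edges", "modules"):
        if key not in obj:
            raise ValueError(f"structure file missing key {key!r}")
    nodes: dict[str, NodeSpec] = {}
    for n in obj["nodes"]:
        for key in ("id", "role", "states", "module"):
            if key not in n:
                raise ValueError(f"node object missing key {key!r}")
        nodes[n["id"]] = NodeSpec(n["id"], n["role"], tuple(n["states"]), n["module"])
    edges = [EdgeSpec(p, c) for p, c in obj["edges"]]
    mods = obj["modules"]
    main = _module_from_json(mods["main"]) if mods.get("main") else None
    subs = [_module_from_json(m) for m in mods.get("submodules", [])]
    return ModularBNStructure(
        nodes=nodes,
        edges=edges,
        main_module=main,
        submodules=subs,
        max_parents=int(obj.get("max_parents", 2)),
    )


def save_structure(s: ModularBNStructure, path) -> None:
    """Write the structure as JSON; round-trips through :func:`load_structure`."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(structure_to_json(s), fh, indent=1)


def load_structure(path) -> ModularBNStructure:
    """Read a structure JSON file; malformed input raises ``ValueError``."""
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"not valid JSON: {exc}") from exc
    return structure_from_json(obj)
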