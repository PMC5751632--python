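"""Synthetic multi-channel sensor streams with full context annotations.

No public recording of the study conditions exists, so this module emulates
them: nine sensor channels (wrist accelerometer at 20 Hz; wrist illuminance,
temperature and humidity at 1 Hz; phone accelerometer at 20 Hz), the
10-activity vocabulary, an eating share defaulting to 47.27% of collection
time, per-subject heterogeneity (handedness, age band, per-channel gain and
offset) and per-sample sensor dropout.

Each activity has an emission profile — per-channel Gaussian noise around a
mean plus an optional sinusoid (hand-to-mouth cycling while eating, stride
while walking, vehicle vibration) — and a context-truth table: which of the
15 low-level context properties hold during the activity.  Truth states of
the higher context nodes are derived from the properties by majority, so CPT
learning receives a fully annotated state vector per window.

Left-handed subjects wear the device on their non-dominant wrist: the x-axis
of the wrist accelerometer is strongly attenuated and steadier while the
other axes get noisier, which is the heterogeneity case the recognizer must
absorb through its remaining contexts.

The module also provides ancestral (forward) sampling from any fitted
network, used for CPT parameter-recovery checks, and a random tree-model
generator for inference-oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cpt import CPTBank, CPTTable
from .structure import (
    BINARY_STATES,
    EdgeSpec,
    ModularBNStructure,
    NodeSpec,
    SubmoduleSpec,
    _SUBMODULE_HIERARCHY,
    SHARED_NODES,
    QUERY_NODE,
)
from .windows import CHANNELS, CHANNEL_RATES, EATING_LABELS


@dataclass
class ActivityProfile:
    """Emission and context-truth specification for one activity."""

    index: int
    name: str
    emissions: dict[str, dict[str, float]]  # channel -> {mean, sd, amp, period}
    true_contexts: frozenset[str]


@dataclass
class SubjectProfile:
    """Per-subject sensor modulation."""

    subject_id: int
    handedness: str  # "right" or "left"
    age_band: str  # "child", "adult" or "senior"
    gain: dict[str, float] = field(default_factory=dict)
    offset: dict[str, float] = field(default_factory=dict)
    dropout: dict[str, float] = field(default_factory=dict)


def load_default_profiles() -> dict[int, ActivityProfile]:
    """The 10 activity profiles shipped with the package."""
    text = resources.files("eatbn").joinpath("data/default_profiles.yaml").read_text()
    cfg = yaml.safe_load(text)
    base = cfg["base_emissions"]
    profiles: dict[int, ActivityProfile] = {}
    for idx, spec in cfg["activities"].items():
        emissions = {}
        for chan in CHANNELS:
            em = dict(base[chan])
            em.update(spec.get("emissions", {}).get(chan, {}))
            em.setdefault("amp", 0.0)
            em.setdefault("period", 1.0)
            emissions[chan] = em
        profiles[int(idx)] = ActivityProfile(
            index=int(idx),
            name=spec["name"],
            emissions=emissions,
            true_contexts=frozenset(spec.get("true_contexts", [])),
        )
    return profiles


# -- context truth -------------------------------------------------------------

_PROPERTY_CHILDREN = {
    parent: children
    for hierarchy in _SUBMODULE_HIERARCHY.values()
    for parent, children in hierarchy.items()
}


def context_truth(activity_index: int, true_contexts: frozenset[str]) -> dict[str, str]:
    """Truth states of the query and all 23 inference nodes for one activity.

    Low-level context properties come straight from the activity profile;
    each higher node is true iff a majority of its child contexts is true;
    the query is true iff the activity is an eating activity.
    """
    state: dict[str, bool] = {}
    for prop in (
        "position_of_hand", "dinnerware", "movement_of_hand",
        "posture_body", "move_stop_body", "movement_of_body",
        "body_temperature", "posture_operation", "humidity_of_hand",
        "existence_of_food",
        "eating_place", "indoor_outdoor", "move_stop_spatial",
        "illuminance_of_space", "eating_time",
    ):
        state[prop] = prop in true_contexts

    def derive(node: str) -> bool:
        children = _PROPERTY_CHILDREN.get(node)
        if children is None:
            return state[node]
        votes = [derive(c) for c in children]
        result = sum(votes) * 2 >= len(votes)
        state[node] = result
        return result

    for shared in SHARED_NODES:
        derive(shared)
    state[QUERY_NODE] = activity_index in EATING_LABELS
    return {n: ("true" if v else "false") for n, v in state.items()}


# -- subject generation --------------------------------------------------------


def make_subject_profiles(
    n_subjects: int,
    rng: np.random.Generator,
    dropout_rate: float = 0.01,
) -> list[SubjectProfile]:
    """Draw per-subject modulations: handedness, age band, gain, offset, dropout."""
    subjects = []
    for sid in range(n_subjects):
        handedness = "left" if rng.random() < 0.12 else "right"
        age_band = rng.choice(["child", "adult", "senior"], p=[0.08, 0.72, 0.20])
        gain = {c: float(np.exp(rng.normal(0.0, 0.08))) for c in CHANNELS}
        offset = {c: 0.0 for c in CHANNELS}
        offset["h_temp"] = float(rng.normal(0.0, 0.4))
        offset["h_hum"] = float(rng.normal(0.0, 0.3))
        if age_band == "child":
            gain["h_acc_y"] *= 0.6  # food positioned higher: weaker y motion
        subjects.append(
            SubjectProfile(
                subject_id=sid,
                handedness=str(handedness),
                age_band=str(age_band),
                gain=gain,
                offset=offset,
                dropout={c: dropout_rate for c in CHANNELS},
            )
        )
    return subjects


def _emit_channel(
    channel: str,
    em: dict[str, float],
    subject: SubjectProfile,
    times: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    mean, sd = em["mean"], em["sd"]
    amp, period = em["amp"], em["period"]
    if subject.handedness == "left" and channel.startswith("h_acc"):
        if channel == "h_acc_x":
            mean, amp, sd = 0.3 * mean, 0.3 * amp, 0.5 * sd  # low and steady
        else:
            sd, amp = 1.5 * sd, 0.7 * amp  # irregular non-dominant-hand use
    phase = rng.uniform(0, 2 * np.pi)
    signal = mean + amp * np.sin(2 * np.pi * times / period + phase)
    signal = signal + rng.normal(0.0, sd, size=len(times))
    return subject.gain[channel] * signal + subject.offset[channel]


def generate_dataset(
    n_subjects: int = 6,
    minutes_per_subject: float = 16.0,
    eating_fraction: float = 0.4727,
    seed: int = 0,
    window_s: float = 1.0,
    bout_s: float = 60.0,
    dropout_rate: float = 0.01,
    profiles: dict[int, ActivityProfile] | None = None,
    subjects: list[SubjectProfile] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a labeled sensor log and per-window context annotations.

    Activities are drawn per bout (default one minute) so that the expected
    eating share of collection time equals ``eating_fraction`` (default the
    47.27% study share); eating bouts split 11:6 between dinnerware and
    other eating, mirroring the study's subject counts.  All randomness flows
    from ``seed``; per-subject generators are spawned deterministically.

    Returns
    -------
    records
        Long-format log with columns ``timestamp, channel, value, label``.
    annotations
        One row per window and non-evidence node:
        ``window_start, node_id, state`` — the generative context truth
        consumed by CPT learning.
    """
    if minutes_per_subject <= 0 or bout_s <= 0 or window_s <= 0:
        raise ValueError("durations must be positive")
    if not 0.0 < eating_fraction < 1.0:
        raise ValueError("eating_fraction must lie in (0, 1)")

    if profiles is None:
        profiles = load_default_profiles()
    root_seq = np.random.SeedSequence(seed)
    subject_seqs = root_seq.spawn(n_subjects + 1)
    master_rng = np.random.default_rng(subject_seqs[-1])
    if subjects is None:
        subjects = make_subject_profiles(n_subjects, master_rng, dropout_rate)

    non_eating = sorted(set(profiles) - EATING_LABELS)
    bouts_per_subject = int(round(minutes_per_subject * 60.0 / bout_s))

    rec_frames = []
    ann_rows = []
    truth_cache = {
        idx: context_truth(idx, p.true_contexts) for idx, p in profiles.items()
    }

    for sid, subject in enumerate(subjects):
        rng = np.random.default_rng(subject_seqs[sid])
        t0 = sid * minutes_per_subject * 60.0
        for b in range(bouts_per_subject):
            if rng.random() < eating_fraction:
                activity = int(rng.choice([4, 5], p=[11 / 17, 6 / 17]))
            else:
                activity = int(rng.choice(non_eating))
            profile = profiles[activity]
            bout_start = t0 + b * bout_s
            for channel in CHANNELS:
                rate = CHANNEL_RATES[channel]
                n = int(round(bout_s * rate))
                times = bout_start + np.arange(n) / rate
                values = _emit_channel(
                    channel, profile.emissions[channel], subject, times, rng
                )
                keep = rng.random(n) >= subject.dropout[channel]
                if keep.sum() == 0:
                    continue
                rec_frames.append(
                    pd.DataFrame(
                        {
                            "timestamp": times[keep],
                            "channel": channel,
                            "value": values[keep],
                            "label": activity,
                        }
                    )
                )
            truth = truth_cache[activity]
            n_windows = int(round(bout_s / window_s))
            for w in range(n_windows):
                ws = bout_start + w * window_s
                for node_id, state in truth.items():
                    ann_rows.append((ws, node_id, state))

    records = (
        pd.concat(rec_frames, ignore_index=True)
        .sort_values(["timestamp", "channel"], kind="stable")
        .reset_index(drop=True)
    )
    annotations = pd.DataFrame(ann_rows, columns=["window_start", "node_id", "state"])
    return records, annotations


# -- sampling from a fitted network -------------------------------------------


def generate_from_bn(
    structure: ModularBNStructure,
    cpts: CPTBank,
    n_samples: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Ancestral sampling: one joint node-state sample per row, root to leaves."""
    rng = np.random.default_rng(seed)
    order = structure.topological_order()
    parent = {n: structure.parent_of(n) for n in order}
    columns: dict[str, np.ndarray] = {}
    for node in order:
        table = cpts.tables[node]
        states = np.array(table.states)
        if parent[node] is None:
            probs = table.row(())
            idx = rng.choice(len(states), size=n_samples, p=probs)
        else:
            pstates = columns[parent[node]]
            idx = np.empty(n_samples, dtype=np.int64)
            for ps in np.unique(pstates):
                mask = pstates == ps
                probs = table.row((str(ps),))
                idx[mask] = rng.choice(len(states), size=int(mask.sum()), p=probs)
        columns[node] = states[idx]
    return pd.DataFrame(columns, columns=order)


def random_tree_model(
    n_nodes: int, seed: int = 0, concentration: float = 1.0
) -> tuple[ModularBNStructure, CPTBank]:
    """Random rooted binary tree with Dirichlet-drawn CPT rows, for oracle tests."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    ids = [f"n{i}" for i in range(n_nodes)]
    nodes = {
        ids[0]: NodeSpec(ids[0], "query", BINARY_STATES, "main"),
    }
    edges = []
    for i in range(1, n_nodes):
        parent = ids[int(rng.integers(0, i))]
        nodes[ids[i]] = NodeSpec(ids[i], "inference", BINARY_STATES, "main")
        edges.append(EdgeSpec(parent, ids[i]))
    # re-label leaves as evidence so EvidenceAssignment contracts apply
    non_leaves = {e.parent for e in edges}
    for nid in ids[1:]:
        if nid not in non_leaves:
            nodes[nid] = NodeSpec(nid, "evidence", BINARY_STATES, "main")
    main = SubmoduleSpec(
        "main", ids[0], frozenset(ids), frozenset(edges)
    )
    structure = ModularBNStructure(
        nodes=nodes, edges=edges, main_module=main, submodules=[], max_parents=2
    )
    tables = {}
    for nid in ids:
        parent = structure.parent_of(nid)
        parents = () if parent is None else (parent,)
        combos = [()] if parent is None else [("true",), ("false",)]
        probs = {
            c: rng.dirichlet([concentration, concentration]) for c in combos
        }
        tables[nid] = CPTTable(nid, parents, BINARY_STATES, probs)
    return structure, CPTBank(tables=tables, alpha=0.0)
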