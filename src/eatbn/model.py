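"""The bundled recognizer: structure + stump bank + CPT bank + threshold.

Training wires the modules together: windowed features train one decision
stump per evidence node against its owning context's truth state; every
window then contributes one fully assigned state vector (annotated truths for
the query and context nodes, stump outputs for the evidence nodes) to the
counting-based CPT learner.  Recognition runs each window's features through
the stump bank into an evidence assignment and queries the tree exactly;
missing features become absent evidence and are marginalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .cpt import CPTBank, CountBank, accumulate, finalize
from .evidence import EvidenceStump, fit_stump, predict_evidence
from .inference import PosteriorReport, infer_posterior
from .structure import (
    ModularBNStructure,
    evidence_feature,
    structure_from_json,
    structure_to_json,
    validate_structure,
)
from .windows import WindowFeatureVector


@dataclass
class EatingRecognizer:
    """A trained eating-activity recognizer."""

    structure: ModularBNStructure
    stumps: dict[str, EvidenceStump]
    cpts: CPTBank
    threshold: float = 0.6

    def evidence_for(self, features: dict[str, float]) -> dict[str, str]:
        """Evidence assignment for one window; unavailable evidence omitted."""
        ev: dict[str, str] = {}
        for node_id, stump in self.stumps.items():
            state = predict_evidence(stump, features)
            if state is not None:
                ev[node_id] = "true" if state else "false"
        return ev

    def posterior(self, features: dict[str, float]) -> PosteriorReport:
        return infer_posterior(
            self.structure, self.cpts, self.evidence_for(features), self.threshold
        )

    def recognize(self, windows: list[WindowFeatureVector]) -> pd.DataFrame:
        """Per-window posterior, shared-node posteriors and decision."""
        rows = []
        for w in windows:
            rep = self.posterior(w.features)
            row = {
                "window_start": w.window_start,
                "posterior": rep.query_posterior,
                "decision": rep.decision,
            }
            for shared, p in rep.shared_node_posteriors.items():
                row[f"p_{shared}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    # -- serialization --------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "structure": structure_to_json(self.structure),
            "stumps": {nid: s.to_json() for nid, s in self.stumps.items()},
            "cpts": self.cpts.to_json(),
            "threshold": self.threshold,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def from_json(cls, obj: dict) -> "EatingRecognizer":
        for key in ("structure", "stumps", "cpts", "threshold"):
            if key not in obj:
                raise ValueError(f"model file missing key {key!r}")
        return cls(
            structure=structure_from_json(obj["structure"]),
            stumps={
                nid: EvidenceStump.from_json(s) for nid, s in obj["stumps"].items()
            },
            cpts=CPTBank.from_json(obj["cpts"]),
            threshold=float(obj["threshold"]),
        )

    @classmethod
    def load(cls, path) -> "EatingRecognizer":
        with open(path, encoding="utf-8") as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"not valid JSON: {exc}") from exc
        return cls.from_json(obj)


def _annotation_lookup(annotations: pd.DataFrame) -> dict[float, dict[str, str]]:
    # CSV round-trips may coerce "true"/"false" to booleans; normalize back
    states = [str(s).lower() for s in annotations["state"]]
    lookup: dict[float, dict[str, str]] = {}
    for ws, nid, state in zip(annotations["window_start"], annotations["node_id"], states):
        lookup.setdefault(float(ws), {})[nid] = state
    return lookup


def train_model(
    windows: list[WindowFeatureVector],
    annotations: pd.DataFrame,
    structure: ModularBNStructure,
    alpha: float = 1.0,
    threshold: float = 0.6,
) -> EatingRecognizer:
    """Train stumps and CPTs from annotated windows.

    ``annotations`` carries the generative truth state of the query and every
    context node per window (columns ``window_start, node_id, state``).  Each
    evidence node's stump is trained to predict its parent context's truth
    from the node's wired feature; CPT counting then uses annotated truths
    for non-evidence nodes and stump outputs for evidence nodes, so evidence
    CPT rows capture the stumps' actual error behavior.
    """
    problems = validate_structure(structure)
    if problems:
        raise ValueError(f"invalid structure: {problems[0]}")

    lookup = _annotation_lookup(annotations)
    usable = [w for w in windows if w.window_start in lookup]
    if not usable:
        raise ValueError("no windows with matching annotations")

    stumps: dict[str, EvidenceStump] = {}
    for node_id in structure.evidence_nodes:
        feature = evidence_feature(node_id)
        parent = structure.parent_of(node_id)
        values, targets = [], []
        for w in usable:
            if feature in w.features:
                values.append(w.features[feature])
                targets.append(lookup[w.window_start][parent] == "true")
        stumps[node_id] = fit_stump(node_id, feature, values, targets)

    bank = CountBank.for_structure(structure)
    for w in usable:
        assignment = dict(lookup[w.window_start])
        for node_id, stump in stumps.items():
            state = predict_evidence(stump, w.features)
            # training windows pass the channel-completeness rule, so the
            # feature is present; a degenerate stump still yields a state
            if state is None:
                raise ValueError(
                    f"feature {stump.feature!r} missing from training window "
                    f"at {w.window_start}"
                )
            assignment[node_id] = "true" if state else "false"
        accumulate(bank, assignment)
    cpts = finalize(bank, alpha)

    return EatingRecognizer(
        structure=structure, stumps=stumps, cpts=cpts, threshold=threshold
    )
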