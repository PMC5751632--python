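"""Per-evidence-node decision stumps.

Each of the 64 evidence nodes owns one depth-1 decision tree (a stump): a
single threshold on the single window feature the structure wires to it.
Training picks the threshold/polarity pair maximizing training accuracy by
exhaustive search over midpoints between consecutive distinct feature values
(plus the two constant predictors).  Prediction is hard thresholding; a value
exactly at the threshold maps to state ``true`` for either polarity, and a
missing feature yields ``None`` — the "evidence unavailable" marker that
inference marginalizes out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: polarity "ge": true iff value >= threshold; "le": true iff value <= threshold.
POLARITIES = ("ge", "le")


@dataclass
class EvidenceStump:
    node_id: str
    feature: str
    threshold: float
    polarity: str  # "ge" or "le"
    train_accuracy: float
    degenerate: bool = False  # single-class training targets; constant output

    def predict_value(self, value: float) -> bool:
        if self.polarity == "ge":
            return bool(value >= self.threshold)
        return bool(value <= self.threshold)

    def to_json(self) -> dict:
        return {
            "node_id": self.node_id,
            "feature": self.feature,
            "threshold": self.threshold,
            "polarity": self.polarity,
            "train_accuracy": self.train_accuracy,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "EvidenceStump":
        return cls(
            node_id=obj["node_id"],
            feature=obj["feature"],
            threshold=float(obj["threshold"]),
            polarity=obj["polarity"],
            train_accuracy=float(obj["train_accuracy"]),
            degenerate=bool(obj.get("degenerate", False)),
        )


def _constant_stump(node_id, feature, predict_true: bool, accuracy: float) -> EvidenceStump:
    # threshold at -inf/ge predicts true always; +inf/le ... use -inf with
    # polarity chosen so the constant prediction falls out of the tie rule
    threshold = -np.inf if predict_true else np.inf
    return EvidenceStump(
        node_id=node_id,
        feature=feature,
        threshold=float(threshold),
        polarity="ge",
        train_accuracy=accuracy,
        degenerate=True,
    )


def fit_stump(node_id: str, feature: str, values, targets) -> EvidenceStump:
    """Fit one evidence stump by exhaustive threshold search.

    Candidate thresholds are the midpoints between consecutive sorted distinct
    values, plus one sentinel below the minimum and one above the maximum (the
    constant predictors), each tried at both polarities.  The candidate with
    the highest training accuracy wins; ties go to the smallest threshold, and
    at equal threshold to polarity ``ge``.

    Single-class targets (or fewer than 2 samples) produce a degenerate stump
    that predicts the majority class constantly and is flagged as such.
    """
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets).astype(bool)
    if len(values) != len(targets):
        raise ValueError("values and targets differ in length")

    n = len(values)
    n_true = int(targets.sum())
    if n < 2 or n_true == 0 or n_true == n:
        majority = n_true * 2 >= n
        acc = max(n_true, n - n_true) / n if n else 0.0
        return _constant_stump(node_id, feature, majority, acc)

    distinct = np.unique(values)
    candidates = [distinct[0] - 1.0]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(distinct[-1] + 1.0)

    best = None  # (accuracy, threshold, polarity_index)
    for thr in candidates:
        ge_pred = values >= thr
        acc_ge = float((ge_pred == targets).mean())
        acc_le = float(((values <= thr) == targets).mean())
        for acc, pol in ((acc_ge, "ge"), (acc_le, "le")):
            if best is None or acc > best[0] + 1e-12:
                best = (acc, float(thr), pol)

    acc, thr, pol = best
    return EvidenceStump(
        node_id=node_id,
        feature=feature,
        threshold=thr,
        polarity=pol,
        train_accuracy=acc,
        degenerate=False,
    )


def predict_evidence(stump: EvidenceStump, features: dict[str, float]) -> bool | None:
    """Evidence state for one window, or ``None`` when the feature is missing."""
    value = features.get(stump.feature)
    if value is None or not np.isfinite(value):
        return None
    return stump.predict_value(float(value))
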