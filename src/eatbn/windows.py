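"""Window segmentation, per-window features and attribute-class scoring.

Raw sensor logs are long-format records ``(timestamp, channel, value, label)``
covering nine channels: the wrist accelerometer ``h_acc_{x,y,z}`` sampled at
20 Hz, the wrist environmental channels ``h_lux``/``h_temp``/``h_hum`` at
1 Hz, and the phone accelerometer ``acc_{x,y,z}``.  Streams are cut into
non-overlapping, left-closed right-open windows; a window is emitted only when
every required channel contributed at least one sample.

Per window, accelerometer axes yield mean, standard deviation and range;
environmental channels yield the mean — 21 features in total.  Attributes can
be scored against the eating/non-eating class with the four classical filter
metrics: Pearson correlation, information gain, gain ratio and symmetric
uncertainty (entropies in bits, attributes discretized by equal frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The nine sensor channels, wrist ("h_") first.
CHANNELS = (
    "h_acc_x", "h_acc_y", "h_acc_z",
    "h_lux", "h_temp", "h_hum",
    "acc_x", "acc_y", "acc_z",
)

ACC_CHANNELS = ("h_acc_x", "h_acc_y", "h_acc_z", "acc_x", "acc_y", "acc_z")
ENV_CHANNELS = ("h_lux", "h_temp", "h_hum")

#: Nominal sampling rate per channel (Hz).
CHANNEL_RATES = {c: (20.0 if c in ACC_CHANNELS else 1.0) for c in CHANNELS}

#: Activity vocabulary, indexed 1-10.
ACTIVITIES = {
    1: "washing",
    2: "walking",
    3: "housework",
    4: "eating_dinnerware",
    5: "eating_etc",
    6: "conversation",
    7: "driving",
    8: "sedentary_work",
    9: "subway",
    10: "playing_piano",
}

#: Activity indices counted as eating.
EATING_LABELS = frozenset({4, 5})

#: All 21 window feature names.
FEATURE_NAMES = tuple(
    f"{c}_{stat}" for c in ACC_CHANNELS for stat in ("mean", "sd", "range")
) + tuple(f"{c}_mean" for c in ENV_CHANNELS)


@dataclass
class WindowFeatureVector:
    """Features, majority activity label and eating flag for one window."""

    window_start: float
    features: dict[str, float]
    label: int
    is_eating: bool


@dataclass
class AttributeScore:
    """The four filter scores of an attribute against the class."""

    pearson: float
    info_gain: float
    gain_ratio: float
    sym_uncert: float


def compute_features(samples: dict[str, np.ndarray]) -> dict[str, float]:
    """Per-window feature map from raw samples keyed by channel.

    Accelerometer axes contribute mean, standard deviation (population) and
    range; environmental channels contribute the mean.  Channels absent from
    ``samples`` simply contribute no features (the evidence layer treats the
    corresponding evidence as unavailable).
    """
    feats: dict[str, float] = {}
    for c in ACC_CHANNELS:
        v = samples.get(c)
        if v is None or len(v) == 0:
            continue
        v = np.asarray(v, dtype=float)
        feats[f"{c}_mean"] = float(v.mean())
        feats[f"{c}_sd"] = float(v.std())
        feats[f"{c}_range"] = float(v.max() - v.min())
    for c in ENV_CHANNELS:
        v = samples.get(c)
        if v is None or len(v) == 0:
            continue
        feats[f"{c}_mean"] = float(np.asarray(v, dtype=float).mean())
    return feats


def _majority_label(labels: np.ndarray) -> int:
    # majority; ties broken toward the smaller activity index
    idx, counts = np.unique(labels, return_counts=True)
    return int(idx[np.argmax(counts)])  # np.unique sorts, argmax takes first max


def segment_windows(
    records: pd.DataFrame,
    window_s: float = 1.0,
    required_channels: tuple[str, ...] | None = None,
) -> list[WindowFeatureVector]:
    """Cut a long-format sensor log into fixed windows with features.

    Parameters
    ----------
    records
        Columns ``timestamp, channel, value`` and optionally ``label``.
        Timestamps must be non-decreasing within each channel.
    window_s
        Window length in seconds; windows are ``[t, t + window_s)``.
    required_channels
        Channels that must each contribute at least one sample for a window
        to be emitted.  Defaults to all nine channels (training contract);
        recognition over a stream with a dead sensor passes the channels that
        are actually present.

    Returns
    -------
    list of :class:`WindowFeatureVector`, ordered by window start.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if required_channels is None:
        required_channels = CHANNELS
    if len(records) == 0:
        return []

    bad = set(records["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown channels in stream: {sorted(bad)}")

    for chan, grp in records.groupby("channel", sort=False):
        ts = grp["timestamp"].to_numpy()
        drops = np.nonzero(np.diff(ts) < 0)[0]
        if len(drops):
            raise ValueError(
                f"timestamps not sorted in channel {chan!r} at sample index {int(drops[0]) + 1}"
            )

    df = records.copy()
    df["_win"] = np.floor(df["timestamp"].to_numpy() / window_s).astype(np.int64)
    has_label = "label" in df.columns

    out: list[WindowFeatureVector] = []
    required = set(required_channels)
    for win, grp in df.groupby("_win", sort=True):
        present = set(grp["channel"].unique())
        if not required <= present:
            continue
        samples = {
            c: sub["value"].to_numpy() for c, sub in grp.groupby("channel", sort=False)
        }
        feats = compute_features(samples)
        if has_label:
            label = _majority_label(grp["label"].to_numpy().astype(int))
        else:
            label = 0
        out.append(
            WindowFeatureVector(
                window_start=float(win) * window_s,
                features=feats,
                label=label,
                is_eating=label in EATING_LABELS,
            )
        )
    return out


def windows_to_frame(windows: list[WindowFeatureVector]) -> pd.DataFrame:
    """Tabular view: one row per window, one column per feature."""
    rows = []
    for w in windows:
        row = {"window_start": w.window_start, "label": w.label, "is_eating": w.is_eating}
        row.update(w.features)
        rows.append(row)
    return pd.DataFrame(rows)


# -- attribute scoring ---------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def equal_frequency_bins(a: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins.

    Deterministic: rank ``r`` of ``n`` (stable sort) maps to bin
    ``r * n_bins // n``, except that equal values always share the bin of
    their first-ranked occurrence — a constant attribute therefore occupies
    a single bin and carries no information.
    """
    a = np.asarray(a, dtype=float)
    n = len(a)
    order = np.argsort(a, kind="stable")
    s = a[order]
    tentative = np.arange(n) * n_bins // n
    starts = np.r_[True, s[1:] != s[:-1]]  # first position of each tied run
    group_bin = tentative[starts]
    bins_sorted = group_bin[np.cumsum(starts) - 1]
    bins = np.empty(n, dtype=np.int64)
    bins[order] = bins_sorted
    return bins


def score_attribute(a, c, n_bins: int = 10) -> AttributeScore:
    """Score one attribute against the binary eating class.

    ``pearson`` correlates the raw attribute with the class coded {0, 1}
    (eating = 1).  The entropic scores are computed on the contingency table
    of the equal-frequency-discretized attribute against the class, with
    logarithms base 2:

    * ``info_gain``  = H(C) - H(C|A)
    * ``gain_ratio`` = (H(C) - H(C|A)) / H(A), 0 when H(A) = 0
    * ``sym_uncert`` = 2 (H(C) - H(C|A)) / (H(C) + H(A)), 0 when both are 0
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c).astype(bool)
    if len(a) != len(c):
        raise ValueError(f"length mismatch: {len(a)} attribute values, {len(c)} labels")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")

    c01 = c.astype(float)
    if a.std() == 0 or c01.std() == 0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(a, c01)[0, 1])

    bins = equal_frequency_bins(a, n_bins)
    # joint contingency table: rows = attribute bins, cols = class
    table = np.zeros((n_bins, 2))
    np.add.at(table, (bins, c.astype(int)), 1.0)

    h_c = _entropy(table.sum(axis=0))
    h_a = _entropy(table.sum(axis=1))
    n = table.sum()
    h_c_given_a = 0.0
    for row in table:
        if row.sum() > 0:
            h_c_given_a += (row.sum() / n) * _entropy(row)
    info_gain = max(h_c - h_c_given_a, 0.0)

    gain_ratio = info_gain / h_a if h_a > 0 else 0.0
    denom = h_c + h_a
    sym_uncert = 2.0 * info_gain / denom if denom > 0 else 0.0
    return AttributeScore(pearson, info_gain, gain_ratio, sym_uncert)
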