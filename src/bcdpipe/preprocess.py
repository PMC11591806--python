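"""Min-max normalization and information-gain feature selection.

Both stages are fold-safe: statistics are fit on a training table only and
then applied to held-out data, so a cross-validation test fold never leaks
into the preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import IGPolicy
from .data_io import LabeledTable

logger = logging.getLogger(__name__)


@dataclass
class MinMaxModel:
    """Per-feature minimum and maximum learned from a training table."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.mins > self.maxs):
            raise ValueError("per-feature min must not exceed max")

    @property
    def b(self) -> int:
        return len(self.mins)


@dataclass
class FeatureRanking:
    """Per-feature information gain (bits) plus the selected index set.

    ``order`` ranks features by gain descending (ties broken by original
    column order); ``selected`` holds the chosen indices in original column
    order and is never empty.
    """

    gains: np.ndarray
    order: list[int]
    selected: list[int]
    policy: str

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        names = feature_names or [f"f{i}" for i in range(len(self.gains))]
        return {
            "policy": self.policy,
            "gain_bits": {names[i]: float(g) for i, g in enumerate(self.gains)},
            "selected": [names[i] for i in self.selected],
        }


def fit_minmax(train: LabeledTable) -> MinMaxModel:
    """Column-wise min/max of the training table only."""
    return MinMaxModel(train.values.min(axis=0), train.values.max(axis=0))


def apply_minmax(model: MinMaxModel, table: LabeledTable) -> LabeledTable:
    """Map each value to (x - min) / (max - min), clipped to [0, 1].

    Constant training features (max == min) map to 0; out-of-range test
    values are clipped so downstream stages always see [0, 1].
    """
    if table.b != model.b:
        raise ValueError(f"feature count mismatch: table has {table.b}, model has {model.b}")
    span = model.maxs - model.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.values - model.mins) / safe
    scaled[:, span == 0] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return LabeledTable(scaled, table.labels, list(table.feature_names),
                        list(table.instance_ids))


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy of a categorical vector, in bits (0 log 0 := 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels.astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretize(feature: np.ndarray, bins: int) -> np.ndarray:
    """Feature values as discrete symbols for the conditional entropy.

    Integer-valued features on at most a ``bins``-point scale are used
    as-is; anything else gets equal-width bins over the observed range.
    """
    feature = np.asarray(feature, dtype=float)
    values = np.unique(feature)
    if len(values) <= bins and np.allclose(feature, np.rint(feature)):
        return feature.astype(int)
    lo, hi = feature.min(), feature.max()
    if lo == hi:
        return np.zeros(len(feature), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    # right-inclusive top edge so the maximum lands in the last bin
    return np.clip(np.digitize(feature, edges[1:-1]), 0, bins - 1)


def information_gain(feature: np.ndarray, labels: np.ndarray, bins: int = 10) -> float:
    """IG = H(labels) - sum_v (n_v / n) H(labels | feature == v), in bits."""
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if len(feature) != len(labels):
        raise ValueError("feature and labels must have equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    symbols = _discretize(feature, bins)
    n = len(labels)
    h = entropy(labels)
    cond = 0.0
    for v in np.unique(symbols):
        sel = symbols == v
        cond += sel.sum() / n * entropy(labels[sel])
    return max(0.0, h - cond)


def select_features(train: LabeledTable, policy: IGPolicy, bins: int | None = None) -> FeatureRanking:
    """Rank features by information gain and apply the selection policy.

    above_mean keeps features with gain strictly greater than the mean
    gain, falling back to all features when none qualifies (all-equal
    gains); top_k keeps the k best.  At least one feature is always
    selected.
    """
    if train.n < 2 or len(set(train.labels)) < 2:
        raise ValueError("feature selection needs >= 2 instances and >= 2 classes")
    bins = bins if bins is not None else policy.bins
    gains = np.array([information_gain(train.values[:, j], train.labels, bins)
                      for j in range(train.b)])
    order = sorted(range(train.b), key=lambda j: (-gains[j], j))
    if policy.mode == "top_k":
        k = policy.top_k
        if k is None or k > train.b:
            raise ValueError(f"top_k={k} exceeds feature count {train.b}")
        selected = sorted(order[:k])
        tag = f"top_k={k}"
    else:
        mean_gain = gains.mean()
        selected = [j for j in range(train.b) if gains[j] > mean_gain]
        if not selected:
            selected = list(range(train.b))
            logger.info("above_mean selected nothing (uniform gains); keeping all features")
        tag = "above_mean"
    return FeatureRanking(gains, order, selected, tag)
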