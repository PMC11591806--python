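"""Synthetic two-class tabular data with planted outliers.

Emulates the kind of data the pipeline targets — bounded numeric cytology
scores for a benign/malignant two-class problem — as two spherical
Gaussian clouds clipped to a value range, with a known minority of
anomalous training instances.  Because the planting truth is returned
alongside the table, every downstream stage (SD filtering, optimizer-based
rejection, ensemble evaluation) is testable without any external download.

Outlier modes
-------------
label_flip
    The instance keeps its feature vector but its label is inverted —
    a mislabeled case.
mean_shift
    Every feature is displaced by a fixed multiple of the within-class SD
    (random sign per feature), placing the instance at least four
    within-class SDs from its class mean in Euclidean distance — a
    measurement-error case.
uniform_noise
    All features are redrawn uniformly over the value range — a corrupted
    record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.model_selection import train_test_split

from .data_io import BENIGN, MALIGNANT, LabeledTable

OutlierMode = Literal["label_flip", "mean_shift", "uniform_noise"]

#: labels for the two generated classes, in generation order
_CLASSES = (BENIGN, MALIGNANT)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    class_separation is the Euclidean distance between the two class mean
    vectors, in raw feature units; within_sd the isotropic within-class SD.
    With the defaults (separation 4, SD 1 on a 1-10 range) the classes
    overlap a little, like well-separated but not trivial cytology data.
    """

    n_per_class: int = 60
    b: int = 5
    class_separation: float = 4.0
    within_sd: float = 1.0
    outlier_rate: float = 0.05
    outlier_mode: OutlierMode = "mean_shift"
    value_range: tuple[float, float] = (1.0, 10.0)
    seed: int = 0
    integer_values: bool = False

    def validate(self) -> "SyntheticSpec":
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if not (0.0 <= self.outlier_rate < 0.5):
            raise ValueError("outlier_rate must lie in [0, 0.5)")
        if self.outlier_mode not in ("label_flip", "mean_shift", "uniform_noise"):
            raise ValueError(f"unknown outlier_mode: {self.outlier_mode!r}")
        if not self.value_range[0] < self.value_range[1]:
            raise ValueError("value_range must be (low, high) with low < high")
        return self


@dataclass
class OutlierTruth:
    """Boolean planting mask: True marks a planted outlier."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def class_means(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """The two class mean vectors, symmetric about the range midpoint."""
    lo, hi = spec.value_range
    center = (lo + hi) / 2.0
    offset = spec.class_separation / (2.0 * math.sqrt(spec.b))
    return {
        BENIGN: np.full(spec.b, center - offset),
        MALIGNANT: np.full(spec.b, center + offset),
    }


def generate(spec: SyntheticSpec) -> tuple[LabeledTable, OutlierTruth]:
    """Draw one dataset per ``spec``; fully reproducible from ``spec.seed``.

    One RNG stream per call, derived from the seed; no global state.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.value_range
    means = class_means(spec)
    n = 2 * spec.n_per_class

    labels = np.array([_CLASSES[0]] * spec.n_per_class + [_CLASSES[1]] * spec.n_per_class,
                      dtype=object)
    values = np.empty((n, spec.b))
    for cls in _CLASSES:
        rows = np.flatnonzero(labels == cls)
        values[rows] = means[cls] + rng.normal(0.0, spec.within_sd, (len(rows), spec.b))

    n_out = round(spec.outlier_rate * n)
    mask = np.zeros(n, dtype=bool)
    if n_out:
        out_idx = rng.choice(n, size=n_out, replace=False)
        mask[out_idx] = True
        if spec.outlier_mode == "label_flip":
            flip = {BENIGN: MALIGNANT, MALIGNANT: BENIGN}
            for i in out_idx:
                labels[i] = flip[labels[i]]
        elif spec.outlier_mode == "mean_shift":
            # per-feature displacement large enough that the Euclidean shift
            # is >= 4 within-class SDs even after clipping to the range
            step = max(2.5, 4.0 / math.sqrt(spec.b)) * spec.within_sd
            signs = rng.choice([-1.0, 1.0], size=(n_out, spec.b))
            values[out_idx] = means_of(labels[out_idx], means) + signs * step
        else:  # uniform_noise
            values[out_idx] = rng.uniform(lo, hi, (n_out, spec.b))

    np.clip(values, lo, hi, out=values)
    if spec.integer_values:
        values = np.clip(np.rint(values), math.ceil(lo), math.floor(hi))

    ids = [f"syn{i:05d}" for i in range(n)]
    table = LabeledTable(values, labels, [f"f{j + 1}" for j in range(spec.b)], ids)
    return table, OutlierTruth(mask)


def means_of(labels: np.ndarray, means: dict[str, np.ndarray]) -> np.ndarray:
    return np.stack([means[lab] for lab in labels])


def holdout_split(
    table: LabeledTable,
    fraction: float,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[LabeledTable, LabeledTable]:
    """Disjoint train/test partition; ``fraction`` is the test share.

    Stratification preserves the class proportions within one instance per
    class and requires at least two instances per class.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    if stratified:
        _, counts = np.unique(table.labels.astype(str), return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split requires >= 2 instances per class")
    idx = np.arange(table.n)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=fraction,
        stratify=table.labels.astype(str) if stratified else None,
        random_state=seed,
    )
    return table.subset_rows(np.sort(train_idx)), table.subset_rows(np.sort(test_idx))
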