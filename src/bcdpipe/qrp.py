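"""Quick Rejection Phase: class-conditional standard-deviation filtering.

Each training instance is scored by how far it sits from the mean of its
own class, feature-wise, and instances whose score exceeds a global
threshold are rejected.  The score of instance x against class profile
(mu, sigma) is the mean over features of |x_j - mu_j| / sigma_j (sigma is
the sample SD with the d-1 denominator, floored at sd_epsilon).  The
threshold trd is the sum over classes of the class's mean instance score,
so it adapts to how dispersed each class actually is.

In the default "standardized" mode both sides of the comparison are
measured in SD units, making the filter invariant to per-feature
rescaling.  "literal" mode drops the sigma-weighting from the threshold
and the scores, using raw mean absolute deviations instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import QRPConfig
from .data_io import LabeledTable

logger = logging.getLogger(__name__)


@dataclass
class ClassProfile:
    """Per-class mean/SD vectors with the class's threshold contribution."""

    label: str
    mean: np.ndarray
    sd: np.ndarray
    count: int
    trd_cl: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd < 0):
            raise ValueError("sd components must be non-negative")
        if self.count < 1:
            raise ValueError("class must have at least one member")


@dataclass
class QRPResult:
    """Scores, threshold and the kept/rejected partition of a training table."""

    scores: np.ndarray
    trd: float
    kept: np.ndarray
    rejected: np.ndarray
    profiles: dict[str, ClassProfile] = field(default_factory=dict)

    def to_dict(self, instance_ids: list[str] | None = None) -> dict:
        rej = [int(i) for i in self.rejected]
        d = {
            "trd": float(self.trd),
            "n_kept": int(len(self.kept)),
            "n_rejected": int(len(self.rejected)),
            "rejected_rows": rej,
            "trd_by_class": {lab: float(p.trd_cl) for lab, p in self.profiles.items()},
        }
        if instance_ids is not None:
            d["rejected_ids"] = [instance_ids[i] for i in rej]
        return d


def fit_class_profiles(train: LabeledTable, sd_epsilon: float = 1e-8) -> dict[str, ClassProfile]:
    """Per-class mean and sample SD (d-1 denominator), SD floored at sd_epsilon.

    Singleton classes get sd = sd_epsilon everywhere (no spread estimate).
    """
    profiles: dict[str, ClassProfile] = {}
    for cls in train.classes:
        rows = train.values[train.labels == cls]
        d = len(rows)
        if d == 0:
            raise ValueError(f"class {cls!r} has no members")
        mu = rows.mean(axis=0)
        if d == 1:
            sd = np.full(train.b, sd_epsilon)
        else:
            sd = np.maximum(rows.std(axis=0, ddof=1), sd_epsilon)
        profiles[cls] = ClassProfile(cls, mu, sd, d)
    return profiles


def deviation_score(instance: np.ndarray, profile: ClassProfile, standardized: bool = True) -> float:
    """Mean over features of the (optionally SD-standardized) absolute deviation."""
    instance = np.asarray(instance, dtype=float)
    if instance.shape != profile.mean.shape:
        raise ValueError("instance length must match the profile's feature count")
    dev = np.abs(instance - profile.mean)
    if standardized:
        dev = dev / profile.sd
    return float(dev.mean())


def rejection_threshold(
    train: LabeledTable,
    profiles: dict[str, ClassProfile],
    mode: str = "standardized",
) -> float:
    """Global threshold: sum over classes of the class's mean instance score.

    Side effect: stores each class's contribution in ``profile.trd_cl``.
    """
    if set(train.classes) - set(profiles):
        raise ValueError("profiles must cover every class in the table")
    standardized = mode == "standardized"
    trd = 0.0
    for cls, profile in profiles.items():
        rows = train.values[train.labels == cls]
        scores = [deviation_score(row, profile, standardized) for row in rows]
        profile.trd_cl = float(np.mean(scores)) if scores else 0.0
        trd += profile.trd_cl
    return trd


def qrp_filter(train: LabeledTable, config: QRPConfig | None = None) -> QRPResult:
    """Score every instance against its own class and reject scores > trd.

    The inequality is strict, so ties with the threshold are kept.  If a
    whole class would be rejected, its lowest-scoring instance is retained
    (with a logged warning) so downstream stages keep all classes.
    """
    config = config or QRPConfig()
    standardized = config.threshold_mode == "standardized"
    for cls in train.classes:
        if int((train.labels == cls).sum()) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 instances for SD filtering")
    profiles = fit_class_profiles(train, config.sd_epsilon)
    trd = rejection_threshold(train, profiles, config.threshold_mode)
    scores = np.array([
        deviation_score(train.values[i], profiles[train.labels[i]], standardized)
        for i in range(train.n)
    ])
    rejected_mask = scores > trd
    for cls in train.classes:
        cls_rows = np.flatnonzero(train.labels == cls)
        if rejected_mask[cls_rows].all():
            keep_back = cls_rows[np.argmin(scores[cls_rows])]
            rejected_mask[keep_back] = False
            logger.warning(
                "all %d instances of class %r scored above trd=%.4f; retaining row %d",
                len(cls_rows), cls, trd, keep_back,
            )
    kept = np.flatnonzero(~rejected_mask)
    rejected = np.flatnonzero(rejected_mask)
    logger.info("QRP: trd=%.4f, kept %d of %d instances", trd, len(kept), train.n)
    return QRPResult(scores, trd, kept, rejected, profiles)
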