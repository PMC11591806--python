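"""Pipeline configuration: one declarative document, validated on load.

Every knob of the pipeline (normalization, information-gain policy, the
quick-rejection filter, the binary Harris hawk optimizer, the ensemble and
the cross-validation protocol) lives here so a run is reproducible from
(config, seed, input) alone.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration document violates an invariant."""


@dataclass
class IGPolicy:
    """Feature-selection cutoff for the information-gain ranking.

    mode "above_mean" keeps every feature whose gain strictly exceeds the
    mean gain (falling back to all features when none does); "top_k" keeps
    the k best-ranked features.
    """

    mode: str = "above_mean"
    top_k: int | None = None
    bins: int = 10

    def validate(self) -> None:
        if self.mode not in ("above_mean", "top_k"):
            raise ConfigError(f"unknown ig policy mode: {self.mode!r}")
        if self.mode == "top_k" and (self.top_k is None or self.top_k < 1):
            raise ConfigError("top_k policy requires top_k >= 1")
        if self.bins < 2:
            raise ConfigError("bins must be >= 2")


@dataclass
class QRPConfig:
    """Quick rejection phase: class-conditional standard-deviation filter.

    threshold_mode "standardized" (default) measures every deviation in
    units of the per-feature class SD on both sides of the comparison;
    "literal" uses raw absolute deviations for the threshold instead.
    """

    threshold_mode: str = "standardized"
    sd_epsilon: float = 1e-8

    def validate(self) -> None:
        if self.threshold_mode not in ("standardized", "literal"):
            raise ConfigError(f"unknown threshold_mode: {self.threshold_mode!r}")
        if self.sd_epsilon <= 0:
            raise ConfigError("sd_epsilon must be positive")


@dataclass
class BHHOConfig:
    """Binary Harris hawk optimizer parameters.

    lb/ub bound the continuous hawk positions; with the default ±4 the
    sigmoid transfer spans roughly (0.018, 0.982) so every bit can still
    flip.  alpha weights the classification-error term of the fitness and
    delta = 1 - alpha the kept-fraction term; levy_beta is the exponent of
    the heavy-tailed dive steps.
    """

    pop_size: int = 10
    it_max: int = 50
    lb: float = -4.0
    ub: float = 4.0
    levy_beta: float = 1.5
    alpha: float = 0.99
    delta: float = 0.01
    fitness_knn_k: int = 5

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        if self.it_max < 1:
            raise ConfigError("it_max must be >= 1")
        if not self.lb < self.ub:
            raise ConfigError("lb must be < ub")
        if self.levy_beta <= 0:
            raise ConfigError("levy_beta must be > 0")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError("alpha must lie in [0, 1]")
        if not math.isclose(self.alpha + self.delta, 1.0, abs_tol=1e-9):
            raise ConfigError("alpha + delta must equal 1")
        if self.fitness_knn_k < 1:
            raise ConfigError("fitness_knn_k must be >= 1")


@dataclass
class ECMConfig:
    """Ensemble classifier settings (naive Bayes + KNN + SVM, majority vote)."""

    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    tie_order: tuple[str, ...] = ("nb", "knn", "svm")

    def validate(self) -> None:
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")
        if self.svm_c <= 0:
            raise ConfigError("svm_c must be positive")
        if not self.tie_order:
            raise ConfigError("tie_order must be non-empty")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (normalize -> IG -> CORT -> ensemble CV)."""

    normalize: bool = True
    ig: IGPolicy = field(default_factory=IGPolicy)
    qrp: QRPConfig = field(default_factory=QRPConfig)
    bhho: BHHOConfig = field(default_factory=BHHOConfig)
    ecm: ECMConfig = field(default_factory=ECMConfig)
    cv_folds: int = 5
    seed: int = 42

    def validate(self) -> "PipelineConfig":
        self.ig.validate()
        self.qrp.validate()
        self.bhho.validate()
        self.ecm.validate()
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        return self

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ecm"]["tie_order"] = list(self.ecm.tie_order)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        sections = {"ig": IGPolicy, "qrp": QRPConfig, "bhho": BHHOConfig, "ecm": ECMConfig}
        for key, value in d.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                if key == "ecm" and "tie_order" in value:
                    value = dict(value, tie_order=tuple(value["tie_order"]))
                try:
                    kwargs[key] = sections[key](**value)
                except TypeError as exc:
                    raise ConfigError(f"bad key in section {key!r}: {exc}") from exc
            elif key in ("normalize", "cv_folds", "seed"):
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config key: {key!r}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        return cls.from_dict(doc)
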