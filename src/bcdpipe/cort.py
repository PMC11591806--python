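"""CORT: combined outlier rejection (quick SD phase + BHHO refinement).

Phase one (:mod:`bcdpipe.qrp`) discards instances far from their class
mean.  Phase two — the accurate rejection phase (ARP) — encodes the
survivors as a bit vector (1 = keep) and lets BHHO minimize

    fitness(R) = alpha * gamma(R) + delta * (|N| - |R|) / |N|

where R is the selected subset of the |N| candidates and delta = 1 -
alpha (default alpha = 0.99).  gamma(R) is the error of a k-nearest-
neighbour evaluator built from R and assessed over *all* candidates:
every candidate — selected or not — is classified by its k nearest
selected instances (itself excluded, Euclidean distance on the current
feature set).  Assessing the whole candidate set means a rejected
instance still has to be explicable by the instances that remain, so
discarding ordinary instances is never free; the second term charges
each rejection a further delta/|N|, favouring the edit that perturbs the
training set least at equal error.  Masks too small for the evaluator
(|R| < k + 1) or missing a class are invalid and score +inf.

The all-ones mask (reject nothing beyond phase one) is injected into the
initial optimizer population, so by elitism the final subset is never
worse, under this objective, than keeping every phase-one survivor.

With the conventional 99:1 weighting the error term dominates: the
optimizer will happily reject many instances to remove a single residual
nearest-neighbour error.  On overlapping classes this smooths the class
boundary aggressively — see the methods note for the consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from . import bhho
from .config import PipelineConfig
from .data_io import LabeledTable
from .qrp import QRPResult, qrp_filter

logger = logging.getLogger(__name__)


@dataclass
class FitnessSpec:
    """Weights and evaluator settings of the instance-selection fitness."""

    alpha: float = 0.99
    delta: float = 0.01
    knn_k: int = 5

    def validate(self) -> "FitnessSpec":
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if abs(self.alpha + self.delta - 1.0) > 1e-9:
            raise ValueError("alpha + delta must equal 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        return self


@dataclass
class CORTResult:
    """Both phases' rejections plus the optimizer trace.

    Counts follow the phase bookkeeping: tm training instances enter, out
    are rejected quickly, rest = tm - out survive to the accurate phase,
    and ins of those are finally kept.
    """

    qrp: QRPResult
    bhho: bhho.BHHOResult
    kept: np.ndarray          # final kept row indices into the input table
    tm: int
    out: int
    rest: int
    ins: int

    def to_dict(self, instance_ids: list[str] | None = None) -> dict:
        d = {
            "tm": self.tm,
            "out": self.out,
            "rest": self.rest,
            "ins": self.ins,
            "qrp": self.qrp.to_dict(instance_ids),
            "arp": self.bhho.to_dict(),
            "kept_rows": [int(i) for i in self.kept],
        }
        if instance_ids is not None:
            d["kept_ids"] = [instance_ids[i] for i in self.kept]
        return d


def combine_fitness(gamma: float, size_fraction: float, spec: FitnessSpec) -> float:
    """alpha * gamma + delta * size_fraction — the scalarized objective.

    ``size_fraction`` is the parsimony share being penalized; the
    instance-rejection fitness passes the rejected fraction
    (|N| - |R|) / |N|.
    """
    return spec.alpha * gamma + spec.delta * size_fraction


def loo_knn_error(values: np.ndarray, y: np.ndarray, k: int,
                  dist: np.ndarray | None = None) -> float:
    """Leave-one-out error of a k-NN majority vote (Euclidean distance).

    Each instance is classified by its k nearest *other* instances; a tied
    vote (possible for even k) falls back to the single nearest neighbour.
    """
    m = len(y)
    if m < k + 1:
        raise ValueError("need at least k + 1 instances for leave-one-out k-NN")
    if dist is None:
        dist = squareform(pdist(values, metric="sqeuclidean"))
        np.fill_diagonal(dist, np.inf)
    nn = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    votes = y[nn].sum(axis=1)
    pred = np.where(votes * 2 > k, 1, 0)
    if k % 2 == 0:
        tied = votes * 2 == k
        if tied.any():
            nearest = np.argmin(dist[tied], axis=1)
            pred[tied] = y[nearest]
    return float(np.mean(pred != y))


def selection_error(dist_to_selected: np.ndarray, y_selected: np.ndarray,
                    y_all: np.ndarray, k: int) -> float:
    """Error over all candidates, each classified by its k nearest selected.

    ``dist_to_selected`` is the (n_candidates, |R|) distance block with
    self-distances already set to +inf, so selected instances are scored
    leave-one-out.  Tied votes (even k) fall back to the nearest selected
    neighbour.
    """
    nn = np.argpartition(dist_to_selected, kth=k - 1, axis=1)[:, :k]
    votes = y_selected[nn].sum(axis=1)
    pred = np.where(votes * 2 > k, 1, 0)
    if k % 2 == 0:
        tied = votes * 2 == k
        if tied.any():
            nearest = np.argmin(dist_to_selected[tied], axis=1)
            pred[tied] = y_selected[nearest]
    return float(np.mean(pred != y_all))


def make_instance_fitness(candidates: LabeledTable, spec: FitnessSpec):
    """Closure over a precomputed distance matrix for fast mask evaluation."""
    spec.validate()
    classes = candidates.classes
    if len(classes) < 2:
        raise ValueError("candidate table must have >= 2 classes")
    y = np.asarray(candidates.labels == classes[-1], dtype=np.int8)
    dist = squareform(pdist(candidates.values, metric="sqeuclidean"))
    np.fill_diagonal(dist, np.inf)
    n_total = candidates.n
    k = spec.knn_k

    def fitness(mask: np.ndarray) -> float:
        idx = np.flatnonzero(np.asarray(mask) > 0)
        r = len(idx)
        if r < k + 1:
            return np.inf
        y_sub = y[idx]
        if y_sub.min() == y_sub.max():  # a class is absent from the selection
            return np.inf
        gamma = selection_error(dist[:, idx], y_sub, y, k)
        return combine_fitness(gamma, (n_total - r) / n_total, spec)

    return fitness


def instance_fitness(mask: np.ndarray, candidates: LabeledTable,
                     spec: FitnessSpec) -> float:
    """Fitness of one instance-selection mask (see module docstring)."""
    return make_instance_fitness(candidates, spec)(mask)


def cort_reject(train: LabeledTable, config: PipelineConfig | None = None,
                seed: int | None = None) -> CORTResult:
    """Run both rejection phases on a training table.

    Returns the final kept row indices (into ``train``) together with full
    provenance: per-phase rejections, the optimizer trace and the seed.
    """
    config = (config or PipelineConfig()).validate()
    seed = config.seed if seed is None else seed

    qrp_result = qrp_filter(train, config.qrp)
    rest_idx = qrp_result.kept
    spec = FitnessSpec(config.bhho.alpha, config.bhho.delta, config.bhho.fitness_knn_k)
    if len(rest_idx) < spec.knn_k + 2:
        raise ValueError(
            f"only {len(rest_idx)} instances survive the quick phase; "
            f"need at least knn_k + 2 = {spec.knn_k + 2} for the accurate phase"
        )
    candidates = train.subset_rows(rest_idx)
    fitness = make_instance_fitness(candidates, spec)
    result = bhho.optimize(
        fitness,
        dim=len(rest_idx),
        config=config.bhho,
        seed=seed,
        init_masks=[np.ones(len(rest_idx), dtype=np.int8)],
    )
    kept = rest_idx[np.flatnonzero(result.best_mask > 0)]
    logger.info("CORT: tm=%d out=%d rest=%d ins=%d", train.n,
                len(qrp_result.rejected), len(rest_idx), len(kept))
    return CORTResult(
        qrp=qrp_result,
        bhho=result,
        kept=kept,
        tm=train.n,
        out=len(qrp_result.rejected),
        rest=len(rest_idx),
        ins=len(kept),
    )
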