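"""Fixed-final-size prototype generation: DSM and LVQ3.

Both methods compress the kNN reference set to exactly ``M`` labelled
prototypes -- a hard requirement for embedded deployment, where memory
must be deterministic.  Initialization places one prototype at each class
centroid and fills the remaining ``M - C`` slots round-robin over classes
with randomly drawn class members.  The correction phase then sweeps the
training set for ``I`` iterations, nudging prototypes with the standard
competitive-learning updates

    reward(p, x):   p <- p + alpha * (x - p)
    penalize(p, x): p <- p - alpha * (x - p)

with a fixed learning rate ``alpha = 0.01``.

*DSM* (decision surface mapping) models class borders: when the nearest
prototype ``p0`` disagrees with the sample label, ``p0`` is penalized and
the nearest same-label prototype ``ps`` (if any) rewarded; agreeing
samples change nothing.

*LVQ3* updates the two nearest prototypes ``(p0, p1)``: if both share the
sample's label, both are rewarded at the damped rate ``epsilon * alpha``;
otherwise, when the sample falls inside the relative-distance window
``min(d0/d1, d1/d0) > (1 - w)/(1 + w)`` and exactly one of the pair
matches, the match is rewarded and the other penalized.

Nearest-prototype search uses plain minimum searches (no sorting), so a
DSM run performs exactly ``I * N * M`` prototype-distance evaluations --
an accounting the instrumented counter reproduces exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .knn import LabeledDataset

__all__ = [
    "ReductionConfig",
    "PrototypeSet",
    "OpCounter",
    "initialize_prototypes",
    "dsm_step",
    "lvq3_step",
    "reduce",
    "count_operations",
]


@dataclass(frozen=True)
class ReductionConfig:
    """Parameters of a reduction run.

    ``m_prototypes`` is the exact final set size (>= number of classes),
    ``iterations`` the number of full passes over the training data.
    ``window`` and ``epsilon`` apply to LVQ3 only.  ``seed`` drives the
    random fill of initialization (and the optional shuffled pass order).
    """

    method: str = "dsm"
    m_prototypes: int = 7
    iterations: int = 40
    learning_rate: float = 0.01
    window: float = 0.3
    epsilon: float = 0.1
    seed: int = 0
    shuffle: bool = False

    def __post_init__(self):
        if self.method not in ("dsm", "lvq3"):
            raise ValueError("method must be 'dsm' or 'lvq3'")
        if self.m_prototypes < 1:
            raise ValueError("m_prototypes must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.window < 1:
            raise ValueError("window must lie in (0, 1)")


@dataclass
class PrototypeSet:
    """Exactly M labelled prototype vectors (the reduced reference set)."""

    prototypes: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be an (M, n_channels) matrix")
        if len(self.labels) != self.prototypes.shape[0]:
            raise ValueError("prototypes and labels must be aligned")

    def __len__(self) -> int:
        return self.prototypes.shape[0]

    def to_dataset(self) -> LabeledDataset:
        """View the prototype set as a dataset (one block per prototype)."""
        return LabeledDataset(self.prototypes, self.labels,
                              np.arange(len(self)))


class OpCounter:
    """Counts prototype-distance evaluations during a reduction run."""

    def __init__(self):
        self.distance_evals = 0


def initialize_prototypes(data: LabeledDataset, m: int,
                          seed: int = 0) -> PrototypeSet:
    """Class centroids first, then a seeded round-robin random fill.

    The first C prototypes are the per-class centres of mass (classes in
    sorted label order).  The remaining ``M - C`` are drawn round-robin
    over the classes, uniformly at random within each class without
    replacement; a class with fewer samples than requested draws falls
    back to sampling with replacement, with a warning.  Needs no distance
    evaluations (centroids are running sums).
    """
    classes = data.classes
    c = len(classes)
    if m < c:
        raise ValueError(f"m_prototypes={m} must be >= number of classes {c}")
    rng = np.random.default_rng(seed)
    protos = [data.samples[data.labels == cl].mean(axis=0) for cl in classes]
    labels = list(classes)

    n_extra = m - c
    per_class = [n_extra // c + (1 if i < n_extra % c else 0)
                 for i in range(c)]
    for cl, n_draw in zip(classes, per_class):
        if n_draw == 0:
            continue
        idx = np.nonzero(data.labels == cl)[0]
        if n_draw > len(idx):
            warnings.warn(
                f"class {cl!r} has only {len(idx)} samples for {n_draw} "
                "draws; sampling with replacement", RuntimeWarning,
                stacklevel=2)
            chosen = rng.choice(idx, size=n_draw, replace=True)
        else:
            chosen = rng.choice(idx, size=n_draw, replace=False)
        for i in chosen:
            protos.append(data.samples[i].copy())
            labels.append(cl)
    return PrototypeSet(np.array(protos), np.array(labels))


def _reward(protos: np.ndarray, i: int, x: np.ndarray, alpha: float) -> None:
    protos[i] += alpha * (x - protos[i])


def _penalize(protos: np.ndarray, i: int, x: np.ndarray, alpha: float) -> None:
    protos[i] -= alpha * (x - protos[i])


def _sq_distances(protos: np.ndarray, x: np.ndarray) -> np.ndarray:
    diff = protos - x
    return np.einsum("ij,ij->i", diff, diff)


def dsm_step(protos: PrototypeSet, x, y, alpha: float = 0.01,
             counter: Optional[OpCounter] = None) -> PrototypeSet:
    """One DSM correction: penalize a wrong nearest, reward nearest same-label.

    Mutates ``protos`` in place and returns it.  Evaluates exactly M
    prototype distances (one pass; the same-label minimum search reuses
    them).
    """
    x = np.asarray(x, dtype=float)
    p = protos.prototypes
    d2 = _sq_distances(p, x)
    if counter is not None:
        counter.distance_evals += len(p)
    i0 = int(np.argmin(d2))
    if protos.labels[i0] == y:
        return protos
    _penalize(p, i0, x, alpha)
    same = np.nonzero(protos.labels == y)[0]
    if len(same):
        i_s = int(same[np.argmin(d2[same])])
        _reward(p, i_s, x, alpha)
    return protos


def lvq3_step(protos: PrototypeSet, x, y, alpha: float = 0.01,
              window: float = 0.3, epsilon: float = 0.1,
              counter: Optional[OpCounter] = None) -> PrototypeSet:
    """One LVQ3 correction on the two nearest prototypes.

    Mutates ``protos`` in place and returns it.
    """
    x = np.asarray(x, dtype=float)
    p = protos.prototypes
    if len(p) < 2:
        raise ValueError("LVQ3 requires at least 2 prototypes")
    d2 = _sq_distances(p, x)
    if counter is not None:
        counter.distance_evals += len(p)
    order = np.argpartition(d2, 1)[:2]
    if d2[order[0]] > d2[order[1]] or (
            d2[order[0]] == d2[order[1]] and order[0] > order[1]):
        order = order[::-1]
    i0, i1 = int(order[0]), int(order[1])
    l0, l1 = protos.labels[i0], protos.labels[i1]

    if l0 == y and l1 == y:
        _reward(p, i0, x, epsilon * alpha)
        _reward(p, i1, x, epsilon * alpha)
        return protos

    d0, d1 = np.sqrt(d2[i0]), np.sqrt(d2[i1])
    if d0 == 0.0 and d1 == 0.0:
        inside = True
    elif d1 == 0.0 or d0 == 0.0:
        inside = False
    else:
        inside = min(d0 / d1, d1 / d0) > (1 - window) / (1 + window)
    if inside:
        if l0 == y and l1 != y:
            _reward(p, i0, x, alpha)
            _penalize(p, i1, x, alpha)
        elif l1 == y and l0 != y:
            _reward(p, i1, x, alpha)
            _penalize(p, i0, x, alpha)
    return protos


def reduce(data: LabeledDataset, cfg: ReductionConfig,
           counter: Optional[OpCounter] = None) -> PrototypeSet:
    """Initialize then run I correction passes; output size is exactly M.

    Pass order within an iteration is stable dataset order, or a fresh
    seeded permutation per iteration when ``cfg.shuffle`` is set (used by
    the order-robustness property tests).
    """
    protos = initialize_prototypes(data, cfg.m_prototypes, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    samples, labels = data.samples, data.labels
    n = data.n_samples
    for _ in range(cfg.iterations):
        order = rng.permutation(n) if cfg.shuffle else range(n)
        if cfg.method == "dsm":
            for i in order:
                dsm_step(protos, samples[i], labels[i],
                         alpha=cfg.learning_rate, counter=counter)
        else:
            for i in order:
                lvq3_step(protos, samples[i], labels[i],
                          alpha=cfg.learning_rate, window=cfg.window,
                          epsilon=cfg.epsilon, counter=counter)
    return protos


def count_operations(n: int, m: int, c: int, iterations: int) -> dict:
    """Predicted dominant-term operation counts for a reduction run.

    Initialization needs no distance evaluations (centroids are sums,
    O(M*N) arithmetic); the minimum-search correction phase evaluates
    exactly ``I * N * M`` prototype distances.
    """
    if min(n, m, c) < 1 or iterations < 0 or m < c:
        raise ValueError("arguments must be positive with m >= c")
    return {
        "init_distance_evals": 0,
        "init_arithmetic_ops": m * n,
        "reduction_distance_evals": iterations * n * m,
    }
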