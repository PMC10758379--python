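"""Block-wise cross-validation, hyperparameter grids and regression baselines.

Samples within one repetition block are serially correlated, so folding
must respect blocks: leave-one-group-out cross-validation holds out one
whole block per fold and trains on the rest, preventing within-block
leakage.  Accuracy is the arithmetic mean of per-fold accuracies (exact
label matches only; proportional scale is not scored offline).

``k`` is additionally reported as ``k_rel = k / n`` so neighbour counts
compare across datasets of different sizes; the largest admissible ``k``
is ``n`` minus the largest block size (the smallest training split any
fold sees).

Ridge regression (RR) and ridge regression on random Fourier features
(RR-RFF) are the regression baselines the instance-based methods are
compared against: one-hot class targets scaled by exertion intensity,
closed-form ridge solution, prediction by argmax activation with the
activation value as intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .knn import (KnnConfig, KnnModel, LabeledDataset, METRICS,
                  knn_classify_batch)
from .reduction import ReductionConfig, reduce as reduce_prototypes

__all__ = [
    "CvResult",
    "max_k",
    "blockwise_cv",
    "grid_search",
    "RidgeModel",
    "rr_fit",
    "rr_predict",
    "rff_map",
    "median_heuristic",
    "RffModel",
    "rr_rff_fit",
    "rr_rff_predict",
]

#: metric preference order for grid-search ties
_METRIC_ORDER = ("euclidean", "manhattan", "chebyshev", "mahalanobis")


@dataclass
class CvResult:
    """Per-fold accuracies of one configuration, with k_rel bookkeeping."""

    fold_accuracies: list
    config: KnnConfig
    k_rel: float

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def max_k(data: LabeledDataset) -> int:
    """Largest admissible k: total samples minus the largest block."""
    _, counts = np.unique(data.blocks, return_counts=True)
    return data.n_samples - int(counts.max())


def blockwise_cv(data: LabeledDataset, cfg: KnnConfig,
                 reduction: Optional[ReductionConfig] = None) -> CvResult:
    """Leave-one-group-out CV over repetition blocks.

    One fold per block id; the held-out block is classified against a
    model fitted on all remaining blocks (inverse covariance, when the
    metric needs it, is refitted per fold on training data only).  With a
    ``reduction`` configuration, each fold's training split is first
    compressed to M prototypes and the held-out block is classified
    against the prototypes instead (DSM-kNN style evaluation).
    """
    block_ids = np.unique(data.blocks)
    if len(block_ids) < 2:
        raise ValueError("block-wise CV needs at least 2 blocks")
    bound = max_k(data)
    if cfg.k > bound:
        raise ValueError(
            f"k={cfg.k} exceeds the block-wise bound n - max_block = {bound}")
    fold_accuracies = []
    for b in block_ids:
        test_mask = data.blocks == b
        train = data.subset(~test_mask)
        test = data.subset(test_mask)
        assert not np.intersect1d(np.unique(train.blocks),
                                  np.unique(test.blocks)).size, \
            "train/test block leakage"
        if reduction is not None:
            protos = reduce_prototypes(train, reduction)
            model = KnnModel.fit(protos.to_dataset(), cfg)
        else:
            model = KnnModel.fit(train, cfg)
        predicted = knn_classify_batch(model, test.samples)
        fold_accuracies.append(float(np.mean(predicted == test.labels)))
    return CvResult(fold_accuracies, cfg, k_rel=cfg.k / data.n_samples)


def grid_search(data: LabeledDataset, ks: Sequence[int],
                metrics: Sequence[str] = ("euclidean",),
                weightings: Sequence[str] = ("1/d^2",),
                ) -> Tuple[CvResult, pd.DataFrame]:
    """Exhaustive (k, metric, weighting) search by block-wise CV accuracy.

    Returns the best result and the full tidy table (columns ``k, k_rel,
    metric, weighting, fold, accuracy``), suitable for accuracy-vs-k_rel
    curves.  Ties break toward the smallest k, then the metric order
    euclidean, manhattan, chebyshev, mahalanobis, then weighting order.
    """
    if not (len(ks) and len(metrics) and len(weightings)):
        raise ValueError("grids must be non-empty")
    rows, results = [], []
    for metric in metrics:
        for weighting in weightings:
            for k in ks:
                cfg = KnnConfig(k=int(k), metric=metric, weighting=weighting)
                res = blockwise_cv(data, cfg)
                results.append(res)
                for fold, acc in enumerate(res.fold_accuracies):
                    rows.append({"k": int(k), "k_rel": res.k_rel,
                                 "metric": metric, "weighting": weighting,
                                 "fold": fold, "accuracy": acc})
    table = pd.DataFrame(rows)

    def sort_key(r: CvResult):
        return (-r.mean_accuracy, r.config.k,
                _METRIC_ORDER.index(r.config.metric),
                list(r.config.weighting))

    best = min(results, key=sort_key)
    return best, table


# ---------------------------------------------------------------------------
# regression baselines
# ---------------------------------------------------------------------------

@dataclass
class RidgeModel:
    """Closed-form ridge solution on one-hot intensity-scaled targets."""

    weights: np.ndarray           # (n_features [+1], n_classes)
    classes: np.ndarray
    fit_intercept: bool = True


def rr_fit(x: np.ndarray, labels, intensities=None, lam: float = 1.0,
           fit_intercept: bool = True) -> RidgeModel:
    """Fit ridge regression: W = (X'X + lam I)^-1 X'Y.

    Targets are one-hot class indicators scaled by per-sample exertion
    intensity (defaults to 1, i.e. full-intensity training).  ``lam = 0``
    is permitted (ordinary least squares via ``lstsq``).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    y = (labels[:, None] == classes[None, :]).astype(float)
    if intensities is not None:
        y = y * np.asarray(intensities, dtype=float)[:, None]
    design = np.hstack([x, np.ones((len(x), 1))]) if fit_intercept else x
    if lam == 0:
        w = np.linalg.lstsq(design, y, rcond=None)[0]
    else:
        g = design.T @ design + lam * np.eye(design.shape[1])
        w = np.linalg.solve(g, design.T @ y)
    return RidgeModel(weights=w, classes=classes, fit_intercept=fit_intercept)


def rr_predict(model: RidgeModel, x) -> Tuple[np.ndarray, np.ndarray,
                                              np.ndarray]:
    """Predict labels and scales: argmax activation, activation clamped [0,1].

    Returns ``(labels, scales, activations)`` for an (n, d) query array
    (a single vector is promoted to n = 1).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    design = np.hstack([x, np.ones((len(x), 1))]) \
        if model.fit_intercept else x
    act = design @ model.weights
    idx = np.argmax(act, axis=1)
    labels = model.classes[idx]
    scales = np.clip(act[np.arange(len(x)), idx], 0.0, 1.0)
    return labels, scales, act


def median_heuristic(x: np.ndarray, max_pairs: int = 2000,
                     seed: int = 0) -> float:
    """Median pairwise Euclidean distance (subsampled), the RFF bandwidth."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n, size=max_pairs)
    keep = i != j
    d = np.linalg.norm(x[i[keep]] - x[j[keep]], axis=1)
    med = float(np.median(d))
    return med if med > 0 else 1.0


def rff_map(x, d_features: int, sigma: float, seed: int = 0) -> np.ndarray:
    """Random Fourier features z(x) = sqrt(2/D) cos(Wx + b).

    ``W ~ Normal(0, sigma^-2)`` and ``b ~ Uniform[0, 2pi)`` are drawn once
    from ``seed``, so the map is deterministic given the seed; every
    entry is bounded by ``sqrt(2/D)``.  Inner products of mapped points
    approximate the Gaussian kernel exp(-||x-y||^2 / (2 sigma^2)) with
    O(1/sqrt(D)) error.
    """
    if d_features < 1:
        raise ValueError("d_features must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0 / sigma, size=(x.shape[1], d_features))
    b = rng.uniform(0.0, 2 * np.pi, size=d_features)
    return np.sqrt(2.0 / d_features) * np.cos(x @ w + b)


@dataclass
class RffModel:
    """RR-RFF: ridge regression in a random-Fourier-feature space."""

    ridge: RidgeModel
    d_features: int
    sigma: float
    seed: int


def rr_rff_fit(x, labels, intensities=None, d_features: int = 200,
               sigma: Optional[float] = None, lam: float = 1.0,
               seed: int = 0) -> RffModel:
    """Map inputs through RFF (bandwidth defaulting to the median
    heuristic), then fit ridge regression in feature space."""
    x = np.asarray(x, dtype=float)
    if sigma is None:
        sigma = median_heuristic(x, seed=seed)
    z = rff_map(x, d_features, sigma, seed=seed)
    ridge = rr_fit(z, labels, intensities=intensities, lam=lam)
    return RffModel(ridge=ridge, d_features=d_features, sigma=sigma,
                    seed=seed)


def rr_rff_predict(model: RffModel, x):
    """Predict labels/scales/activations for queries through the RFF map."""
    z = rff_map(x, model.d_features, model.sigma, seed=model.seed)
    return rr_predict(model.ridge, z)
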