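"""Parameterized k-nearest-neighbour classification on envelope vectors.

The classifier is instance-based: a reference set of labelled 8-channel
envelope vectors, a neighbour count ``k``, a distance metric (Manhattan,
Euclidean, Chebyshev or Mahalanobis) and a distance weighting (uniform or
an inverse power 1/d^e, e in {1/2, 1, 2, 3}).  Prediction is a (weighted)
majority vote over the ``k`` nearest references; for ``k = 1`` the sort is
replaced by a single minimum search.

Declared conventions (the field-standard kNN literature leaves these open):

* a zero-distance neighbour under inverse weighting wins outright
  (infinite-weight semantics); several disagreeing zero-distance
  neighbours are resolved by unweighted majority, then label order;
* vote ties break by smallest summed distance among the tied classes,
  then by label-alphabet order;
* equal distances at the k-th rank keep the first sample in stable data
  order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .envelope import N_CHANNELS

GESTURES = ("rs", "pw", "pn", "fl", "ex", "pr", "su")
REST_LABEL = "rs"
METRICS = ("manhattan", "euclidean", "chebyshev", "mahalanobis")
WEIGHTINGS = ("uniform", "1/sqrt(d)", "1/d", "1/d^2", "1/d^3")

#: exponent e of the inverse-distance weight w = d**(-e)
WEIGHT_EXPONENTS = {
    "uniform": 0.0,
    "1/sqrt(d)": 0.5,
    "1/d": 1.0,
    "1/d^2": 2.0,
    "1/d^3": 3.0,
}

__all__ = [
    "GESTURES",
    "REST_LABEL",
    "METRICS",
    "WEIGHTINGS",
    "WEIGHT_EXPONENTS",
    "LabeledDataset",
    "KnnConfig",
    "KnnModel",
    "distance",
    "pairwise_distances",
    "neighbour_weights",
    "fit_inverse_covariance",
    "classify_distances",
    "knn_classify",
    "knn_classify_batch",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Aligned envelope samples, gesture labels and repetition-block ids.

    ``samples`` is an (N, 8) array of non-negative envelope amplitudes,
    ``labels`` the per-sample gesture label and ``blocks`` the id of the
    repetition capture each sample belongs to (the unit of block-wise
    cross-validation).
    """

    samples: np.ndarray
    labels: np.ndarray
    blocks: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        self.blocks = np.asarray(self.blocks)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be (N, {N_CHANNELS}), got {self.samples.shape}"
            )
        n = self.samples.shape[0]
        if n < 1:
            raise ValueError("dataset must contain at least one sample")
        if len(self.labels) != n or len(self.blocks) != n:
            raise ValueError("samples, labels and blocks must be aligned")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels (the label alphabet of this set)."""
        return np.unique(self.labels)

    def subset(self, mask) -> "LabeledDataset":
        return LabeledDataset(self.samples[mask], self.labels[mask],
                              self.blocks[mask])


@dataclass(frozen=True)
class KnnConfig:
    """Neighbour count, distance metric and distance weighting."""

    k: int = 1
    metric: str = "euclidean"
    weighting: str = "1/d^2"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")


@dataclass
class KnnModel:
    """A fitted instance-based classifier: reference data + configuration."""

    data: LabeledDataset
    config: KnnConfig
    inv_cov: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        if self.config.k > self.data.n_samples:
            raise ValueError("k cannot exceed the reference-set size")
        if self.config.metric == "mahalanobis" and self.inv_cov is None:
            raise ValueError("mahalanobis metric requires a fitted inverse "
                             "covariance (use KnnModel.fit)")

    @classmethod
    def fit(cls, data: LabeledDataset, config: KnnConfig) -> "KnnModel":
        """Attach configuration to data, fitting Sigma^-1 when needed."""
        inv_cov = None
        if config.metric == "mahalanobis":
            inv_cov = fit_inverse_covariance(data)
        return cls(data=data, config=config, inv_cov=inv_cov)


# ---------------------------------------------------------------------------
# distances and weights
# ---------------------------------------------------------------------------

_CDIST_NAME = {
    "manhattan": "cityblock",
    "euclidean": "euclidean",
    "chebyshev": "chebyshev",
    "mahalanobis": "mahalanobis",
}


def pairwise_distances(queries, references, metric: str,
                       inv_cov: Optional[np.ndarray] = None) -> np.ndarray:
    """Distance matrix between query rows and reference rows."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    references = np.atleast_2d(np.asarray(references, dtype=float))
    if queries.shape[1] != references.shape[1]:
        raise ValueError("query/reference dimensionality mismatch")
    if metric == "mahalanobis":
        if inv_cov is None:
            raise ValueError("mahalanobis distance requires inv_cov")
        return cdist(queries, references, metric="mahalanobis", VI=inv_cov)
    if metric not in _CDIST_NAME:
        raise ValueError(f"metric must be one of {METRICS}")
    return cdist(queries, references, metric=_CDIST_NAME[metric])


def distance(a, b, metric: str = "euclidean",
             inv_cov: Optional[np.ndarray] = None) -> float:
    """Distance between two 8-vectors under the given metric."""
    return float(pairwise_distances(np.asarray(a)[np.newaxis],
                                    np.asarray(b)[np.newaxis],
                                    metric, inv_cov)[0, 0])


def neighbour_weights(distances, weighting: str) -> np.ndarray:
    """Per-neighbour vote weights: all ones for uniform, else d**(-e).

    A zero distance yields ``inf`` -- callers implementing the vote apply
    the exact-match rule before summing.
    """
    if weighting not in WEIGHT_EXPONENTS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    e = WEIGHT_EXPONENTS[weighting]
    if e == 0.0:
        return np.ones_like(d)
    with np.errstate(divide="ignore"):
        return d ** (-e)


def fit_inverse_covariance(data: LabeledDataset) -> np.ndarray:
    """Inverse of the pooled 8x8 sample covariance of the reference set.

    The covariance is pooled over all classes.  An ill-conditioned or
    singular estimate is ridge-regularized (1e-6 * trace/8 on the
    diagonal, or 1e-6 if the trace vanishes) with a warning; as a last
    resort the Moore-Penrose pseudo-inverse is used.
    """
    cov = np.cov(data.samples, rowvar=False)
    cov = np.atleast_2d(cov)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-6 * (np.trace(cov) / cov.shape[0] or 1.0)
        warnings.warn(
            "sample covariance is ill-conditioned; adding ridge "
            f"{ridge:.3g} to the diagonal", RuntimeWarning, stacklevel=2)
        cov = cov + ridge * np.eye(cov.shape[0])
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("covariance not invertible; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
        inv = np.linalg.pinv(cov)
    return (inv + inv.T) / 2.0  # enforce exact symmetry


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------

def _tie_break(cands: Sequence, summed_d: dict) -> object:
    """Smallest summed distance among tied classes, then label order."""
    return min(cands, key=lambda c: (summed_d[c], str(c)))


def classify_distances(distances, labels, config: KnnConfig,
                       method: str = "auto"):
    """Vote on precomputed query-to-reference distances.

    ``method`` selects the neighbour-search path: ``"minsearch"`` (single
    minimum search, valid only for k = 1), ``"sort"`` (full stable sort),
    or ``"auto"`` (minsearch when k = 1, else sort).  Both paths implement
    identical vote semantics; their equivalence is a tested property.

    Returns ``(label, neighbour_indices, neighbour_distances)``.
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    k = config.k
    if k > d.shape[0]:
        raise ValueError("k exceeds the number of reference samples")
    if method == "auto":
        method = "minsearch" if k == 1 else "sort"
    if method == "minsearch":
        if k != 1:
            raise ValueError("minimum-search path requires k = 1")
        idx = np.array([int(np.argmin(d))])
    elif method == "sort":
        idx = np.argsort(d, kind="stable")[:k]
    else:
        raise ValueError("method must be 'auto', 'minsearch' or 'sort'")

    nd = d[idx]
    nl = labels[idx]

    inverse = WEIGHT_EXPONENTS[config.weighting] > 0.0
    if inverse and np.any(nd == 0.0):
        # exact-match rule: zero-distance neighbours dominate
        zl = nl[nd == 0.0]
        classes, counts = np.unique(zl, return_counts=True)
        best = counts.max()
        cands = classes[counts == best]
        label = min(cands, key=str)
        return label, idx, nd

    w = neighbour_weights(nd, config.weighting)
    sums: dict = {}
    dist_sums: dict = {}
    for lab, wi, di in zip(nl, w, nd):
        sums[lab] = sums.get(lab, 0.0) + wi
        dist_sums[lab] = dist_sums.get(lab, 0.0) + di
    best = max(sums.values())
    cands = [c for c, s in sums.items() if s == best]
    label = cands[0] if len(cands) == 1 else _tie_break(cands, dist_sums)
    return label, idx, nd


def knn_classify(model: KnnModel, query, method: str = "auto"):
    """Classify one envelope vector.

    Returns ``(label, neighbours)`` where ``neighbours`` is a list of
    ``(reference_index, distance, reference_label)`` for the k nearest
    references in rank order.
    """
    if model.data.n_samples == 0:
        raise ValueError("empty reference set")
    d = pairwise_distances(np.asarray(query)[np.newaxis],
                           model.data.samples, model.config.metric,
                           model.inv_cov)[0]
    label, idx, nd = classify_distances(d, model.data.labels, model.config,
                                        method=method)
    neighbours = [(int(i), float(di), model.data.labels[i])
                  for i, di in zip(idx, nd)]
    return label, neighbours


def knn_classify_batch(model: KnnModel, queries) -> np.ndarray:
    """Vectorized classification of many queries (one distance matrix).

    Semantics are identical to per-query :func:`knn_classify`; the k = 1
    common case short-circuits to a row-wise minimum search, falling back
    to the full vote only for rows touched by the exact-match rule.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    d = pairwise_distances(queries, model.data.samples, model.config.metric,
                           model.inv_cov)
    labels = model.data.labels
    cfg = model.config
    if cfg.k == 1:
        nearest = np.argmin(d, axis=1)
        out = labels[nearest].copy()
        if WEIGHT_EXPONENTS[cfg.weighting] > 0.0:
            zero_rows = np.nonzero(d[np.arange(len(out)), nearest] == 0.0)[0]
            for r in zero_rows:
                out[r] = classify_distances(d[r], labels, cfg)[0]
        return out
    return np.array([classify_distances(row, labels, cfg)[0] for row in d])
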