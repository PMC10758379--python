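"""Rest thresholding and linear proportionality scaling.

Plain kNN classification predicts gesture identity only.  Proportional
control adds an intensity estimate on top of it, built from the *magnitude*
of an envelope sample -- the arithmetic mean over its 8 channels, which is
assumed proportional to exertion intensity:

* rest thresholding: the mean magnitude of the rest samples gathered in
  training is the rest baseline ``t0``; a query whose magnitude does not
  exceed the threshold ``t = g * t0`` is predicted as rest outright;
* normalization: above-threshold queries are divided by their magnitude
  before classification, so that a gesture exerted at low intensity still
  matches its full-intensity references in shape;
* scaling: the predicted gesture receives a linear intensity factor
  ``s(m) = (m - m0) / (m_max - m0)`` clamped to [0, 1], where ``m_max`` is
  the class's mean full-intensity training magnitude and ``m0 = t / v``
  is an offset controlled by the divisor ``v`` (``v = inf`` disables the
  offset).

Defaults ``g = 2.5`` and ``v = 5`` are the configuration carried into the
user studies.  The scaling magnitude is taken from the raw query (before
normalization), since normalization exists only to make classification
magnitude-invariant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .knn import (KnnConfig, KnnModel, LabeledDataset, REST_LABEL,
                  knn_classify)

__all__ = [
    "ProportionalParams",
    "ProportionalPrediction",
    "magnitude",
    "normalize",
    "fit_proportional",
    "scale_factor",
    "build_reference_model",
    "predict_proportional",
]


@dataclass
class ProportionalParams:
    """Fitted rest baseline, gain, offset divisor and per-class maxima."""

    t0: float
    g: float = 2.5
    v: float = 5.0
    m_max: Dict[object, float] = field(default_factory=dict)
    rest_label: object = REST_LABEL

    def __post_init__(self):
        if self.g <= 0:
            raise ValueError("gain g must be positive")
        if self.v <= 0:
            raise ValueError("divisor v must be positive (inf for no offset)")
        if self.t0 < 0:
            raise ValueError("rest baseline t0 must be non-negative")

    @property
    def t(self) -> float:
        """Rest magnitude threshold t = g * t0."""
        return self.g * self.t0

    @property
    def m0(self) -> float:
        """Proportionality-function offset m0 = t / v (0 when v = inf)."""
        if math.isinf(self.v):
            return 0.0
        return self.t / self.v


@dataclass
class ProportionalPrediction:
    """Gesture label with intensity scale in [0, 1] and raw magnitude."""

    label: object
    scale: float
    magnitude: float


def magnitude(x) -> np.ndarray | float:
    """Mean envelope amplitude over the 8 channels.

    Accepts a single 8-vector (returns a float) or an (n, 8) stream
    (returns an n-vector).
    """
    arr = np.asarray(x, dtype=float)
    m = arr.mean(axis=-1)
    return float(m) if m.ndim == 0 else m


def normalize(x) -> np.ndarray:
    """Divide a sample by its magnitude, yielding a magnitude-1 shape vector.

    Rows of an (n, 8) input are normalized independently.  A zero
    magnitude is an error: callers must have applied the rest threshold
    first.
    """
    arr = np.asarray(x, dtype=float)
    m = np.asarray(magnitude(arr))
    if np.any(m <= 0):
        raise ValueError("cannot normalize a sample of zero magnitude "
                         "(apply the rest threshold first)")
    return arr / m[..., np.newaxis]


def fit_proportional(train: LabeledDataset, g: float = 2.5, v: float = 5.0,
                     rest_label=REST_LABEL) -> ProportionalParams:
    """Estimate t0 and per-class magnitude maxima from full-intensity data.

    ``t0`` is the mean magnitude of the rest samples; ``m_max[c]`` the
    mean magnitude of class-c samples, for every non-rest class c.  The
    mean (rather than median or max) is the implemented choice throughout.

    Raises if the training set has no rest samples, or if the resulting
    offset ``m0 = g * t0 / v`` is not below ``m_max[c]`` for some class
    (the proportionality function would be degenerate).  A perfectly
    silent rest (t0 = 0) disables thresholding with a warning.
    """
    rest_mask = train.labels == rest_label
    if not np.any(rest_mask):
        raise ValueError(f"training set contains no {rest_label!r} samples")
    mags = magnitude(train.samples)
    t0 = float(mags[rest_mask].mean())
    params = ProportionalParams(t0=t0, g=g, v=v, rest_label=rest_label)
    for c in train.classes:
        if c == rest_label:
            continue
        params.m_max[c] = float(mags[train.labels == c].mean())
        if params.m0 >= params.m_max[c]:
            raise ValueError(
                f"offset m0={params.m0:.4g} >= m_max[{c!r}]="
                f"{params.m_max[c]:.4g}; lower g or raise v")
    if not params.m_max:
        raise ValueError("training set needs at least one non-rest class")
    if t0 == 0.0:
        warnings.warn("rest baseline t0 = 0: rest threshold disabled, every "
                      "active query will be classified", RuntimeWarning,
                      stacklevel=2)
    return params


def scale_factor(m: float, params: ProportionalParams, cls) -> float:
    """Linear intensity factor s(m) = (m - m0)/(m_max - m0), clamped to [0,1]."""
    if cls == params.rest_label:
        raise ValueError("rest has no proportionality scale")
    if m < 0:
        raise ValueError("magnitude must be non-negative")
    m_max = params.m_max[cls]
    s = (m - params.m0) / (m_max - params.m0)
    return float(min(1.0, max(0.0, s)))


def build_reference_model(train: LabeledDataset, config: KnnConfig,
                          rest_label=REST_LABEL) -> KnnModel:
    """Build the normalized non-rest reference model used above threshold.

    Rest samples are excluded: a query that clears the rest threshold may
    only receive a non-rest label, so rest references would merely distort
    the vote.  The remaining samples are normalized to magnitude 1.
    """
    mask = train.labels != rest_label
    if not np.any(mask):
        raise ValueError("no non-rest samples to build references from")
    active = train.subset(mask)
    data = LabeledDataset(normalize(active.samples), active.labels,
                          active.blocks)
    return KnnModel.fit(data, config)


def predict_proportional(model: KnnModel, params: ProportionalParams,
                         x) -> ProportionalPrediction:
    """Threshold, classify (normalized) and scale one envelope sample.

    Below or at the rest threshold the prediction is ``(rest, 0)``;
    otherwise the normalized query is classified against the non-rest
    reference set and the raw-query magnitude is mapped through the
    class's proportionality function.
    """
    m = magnitude(np.asarray(x, dtype=float))
    if m <= params.t:
        return ProportionalPrediction(params.rest_label, 0.0, float(m))
    label, _ = knn_classify(model, normalize(x))
    return ProportionalPrediction(label, scale_factor(m, params, label),
                                  float(m))
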