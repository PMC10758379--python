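"""End-to-end controllers: training data in, (label, scale) callables out.

A *controller* is what the target-achievement harness drives: a callable
mapping one 8-channel envelope sample to a ``(label, scale)`` pair.  Four
are provided, mirroring the methods compared online:

* ``knn`` -- proportional kNN: rest thresholding, normalization, kNN on
  the normalized non-rest references, linear proportionality scaling;
* ``dsm_knn`` -- the same prediction pipeline after DSM-reducing the
  training set to M prototypes (scaling parameters still come from the
  full training data, reduction only shrinks the reference set);
* ``rr`` -- standard ridge regression on one-hot intensity targets;
* ``rr_rff`` -- ridge regression on random Fourier features.
"""

from __future__ import annotations

from typing import Callable, Dict, Sequence

from .io import RunConfig
from .knn import LabeledDataset, REST_LABEL
from .proportional import (build_reference_model, fit_proportional,
                           predict_proportional)
from .reduction import ReductionConfig, reduce as reduce_prototypes
from .validation import rr_fit, rr_predict, rr_rff_fit, rr_rff_predict

__all__ = ["make_knn_controller", "make_dsm_knn_controller",
           "make_rr_controller", "make_rr_rff_controller",
           "build_controllers"]


def make_knn_controller(train: LabeledDataset,
                        cfg: RunConfig) -> Callable:
    """Proportional kNN pipeline on the full training set."""
    params = fit_proportional(train, g=cfg.g, v=cfg.v)
    model = build_reference_model(train, cfg.knn_config())

    def controller(x):
        p = predict_proportional(model, params, x)
        return p.label, p.scale

    return controller


def make_dsm_knn_controller(train: LabeledDataset,
                            cfg: RunConfig) -> Callable:
    """Proportional kNN on a DSM-reduced reference set."""
    rcfg = ReductionConfig(method=cfg.reduction_method,
                           m_prototypes=cfg.m_prototypes,
                           iterations=cfg.iterations,
                           learning_rate=cfg.learning_rate,
                           window=cfg.window, epsilon=cfg.epsilon,
                           seed=cfg.seed)
    protos = reduce_prototypes(train, rcfg)
    params = fit_proportional(train, g=cfg.g, v=cfg.v)
    model = build_reference_model(protos.to_dataset(), cfg.knn_config())

    def controller(x):
        p = predict_proportional(model, params, x)
        return p.label, p.scale

    return controller


def make_rr_controller(train: LabeledDataset, cfg: RunConfig,
                       lam: float = 1.0) -> Callable:
    """Standard ridge regression baseline."""
    model = rr_fit(train.samples, train.labels, lam=lam)

    def controller(x):
        labels, scales, _ = rr_predict(model, x)
        label = labels[0]
        return label, 0.0 if label == REST_LABEL else float(scales[0])

    return controller


def make_rr_rff_controller(train: LabeledDataset, cfg: RunConfig,
                           lam: float = 1.0, d_features: int = 200) -> Callable:
    """Ridge regression with random Fourier features."""
    model = rr_rff_fit(train.samples, train.labels, lam=lam,
                       d_features=d_features, seed=cfg.seed)

    def controller(x):
        labels, scales, _ = rr_rff_predict(model, x)
        label = labels[0]
        return label, 0.0 if label == REST_LABEL else float(scales[0])

    return controller


_FACTORIES = {
    "knn": make_knn_controller,
    "dsm_knn": make_dsm_knn_controller,
    "rr": make_rr_controller,
    "rr_rff": make_rr_rff_controller,
}


def build_controllers(train: LabeledDataset, cfg: RunConfig,
                      methods: Sequence[str]) -> Dict[str, Callable]:
    """Fit one controller per requested method name."""
    unknown = set(methods) - set(_FACTORIES)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; "
                         f"choose from {sorted(_FACTORIES)}")
    return {m: _FACTORIES[m](train, cfg) for m in methods}
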