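"""Dataset/model serialization and run configuration.

Everything on disk is delimited text for inspectability.  A dataset file
is CSV with a small ``#``-prefixed header carrying the schema version and
the stream kind (``raw`` signed samples vs ``envelope`` amplitudes),
columns ``t, ch1..ch8[, label][, block][, subject]``.  Floats are written
with ``repr`` precision, so ``load(save(x))`` is bit-exact for finite
values.

A model file holds the reference matrix and labels as CSV plus JSON
header lines for the kNN configuration, the optional inverse covariance
and the optional proportional-control parameters.  Prototype sets reuse
the dataset format without the block column.

:class:`RunConfig` gathers every tunable with the user-study defaults
(k=1, euclidean, 1/d^2 weighting, g=2.5, v=5, M=7 prototypes, 40
iterations) and round-trips through YAML; its hash is logged with every
CLI run for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .envelope import FC_DEFAULT, FS_DEFAULT, N_CHANNELS, ORDER_DEFAULT
from .knn import KnnConfig, KnnModel, LabeledDataset
from .proportional import ProportionalParams
from .reduction import PrototypeSet

SCHEMA_VERSION = 1
_CH_COLS = [f"ch{i}" for i in range(1, N_CHANNELS + 1)]

__all__ = [
    "SCHEMA_VERSION",
    "ParseError",
    "RunConfig",
    "config_hash",
    "save_dataset",
    "load_dataset",
    "save_stream",
    "load_stream",
    "save_prototypes",
    "load_prototypes",
    "save_model",
    "load_model",
]


class ParseError(ValueError):
    """A dataset or model file violates the documented schema."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All module parameters with the user-study defaults."""

    # envelope filter
    fs: float = FS_DEFAULT
    fc: float = FC_DEFAULT
    order: int = ORDER_DEFAULT
    # kNN
    k: int = 1
    metric: str = "euclidean"
    weighting: str = "1/d^2"
    # proportional control
    g: float = 2.5
    v: float = 5.0
    # reduction
    reduction_method: str = "dsm"
    m_prototypes: int = 7
    iterations: int = 40
    learning_rate: float = 0.01
    window: float = 0.3
    epsilon: float = 0.1
    # protocol
    dwell_s: float = 1.5
    timeout_s: float = 10.0
    margin: float = 0.2
    # global
    seed: int = 0

    def knn_config(self) -> KnnConfig:
        return KnnConfig(k=self.k, metric=self.metric,
                         weighting=self.weighting)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a configuration, for run provenance logs."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# datasets and streams
# ---------------------------------------------------------------------------

def _write_with_header(path, df: pd.DataFrame, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        # %.17g round-trips every finite double bit-exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if ":" in text:
                key, _, value = text.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file (no data rows)") from None
    if df.empty:
        raise ParseError(f"{path}: empty dataset (header but no rows)")
    return df


def _check_channels(df: pd.DataFrame, path) -> np.ndarray:
    present = [c for c in df.columns if c.startswith("ch")]
    if sorted(present) != sorted(_CH_COLS):
        raise ParseError(
            f"{path}: expected channel columns {_CH_COLS}, found {present}")
    ch = df[_CH_COLS].apply(pd.to_numeric, errors="coerce")
    bad = ch.isna().any(axis=1)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ParseError(
            f"{path}: non-numeric or missing channel value at data row "
            f"{row} (0-based, after header)")
    return ch.to_numpy(dtype=float)


def save_dataset(path, data: LabeledDataset, kind: str = "envelope",
                 config: Optional[RunConfig] = None,
                 subject: Optional[str] = None) -> None:
    """Write a labelled dataset as headered CSV (kind: raw|envelope)."""
    df = pd.DataFrame(data.samples, columns=_CH_COLS)
    df.insert(0, "t", np.arange(data.n_samples))
    df["label"] = data.labels
    df["block"] = data.blocks
    if subject is not None:
        df["subject"] = subject
    header = [f"myoknn dataset v{SCHEMA_VERSION}", f"kind: {kind}"]
    if config is not None:
        header.append("config: " + json.dumps(config.to_dict(),
                                              sort_keys=True))
    _write_with_header(path, df, header)


def load_dataset(path) -> LabeledDataset:
    """Read a labelled dataset (label and block columns required)."""
    df = _read_csv(path)
    samples = _check_channels(df, path)
    for col in ("label", "block"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return LabeledDataset(samples, df["label"].to_numpy(),
                          df["block"].to_numpy())


def save_stream(path, stream: np.ndarray, kind: str,
                config: Optional[RunConfig] = None) -> None:
    """Write an unlabelled (n, 8) stream (e.g. a raw capture to filter)."""
    stream = np.asarray(stream, dtype=float)
    df = pd.DataFrame(stream, columns=_CH_COLS)
    df.insert(0, "t", np.arange(len(df)))
    header = [f"myoknn dataset v{SCHEMA_VERSION}", f"kind: {kind}"]
    if config is not None:
        header.append("config: " + json.dumps(config.to_dict(),
                                              sort_keys=True))
    _write_with_header(path, df, header)


def load_stream(path):
    """Read any stream file; returns ``(samples, kind)``."""
    meta = _read_header(path)
    df = _read_csv(path)
    samples = _check_channels(df, path)
    return samples, meta.get("kind", "envelope")


def save_prototypes(path, protos: PrototypeSet,
                    config: Optional[RunConfig] = None) -> None:
    """Dataset format without the block column."""
    df = pd.DataFrame(protos.prototypes, columns=_CH_COLS)
    df.insert(0, "t", np.arange(len(protos)))
    df["label"] = protos.labels
    header = [f"myoknn dataset v{SCHEMA_VERSION}", "kind: prototypes"]
    if config is not None:
        header.append("config: " + json.dumps(config.to_dict(),
                                              sort_keys=True))
    _write_with_header(path, df, header)


def load_prototypes(path) -> PrototypeSet:
    df = _read_csv(path)
    samples = _check_channels(df, path)
    if "label" not in df.columns:
        raise ParseError(f"{path}: missing required column 'label'")
    return PrototypeSet(samples, df["label"].to_numpy())


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def save_model(path, model: KnnModel,
               params: Optional[ProportionalParams] = None) -> None:
    """Serialize reference matrix + labels + config (+ Sigma^-1, + scaling)."""
    df = pd.DataFrame(model.data.samples, columns=_CH_COLS)
    df["label"] = model.data.labels
    df["block"] = model.data.blocks
    header = [
        f"myoknn model v{SCHEMA_VERSION}",
        "knn: " + json.dumps(dataclasses.asdict(model.config)),
    ]
    if model.inv_cov is not None:
        header.append("invcov: " + json.dumps(model.inv_cov.tolist()))
    if params is not None:
        header.append("proportional: " + json.dumps({
            "t0": params.t0, "g": params.g,
            "v": "inf" if math.isinf(params.v) else params.v,
            "m_max": {str(k): v for k, v in params.m_max.items()},
            "rest_label": str(params.rest_label)}))
    _write_with_header(path, df, header)


def load_model(path):
    """Load a model file; returns ``(KnnModel, ProportionalParams | None)``."""
    meta = _read_header(path)
    if "knn" not in meta:
        raise ParseError(f"{path}: not a model file (missing knn header)")
    df = _read_csv(path)
    samples = _check_channels(df, path)
    for col in ("label", "block"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    data = LabeledDataset(samples, df["label"].to_numpy(),
                          df["block"].to_numpy())
    config = KnnConfig(**json.loads(meta["knn"]))
    inv_cov = (np.array(json.loads(meta["invcov"]))
               if "invcov" in meta else None)
    model = KnnModel(data=data, config=config, inv_cov=inv_cov)
    params = None
    if "proportional" in meta:
        p = json.loads(meta["proportional"])
        v = math.inf if p["v"] == "inf" else float(p["v"])
        params = ProportionalParams(t0=float(p["t0"]), g=float(p["g"]), v=v,
                                    m_max=dict(p["m_max"]),
                                    rest_label=p["rest_label"])
    return model, params
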