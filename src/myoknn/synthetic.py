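"""Seeded synthetic 8-channel envelope data with the structure the method assumes.

The generator stands in for armband captures: each gesture class has a
fixed non-negative 8-channel activation pattern ``a_c`` whose amplitude
scales linearly with exertion intensity ``i``; a sample is

    x = i * a_c + noise,   noise per channel Gaussian(0, sigma) rectified at 0

so envelopes stay non-negative.  Samples come in repetition blocks of 400
(2 s at 200 Hz), the capture unit of block-wise cross-validation; each
(class, repetition, intensity) capture is one block.

Default patterns give each gesture a dominant channel pair with small
cross-talk on the remaining channels, loosely mimicking overlapping
forearm muscle groups (power grasp and pointing share a dominant channel,
so their confusion structure is exercisable).  Pattern magnitudes are
around 0.45, so with the default noise sigma = 0.1 a one-third-intensity
exertion still clears the default rest threshold ``t = 2.5 * t0``.

A raw-signal generator is also provided for exercising the envelope
filter end to end: a zero-mean unit Gaussian carrier amplitude-modulated
by ``i * a_c``, whose rectified-and-low-passed steady state approaches
``i * a_c * E|N(0,1)| = i * a_c * sqrt(2/pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .envelope import FS_DEFAULT, N_CHANNELS
from .knn import LabeledDataset, REST_LABEL, pairwise_distances
from .proportional import normalize

__all__ = [
    "DEFAULT_PATTERNS",
    "SyntheticConfig",
    "generate_envelope_dataset",
    "generate_raw_stream",
    "min_pattern_separation",
]

#: per-gesture activation patterns (8 channels, arbitrary envelope units)
DEFAULT_PATTERNS: Dict[str, np.ndarray] = {
    "rs": np.zeros(8),
    "pw": np.array([1.6, 1.2, 0.3, 0.1, 0.1, 0.1, 0.1, 0.2]),
    "pn": np.array([0.4, 1.5, 1.1, 0.2, 0.1, 0.1, 0.1, 0.1]),
    "fl": np.array([0.1, 0.2, 0.3, 1.5, 1.3, 0.2, 0.1, 0.1]),
    "ex": np.array([0.1, 0.1, 0.1, 0.2, 0.4, 1.6, 1.2, 0.1]),
    "pr": np.array([0.2, 0.1, 0.1, 0.1, 0.1, 0.3, 1.5, 1.3]),
    "su": np.array([1.3, 0.1, 0.1, 0.1, 0.2, 0.1, 0.3, 1.5]),
}


@dataclass
class SyntheticConfig:
    """Stated world of a synthetic capture session.

    ``classes`` lists the gestures (rest first); ``repetitions`` and
    ``samples_per_rep`` mirror the capture protocol (2 s at 200 Hz = 400
    samples per repetition); ``intensities`` are the exertion levels
    recorded (training sets use full intensity only).  ``noise`` selects
    the channel-noise family: zero-rectified Gaussian (default) or
    log-normal.
    """

    classes: Tuple[str, ...] = ("rs", "pw", "pn", "fl", "ex")
    activation_patterns: Optional[Dict[str, np.ndarray]] = None
    noise_sd: float = 0.1
    repetitions: int = 3
    samples_per_rep: int = 400
    intensities: Tuple[float, ...] = (1.0,)
    seed: int = 0
    noise: str = "normal"

    def __post_init__(self):
        if self.noise not in ("normal", "lognormal"):
            raise ValueError("noise must be 'normal' or 'lognormal'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.repetitions, self.samples_per_rep) < 1:
            raise ValueError("repetitions and samples_per_rep must be >= 1")
        if any(not 0 < i <= 1 for i in self.intensities):
            raise ValueError("intensities must lie in (0, 1]")
        if self.activation_patterns is None:
            missing = [c for c in self.classes if c not in DEFAULT_PATTERNS]
            if missing:
                raise ValueError(f"no default pattern for classes {missing}; "
                                 "provide activation_patterns")
            self.activation_patterns = {c: DEFAULT_PATTERNS[c].copy()
                                        for c in self.classes}
        for c in self.classes:
            pat = np.asarray(self.activation_patterns[c], dtype=float)
            if pat.shape != (N_CHANNELS,) or np.any(pat < 0):
                raise ValueError(f"pattern for {c!r} must be a non-negative "
                                 f"{N_CHANNELS}-vector")
            self.activation_patterns[c] = pat


def _noise(rng: np.random.Generator, cfg: SyntheticConfig,
           shape) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(shape)
    if cfg.noise == "lognormal":
        # zero-median multiplicative-style noise, still non-negative shift
        return rng.lognormal(mean=0.0, sigma=1.0, size=shape) * cfg.noise_sd \
            - cfg.noise_sd
    return rng.normal(0.0, cfg.noise_sd, size=shape)


def generate_envelope_dataset(cfg: SyntheticConfig) -> LabeledDataset:
    """Draw a labelled envelope dataset; bit-identical for equal (cfg, seed).

    Block ids enumerate (class, repetition, intensity) captures in order,
    so every block id maps to exactly one capture.  Dataset size is
    ``|classes| * repetitions * |intensities| * samples_per_rep``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples, labels, blocks = [], [], []
    block_id = 0
    for c in cfg.classes:
        pattern = cfg.activation_patterns[c]
        for _ in range(cfg.repetitions):
            for intensity in cfg.intensities:
                base = intensity * pattern
                x = base + _noise(rng, cfg,
                                  (cfg.samples_per_rep, N_CHANNELS))
                np.maximum(x, 0.0, out=x)  # envelopes are non-negative
                samples.append(x)
                labels.extend([c] * cfg.samples_per_rep)
                blocks.extend([block_id] * cfg.samples_per_rep)
                block_id += 1
    return LabeledDataset(np.vstack(samples), np.array(labels),
                          np.array(blocks))


def generate_raw_stream(cfg: SyntheticConfig, gesture: str, intensity: float,
                        duration_s: float,
                        fs: float = FS_DEFAULT) -> np.ndarray:
    """Zero-mean Gaussian carrier amplitude-modulated by ``i * a_c``.

    Rectifying and low-passing the stream recovers a steady-state channel
    mean of ``i * a_c * sqrt(2/pi)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * fs))
    pattern = cfg.activation_patterns[gesture]
    carrier = rng.normal(0.0, 1.0, size=(n, N_CHANNELS))
    return carrier * (intensity * pattern)[np.newaxis, :]


def min_pattern_separation(cfg: SyntheticConfig) -> float:
    """Smallest Euclidean distance between normalized non-rest patterns.

    Reported so the separability of a stated world is explicit; rest is
    excluded (its pattern is ~0 and cannot be shape-normalized).
    """
    active = [c for c in cfg.classes if c != REST_LABEL
              and cfg.activation_patterns[c].sum() > 0]
    if len(active) < 2:
        return float("inf")
    normed = np.vstack([normalize(cfg.activation_patterns[c])
                        for c in active])
    d = pairwise_distances(normed, normed, "euclidean")
    return float(d[np.triu_indices(len(active), k=1)].min())
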