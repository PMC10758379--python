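"""Linear-envelope extraction for 8-channel surface EMG.

The amplitude feature used throughout the package is the *linear envelope*:
full-wave rectification (absolute value, window length 1) followed by a
causal second-order Butterworth low-pass with a 1 Hz cut-off, applied to
each channel independently.  At the armband's 200 Hz sample rate this
yields one 8-vector of non-negative envelope amplitudes per raw sample.

Streams are represented as ``(n_samples, 8)`` float arrays; a single frame
is an 8-vector.  The discrete filter is designed from the analog
specification by bilinear transform (``scipy.signal.butter``) and run with
zero initial conditions, matching a real-time (causal) implementation --
tests therefore probe steady-state behaviour only.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

N_CHANNELS = 8
FS_DEFAULT = 200.0  # Hz, armband maximum sample rate
FC_DEFAULT = 1.0    # Hz, envelope low-pass cut-off
ORDER_DEFAULT = 2

__all__ = [
    "N_CHANNELS",
    "FS_DEFAULT",
    "FC_DEFAULT",
    "ORDER_DEFAULT",
    "rectify",
    "butter_lowpass",
    "envelope_filter",
]


def _as_stream(x) -> np.ndarray:
    """Coerce input to an (n, 8) float array, validating channel count."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2 or arr.shape[1] != N_CHANNELS:
        raise ValueError(
            f"expected {N_CHANNELS} channels, got shape {arr.shape}"
        )
    return arr


def rectify(frames) -> np.ndarray:
    """Full-wave rectification: absolute value per channel, window length 1.

    Parameters
    ----------
    frames : array-like, shape (n, 8) or (8,)
        Raw signed EMG samples in arbitrary ADC units.

    Returns
    -------
    ndarray, shape (n, 8)
        Element-wise absolute values.
    """
    return np.abs(_as_stream(frames))


def butter_lowpass(fs: float = FS_DEFAULT, fc: float = FC_DEFAULT,
                   order: int = ORDER_DEFAULT):
    """Design the discrete envelope low-pass (Butterworth, bilinear transform).

    Returns the ``(b, a)`` transfer-function coefficients.  ``fc`` must lie
    strictly below the Nyquist frequency ``fs / 2``.
    """
    if not fc < fs / 2:
        raise ValueError(f"cut-off fc={fc} must be below Nyquist fs/2={fs / 2}")
    return signal.butter(order, fc, btype="low", fs=fs)


def envelope_filter(stream, fs: float = FS_DEFAULT, fc: float = FC_DEFAULT,
                    order: int = ORDER_DEFAULT) -> np.ndarray:
    """Rectify a raw stream and low-pass it into the linear envelope.

    Channels are filtered independently with identical coefficients,
    causally, from zero initial conditions.  Output length equals input
    length; DC gain is unity, so a constant rectified input settles to
    itself.  An empty stream yields an empty output.
    """
    arr = np.asarray(stream, dtype=float)
    if arr.size == 0:
        return np.empty((0, N_CHANNELS))
    rectified = rectify(arr)
    b, a = butter_lowpass(fs=fs, fc=fc, order=order)
    return signal.lfilter(b, a, rectified, axis=0)
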