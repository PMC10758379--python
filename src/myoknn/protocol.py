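"""Randomized target-achievement protocol and a simulated-user harness.

The online evaluation of a myocontrol method is a *target achievement
test*: the user must reach a prescribed gesture at a prescribed exertion
level and hold it within a scale margin for a dwell time before a
timeout.  A session is a randomized schedule over (gesture, level,
method, repetition) combinations, balanced so that each method and each
level appears equally often in each quarter of the session (breaks fall
at the quarter marks, and time-dependent effects must not favour one
method).  The canonical configurations are 4 gestures x 3 levels x
4 methods x 2 repetitions = 96 tasks and 6 x 3 x 3 x 2 = 108 tasks; rest
is never a trial target.

Here the subject is a :class:`SimulatedUser` that emits noisy envelope
samples of the requested gesture and level, and a *controller* is any
``sample -> (label, scale)`` callable (e.g. the proportional kNN
pipeline).  The user model never sees which method is being tested --
the double-blind surrogate.

Defaults dwell 1.5 s, timeout 10 s and scale margin 0.2 are package
choices (the criterion's shape is standard; its constants are not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .envelope import FS_DEFAULT, N_CHANNELS
from .knn import REST_LABEL
from .synthetic import SyntheticConfig

__all__ = [
    "TrialSpec",
    "TrialResult",
    "generate_schedule",
    "SimulatedUser",
    "run_trial",
    "run_study",
    "success_rate",
]

N_QUARTERS = 4  # breaks after a quarter, the half and three quarters

LEVELS_DEFAULT = (1 / 3, 2 / 3, 1.0)
METHODS_DEFAULT = ("knn", "dsm_knn", "rr", "rr_rff")


@dataclass(frozen=True)
class TrialSpec:
    """One task: hold ``gesture`` at ``level`` under ``method``."""

    gesture: str
    level: float
    method: str
    repetition: int
    slot: int = -1

    def __post_init__(self):
        if self.gesture == REST_LABEL:
            raise ValueError("rest is never a trial target")


@dataclass
class TrialResult:
    """Outcome of one trial; time_to_success present iff success."""

    spec: TrialSpec
    success: bool
    time_to_success: Optional[float] = None

    def __post_init__(self):
        if self.success != (self.time_to_success is not None):
            raise ValueError("time_to_success must be present iff success")


def generate_schedule(gestures: Sequence[str], levels: Sequence[float],
                      methods: Sequence[str], repetitions: int,
                      seed: int = 0) -> list:
    """Randomized schedule of all G*L*M*R combinations, quarter-balanced.

    Every (method, level) cell's combinations are spread round-robin over
    the four quarters (with a seeded per-cell rotation), then each
    quarter is shuffled.  When a cell's count is not divisible by four,
    exact balance is impossible; the round-robin yields the nearest
    balance and a warning is emitted.  The multiset of trials is
    independent of the seed; the order is deterministic given it.
    """
    if not (len(gestures) and len(levels) and len(methods)
            and repetitions >= 1):
        raise ValueError("all protocol counts must be >= 1")
    rng = np.random.default_rng(seed)
    cell_size = len(gestures) * repetitions
    if cell_size % N_QUARTERS != 0:
        warnings.warn(
            f"per-(method, level) count {cell_size} is not divisible by "
            f"{N_QUARTERS}; schedule relaxed to nearest-balanced",
            RuntimeWarning, stacklevel=2)
    quarters: list = [[] for _ in range(N_QUARTERS)]
    for method, level in product(methods, levels):
        combos = [(g, r) for g in gestures for r in range(repetitions)]
        rng.shuffle(combos)
        offset = int(rng.integers(N_QUARTERS))
        for j, (g, r) in enumerate(combos):
            quarters[(j + offset) % N_QUARTERS].append(
                TrialSpec(gesture=g, level=float(level), method=method,
                          repetition=r))
    schedule, slot = [], 0
    for q in quarters:
        order = rng.permutation(len(q))
        for i in order:
            s = q[i]
            schedule.append(TrialSpec(gesture=s.gesture, level=s.level,
                                      method=s.method,
                                      repetition=s.repetition, slot=slot))
            slot += 1
    return schedule


class SimulatedUser:
    """Emits noisy envelope streams for a requested (gesture, level).

    Execution noise has two parts: a per-trial intensity wobble (the user
    does not hit the level exactly) and per-sample channel noise, both
    scaled by ``execution_noise_sd``.  The interface deliberately has no
    notion of which control method is running.
    """

    def __init__(self, cfg: SyntheticConfig,
                 execution_noise_sd: float = 0.05, seed: int = 0):
        self.cfg = cfg
        self.execution_noise_sd = float(execution_noise_sd)
        self._rng = np.random.default_rng(seed)

    def stream(self, gesture: str, level: float, n_samples: int) -> np.ndarray:
        pattern = self.cfg.activation_patterns[gesture]
        wobble = 1.0 + self.execution_noise_sd * self._rng.normal()
        base = max(level * wobble, 0.0) * pattern
        x = base + self._rng.normal(0.0, self.execution_noise_sd,
                                    size=(n_samples, N_CHANNELS))
        return np.maximum(x, 0.0)


def run_trial(spec: TrialSpec, controller: Callable,
              user_model, dwell_s: float = 1.5, timeout_s: float = 10.0,
              margin: float = 0.2, fs: float = FS_DEFAULT) -> TrialResult:
    """Run one target-achievement trial sample by sample.

    Success requires the controller's ``(label, scale)`` to match
    ``(spec.gesture, spec.level)`` with ``|scale - level| <= margin``
    continuously for ``dwell_s`` seconds before ``timeout_s`` elapses.
    ``user_model`` is either a :class:`SimulatedUser` or any object with
    a ``stream(gesture, level, n) -> (n, 8)`` method.
    """
    n_total = int(round(timeout_s * fs))
    dwell_n = int(round(dwell_s * fs))
    stream = user_model.stream(spec.gesture, spec.level, n_total)
    consecutive = 0
    for t in range(n_total):
        label, scale = controller(stream[t])
        on_target = (label == spec.gesture
                     and abs(scale - spec.level) <= margin)
        consecutive = consecutive + 1 if on_target else 0
        if consecutive >= dwell_n:
            return TrialResult(spec, True, time_to_success=(t + 1) / fs)
    return TrialResult(spec, False)


def run_study(schedule: Sequence[TrialSpec],
              controllers: Dict[str, Callable], user_model,
              dwell_s: float = 1.5, timeout_s: float = 10.0,
              margin: float = 0.2, fs: float = FS_DEFAULT) -> list:
    """Run a whole schedule, dispatching each trial to its method's
    controller (``controllers`` maps method name -> controller)."""
    missing = {s.method for s in schedule} - set(controllers)
    if missing:
        raise ValueError(f"no controller for methods {sorted(missing)}")
    return [run_trial(s, controllers[s.method], user_model, dwell_s=dwell_s,
                      timeout_s=timeout_s, margin=margin, fs=fs)
            for s in schedule]


def success_rate(results: Sequence[TrialResult],
                 by: Sequence[str] = ("method",)) -> pd.DataFrame:
    """Per-facet success rates; facets with no trials are simply absent.

    ``by`` may combine ``method``, ``level`` and ``gesture``.  Returns a
    tidy frame with the facet columns plus ``successes``, ``trials`` and
    ``rate``.
    """
    valid = {"method", "level", "gesture"}
    if not set(by) <= valid:
        raise ValueError(f"facets must be among {sorted(valid)}")
    rows = [{"method": r.spec.method, "level": r.spec.level,
             "gesture": r.spec.gesture, "success": r.success}
            for r in results]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=list(by) + ["successes", "trials",
                                                "rate"])
    g = df.groupby(list(by))["success"].agg(successes="sum", trials="count")
    g["rate"] = g["successes"] / g["trials"]
    return g.reset_index()
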