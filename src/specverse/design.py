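"""Event-related task designs for the emotion-discrimination paradigm.

The emulated run presents brief (350 ms) fear and neutral face events with
jittered inter-trial intervals in a 130-volume, TR = 2 s acquisition.
Real designs of this kind are jitter-optimized with a genetic algorithm;
here ITIs are drawn from a truncated-exponential resampler targeting the
reported median ITI (default 4.93 s), because a plain uniform draw on
[3, 10] s does not fit 48 trials into a 260 s run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

CONDITIONS = ("fear", "neutral")
DEFAULT_TRIAL_DURATION = 0.35
DEFAULT_ITI_BOUNDS = (3.0, 10.0)
DEFAULT_ITI_MEDIAN = 4.93
DEFAULT_TR = 2.0
DEFAULT_N_VOLUMES = 130
_LEAD_IN = 4.0  # seconds before the first trial


class PlacementError(ValueError):
    """Raised when the requested trials cannot be placed in the run."""


@dataclass(frozen=True)
class TaskDesign:
    """One run's event table plus acquisition geometry.

    Invariants: onsets strictly increasing, every event finishes before the
    end of the run, ITIs within the configured bounds.
    """

    trial_onsets: np.ndarray = field(repr=False)
    trial_durations: np.ndarray = field(repr=False)
    trial_conditions: np.ndarray = field(repr=False)
    trial_index: np.ndarray = field(repr=False)  # 1..n within condition
    tr: float = DEFAULT_TR
    n_volumes: int = DEFAULT_N_VOLUMES

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.trial_onsets) > 0):
            raise ValueError("trial onsets must be strictly increasing")
        if np.any(self.trial_onsets + self.trial_durations >= self.run_length):
            raise ValueError("events must end before the end of the run")

    @property
    def run_length(self) -> float:
        return self.tr * self.n_volumes

    @property
    def n_trials(self) -> int:
        return self.trial_onsets.size

    def itis(self) -> np.ndarray:
        return np.diff(self.trial_onsets)

    def onsets_for(self, condition: str) -> np.ndarray:
        return self.trial_onsets[self.trial_conditions == condition]

    def events_frame(self) -> pd.DataFrame:
        """BIDS-events-style table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": self.trial_onsets,
                "duration": self.trial_durations,
                "trial_type": self.trial_conditions,
            }
        )


def _iti_scale_for_median(lo: float, hi: float, median: float) -> float:
    """Scale of an exponential truncated to [lo, hi] with the given median."""

    def med(scale: float) -> float:
        # inverse CDF at 0.5 of Exp(scale) truncated to [0, hi - lo]
        span = hi - lo
        z = 1.0 - np.exp(-span / scale)
        return lo - scale * np.log1p(-0.5 * z)

    return brentq(lambda s: med(s) - median, 1e-3, 1e3)


def _draw_itis(
    rng: np.random.Generator, n: int, bounds: tuple[float, float], median: float
) -> np.ndarray:
    lo, hi = bounds
    scale = _iti_scale_for_median(lo, hi, median)
    u = rng.uniform(size=n)
    span = hi - lo
    z = 1.0 - np.exp(-span / scale)
    return lo - scale * np.log1p(-u * z)


def generate_task_design(
    n_fear: int = 24,
    n_neutral: int = 24,
    iti_bounds: tuple[float, float] = DEFAULT_ITI_BOUNDS,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    seed: int = 0,
    trial_duration: float = DEFAULT_TRIAL_DURATION,
    iti_median: float = DEFAULT_ITI_MEDIAN,
    max_tries: int = 200,
) -> TaskDesign:
    """Generate a pseudorandomized event-related design.

    Condition order is a seeded shuffle of the fear/neutral labels; ITIs are
    resampled until the full trial train fits in the run. Identical seeds
    yield identical designs.
    """
    if n_fear < 1 or n_neutral < 1:
        raise ValueError("each condition needs at least one trial")
    lo, hi = iti_bounds
    if not (0 < lo <= hi):
        raise ValueError("invalid ITI bounds")
    n_trials = n_fear + n_neutral
    run_length = tr * n_volumes
    min_span = _LEAD_IN + (n_trials - 1) * lo + trial_duration
    if min_span >= run_length:
        raise PlacementError(
            f"cannot place {n_trials} trials at minimum ITI {lo}s "
            f"in a {run_length}s run"
        )
    rng = np.random.default_rng(seed)
    labels = np.array(["fear"] * n_fear + ["neutral"] * n_neutral)
    rng.shuffle(labels)
    median = min(iti_median, hi)
    for _ in range(max_tries):
        itis = _draw_itis(rng, n_trials - 1, iti_bounds, median)
        onsets = _LEAD_IN + np.concatenate([[0.0], np.cumsum(itis)])
        if onsets[-1] + trial_duration < run_length:
            break
    else:  # pragma: no cover - astronomically unlikely with default geometry
        raise PlacementError("could not fit trial train in run after resampling")
    trial_index = np.zeros(n_trials, dtype=int)
    for cond in CONDITIONS:
        mask = labels == cond
        trial_index[mask] = np.arange(1, mask.sum() + 1)
    return TaskDesign(
        trial_onsets=onsets,
        trial_durations=np.full(n_trials, trial_duration),
        trial_conditions=labels,
        trial_index=trial_index,
        tr=tr,
        n_volumes=n_volumes,
    )
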