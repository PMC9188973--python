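"""Hemodynamic response functions and event-to-BOLD convolution.

The canonical double-gamma HRF is the difference of two gamma densities
(response peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6);
the single-gamma variant keeps only the positive lobe. Regressors are
built on a fine time grid (default 0.1 s) so that sub-TR event durations
(350 ms face presentations) are represented, then sampled at volume
acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

HRF_SUPPORT = 32.0  # seconds of kernel support

# shape parameters of the two gamma lobes (scale fixed at 1 s):
# a density with shape k and scale 1 peaks at k - 1 seconds.
_PEAK_SHAPE = 7.0  # response peak at 6 s
_UNDERSHOOT_SHAPE = 17.0  # undershoot peak at 16 s
_UNDERSHOOT_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class HRFKernel:
    """A sampled HRF kernel on a regular grid of spacing ``dt``."""

    kind: str
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values[0] != 0.0:
            raise ValueError("HRF kernel must start at 0 at t=0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def make_hrf(kind: str = "double_gamma", dt: float = 0.1) -> HRFKernel:
    """Build an HRF kernel.

    Parameters
    ----------
    kind:
        ``"double_gamma"`` (difference of two gamma densities) or
        ``"single_gamma"`` (positive lobe only).
    dt:
        Sampling interval of the kernel in seconds; must be positive.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_SUPPORT + dt / 2, dt)
    peak = gamma_dist.pdf(t, _PEAK_SHAPE, scale=1.0)
    if kind == "double_gamma":
        under = gamma_dist.pdf(t, _UNDERSHOOT_SHAPE, scale=1.0)
        values = peak - _UNDERSHOOT_RATIO * under
    elif kind == "single_gamma":
        values = peak
    else:
        raise ValueError(f"unknown HRF kind: {kind!r}")
    # normalize to unit peak so regression betas are on the amplitude scale
    values = values / values.max()
    values[0] = 0.0
    return HRFKernel(kind=kind, dt=dt, values=values)


def impulse_train(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    run_length: float,
    dt: float = 0.1,
) -> np.ndarray:
    """Amplitude-weighted boxcar train on the fine grid."""
    n = int(np.ceil(run_length / dt))
    train = np.zeros(n)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        train[i0 : min(i1, n)] += amp
    return train


def convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    hrf: HRFKernel,
    tr: float,
    n_volumes: int,
) -> np.ndarray:
    """Convolve an amplitude-weighted event train with the HRF and sample
    at volume acquisition times (t = 0, TR, 2 TR, ...)."""
    run_length = tr * n_volumes
    train = impulse_train(onsets, durations, amplitudes, run_length, hrf.dt)
    full = np.convolve(train, hrf.values)[: train.size]
    step = tr / hrf.dt
    idx = np.round(np.arange(n_volumes) * step).astype(int)
    return full[idx]


def convolve_series(series: np.ndarray, hrf_tr: np.ndarray) -> np.ndarray:
    """Causal convolution of a volume-grid series with a TR-sampled kernel."""
    return np.convolve(series, hrf_tr)[: series.size]


def hrf_at_tr(hrf: HRFKernel, tr: float) -> np.ndarray:
    """Resample a fine-grid kernel at the TR grid (used by deconvolution
    and neural-level interaction construction)."""
    step = tr / hrf.dt
    n = int(np.floor((hrf.values.size - 1) / step)) + 1
    idx = np.round(np.arange(n) * step).astype(int)
    return hrf.values[idx]
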