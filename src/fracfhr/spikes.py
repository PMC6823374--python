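"""Spike detection and qualitative regime classification for voltage traces.

The model papers over a precise operational spike definition, so the
defaults here are deliberately generous: spikes in these units have
amplitude ~2 around a sub-threshold baseline near -1, and any threshold
well inside (0.3, 0.7) detects the same events.  A spike is an upward
threshold crossing; crossings closer together than a refractory minimum are
merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .solver import Trajectory
from .stability import equilibrium

__all__ = [
    "SpikeTrain",
    "RegimeLabel",
    "detect_spikes",
    "spike_times_from_series",
    "first_spike_latency",
    "firing_rate",
    "classify_regime",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_REFRACTORY = 2.0  # ms


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) with the detection settings used."""

    spike_times: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    refractory_min: float = DEFAULT_REFRACTORY

    def __len__(self) -> int:
        return self.spike_times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class RegimeLabel:
    """Qualitative firing-regime label with its supporting diagnostics.

    quiescent      - no post-transient spikes and the tail hugs the fixed point
    tonic_spiking  - spikes at roughly regular inter-spike intervals
    bursting       - groups of spikes separated by long silent gaps
    mixed_mode     - spikes interleaved with sub-threshold oscillations
    """

    label: str
    n_spikes: int
    isi_cv: float
    tail_amplitude: float
    terminal_drift: float


def spike_times_from_series(
    times: np.ndarray,
    v: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_min: float = DEFAULT_REFRACTORY,
) -> np.ndarray:
    """Upward crossings of ``threshold``, merged within ``refractory_min`` ms."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    idx = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    out = []
    last = -np.inf
    for i in idx:
        t = times[i + 1]
        if t - last >= refractory_min:
            out.append(t)
            last = t
    return np.asarray(out)


def detect_spikes(
    traj: Trajectory,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_min: float = DEFAULT_REFRACTORY,
) -> SpikeTrain:
    st = spike_times_from_series(traj.times, traj.v, threshold, refractory_min)
    return SpikeTrain(spike_times=st, threshold=threshold, refractory_min=refractory_min)


def first_spike_latency(train: SpikeTrain) -> float | None:
    """Time of the first spike (stimulus onset is t = 0); None if silent."""
    if len(train) == 0:
        return None
    return float(train.spike_times[0])


def firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spikes per second within [t0, t1] (times in ms)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive duration")
    n = int(np.count_nonzero((train.spike_times >= t0) & (train.spike_times <= t1)))
    return n / ((t1 - t0) / 1000.0)


def classify_regime(
    traj: Trajectory,
    params=None,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_min: float = DEFAULT_REFRACTORY,
    transient_fraction: float = 0.5,
    quiescent_amplitude: float = 0.1,
    burst_gap_factor: float = 5.0,
) -> RegimeLabel:
    """Label the firing regime of a voltage trace.

    Quiescence means no spikes after the transient AND a tail peak-to-peak
    amplitude below ``quiescent_amplitude`` (spiral decay toward the fixed
    point counts as quiescent).  Bursting is flagged when the inter-spike
    intervals are strongly bimodal (some gap exceeds ``burst_gap_factor``
    times the median interval); mixed-mode when prominent sub-threshold
    oscillations separate full spikes.  These labels are qualitative
    diagnostics, not acceptance-grade quantities.
    """
    start = int(transient_fraction * len(traj))
    t_tail, v_tail = traj.times[start:], traj.v[start:]
    spikes_tail = spike_times_from_series(t_tail, v_tail, threshold, refractory_min)
    tail_amp = float(v_tail.max() - v_tail.min())

    drift = np.nan
    if params is not None:
        drift = float(abs(traj.v[-1] - equilibrium(params).v_star))

    train = detect_spikes(traj, threshold, refractory_min)
    n_spikes = len(train)
    isis = train.isis
    isi_cv = float(np.std(isis) / np.mean(isis)) if isis.size >= 2 else np.nan

    if spikes_tail.size == 0 and tail_amp < quiescent_amplitude:
        label = "quiescent"
    elif isis.size >= 2 and np.max(isis) > burst_gap_factor * np.median(isis):
        label = "bursting"
    else:
        # sub-threshold oscillation check: prominent local maxima below threshold
        sub_peaks, _ = find_peaks(v_tail, prominence=0.1)
        sub_peaks = [i for i in sub_peaks if v_tail[i] < threshold]
        label = "mixed_mode" if (spikes_tail.size > 0 and len(sub_peaks) > 0) else "tonic_spiking"
        if spikes_tail.size == 0:
            # oscillating but never crossing threshold: still not quiescent
            label = "mixed_mode" if len(sub_peaks) > 0 else "quiescent"

    return RegimeLabel(
        label=label,
        n_spikes=n_spikes,
        isi_cv=isi_cv,
        tail_amplitude=tail_amp,
        terminal_drift=drift,
    )
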