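"""Response-variable extraction from simulation traces.

Three response variables summarise a simulation:

* ``Z_spike`` -- mean spike rate per neuron, spikes/min;
* ``Z_burst`` -- mean burst rate per neuron, bursts/min, with bursts found
  by a cumulative-moving-average (CMA) analysis of the inter-spike-interval
  (ISI) histogram;
* ``Z_astro`` -- mean number of activations per astrocyte over the whole
  simulation (rising edges of the active flag).

The CMA burst detector works per neuron: the ISI histogram is scanned with
a cumulative moving average; the skewness of the CMA sequence selects a
fraction alpha of the CMA peak, and the last bin (at or after the peak)
whose CMA still exceeds alpha times the peak sets the burst ISI threshold.
Maximal runs of consecutive ISIs at or below the threshold containing at
least ``min_spikes`` spikes are bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import SimTrace

__all__ = [
    "Burst",
    "CmaParams",
    "detect_bursts_cma",
    "mean_spike_rate",
    "mean_burst_rate",
    "astro_activation_count",
    "response_record",
]

#: skewness -> alpha lookup: (upper skewness bound, alpha)
DEFAULT_ALPHA_TABLE = ((1.0, 1.0), (4.0, 0.7), (9.0, 0.5), (np.inf, 0.3))


@dataclass(frozen=True)
class CmaParams:
    bin_width: float = 0.005          # ISI histogram bin width, s
    min_spikes: int = 3               # minimum spikes per burst
    alpha_table: tuple = DEFAULT_ALPHA_TABLE


@dataclass(frozen=True)
class Burst:
    start: float      # s, first spike
    end: float        # s, last spike
    n_spikes: int


def _alpha_from_skewness(skew: float, table) -> float:
    for bound, alpha in table:
        if skew < bound:
            return alpha
    return table[-1][1]


def detect_bursts_cma(spike_times, params: CmaParams = CmaParams()) -> list[Burst]:
    """CMA burst detection on one sorted spike train (times in seconds)."""
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be non-decreasing")
    if t.size < params.min_spikes + 1:
        return []

    isi = np.diff(t)
    max_isi = isi.max()
    if max_isi <= 0:
        # degenerate train of coincident spikes: one burst
        return [Burst(float(t[0]), float(t[-1]), int(t.size))]

    n_bins = max(1, int(np.ceil(2.0 * max_isi / params.bin_width)))
    # left-closed bins of width bin_width; an ISI on the top edge folds into
    # the last bin
    idx = np.minimum((isi / params.bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)

    cma = np.cumsum(counts) / np.arange(1, n_bins + 1)
    m = int(np.argmax(cma))  # first peak on ties
    skew = float(stats.skew(cma)) if cma.size > 1 else 0.0
    alpha = _alpha_from_skewness(skew, params.alpha_table)

    above = np.nonzero(cma[m:] >= alpha * cma[m])[0]
    k_last = m + int(above[-1])
    threshold = (k_last + 1) * params.bin_width  # upper edge of that bin

    bursts: list[Burst] = []
    run_start = 0  # index into spike array of current run's first spike
    for j in range(isi.size + 1):
        end_of_run = j == isi.size or isi[j] > threshold
        if end_of_run:
            n_run = j - run_start + 1
            if n_run >= params.min_spikes:
                bursts.append(Burst(float(t[run_start]), float(t[j]), int(n_run)))
            run_start = j + 1
    return bursts


def mean_spike_rate(trace: SimTrace) -> float:
    """Mean spike rate across neurons, spikes per minute."""
    if trace.n_neurons == 0:
        raise ValueError("trace has no neurons")
    total = float(trace.raster.sum())
    return total / trace.n_neurons / trace.duration_min


def mean_burst_rate(trace: SimTrace, params: CmaParams = CmaParams()) -> float:
    """Mean burst rate across neurons, bursts per minute."""
    if trace.n_neurons == 0:
        raise ValueError("trace has no neurons")
    n_bursts = 0
    for i in range(trace.n_neurons):
        n_bursts += len(detect_bursts_cma(trace.spike_times(i), params))
    return n_bursts / trace.n_neurons / trace.duration_min


def activation_counts(active: np.ndarray) -> np.ndarray:
    """Rising edges per astrocyte from a (steps, M) active-flag matrix."""
    if active.shape[1] == 0:
        return np.zeros(0)
    flags = active.astype(np.int8)
    rises = np.diff(flags, axis=0, prepend=np.zeros((1, flags.shape[1]), np.int8)) > 0
    return rises.sum(axis=0).astype(float)


def astro_activation_count(trace: SimTrace) -> float:
    """Mean number of activations per astrocyte over the simulation."""
    if trace.n_astro == 0:
        warnings.warn("trace has no astrocytes; activation count is 0")
        return 0.0
    return float(activation_counts(trace.active).mean())


def response_record(trace: SimTrace, cma: CmaParams = CmaParams(), **metadata) -> dict:
    """The three response variables plus caller-supplied metadata."""
    rec = {
        "Z_spike": mean_spike_rate(trace),
        "Z_burst": mean_burst_rate(trace, cma),
        "Z_astro": astro_activation_count(trace) if trace.n_astro else 0.0,
    }
    rec.update(metadata)
    return rec
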