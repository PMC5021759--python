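"""Multi-electrode-array spike detection, binning and baseline normalization.

Spikes are detected per electrode as excursions beyond k standard
deviations of the noise (k = 5 by default), with the noise SD estimated
robustly from the median absolute deviation so the spikes themselves do
not inflate the threshold.  Detection is negative-going by default
(extracellular somatic spikes), with configurable polarity, and a 1 ms
lockout collapses each excursion to its peak sample.

Spike times are summed into 1 s bins, split into 5 min chunks, and
array-wide densities are normalized to the recording's own baseline
epoch, giving fold changes / percent increases in spontaneous activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAD_TO_SD = 0.6745  # Phi^-1(0.75): MAD of a Gaussian in SD units


class FlatTraceError(RuntimeError):
    """Raised when a trace has no estimable noise (SD = 0)."""


def noise_sd(samples):
    """Robust noise SD via the median absolute deviation."""
    samples = np.asarray(samples, dtype=float)
    sd = np.median(np.abs(samples - np.median(samples))) / MAD_TO_SD
    if sd == 0:
        raise FlatTraceError("flat trace: noise SD is zero")
    return float(sd)


def detect_spikes(samples, fs_hz, k=5.0, refractory_s=0.001, polarity=-1):
    """Threshold detector: excursions beyond k*SD with a refractory lockout.

    Returns spike times (s) at the peak sample of each excursion.
    ``polarity`` -1 detects negative-going spikes, +1 positive-going.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < fs_hz:
        raise ValueError("need at least 1 s of signal to estimate noise")
    sd = noise_sd(samples)
    sig = samples * polarity  # spikes now positive-going
    above = np.flatnonzero(sig > k * sd)
    if len(above) == 0:
        return np.empty(0)
    lock = max(1, int(round(refractory_s * fs_hz)))
    # split threshold excursions wherever the gap exceeds the lockout
    splits = np.flatnonzero(np.diff(above) > lock) + 1
    peaks = [
        grp[np.argmax(sig[grp])] for grp in np.split(above, splits)
    ]
    return np.asarray(peaks, dtype=float) / fs_hz


@dataclass
class BinnedActivity:
    """1 s-binned spike counts split into 5 min chunks."""

    bins: np.ndarray          # per-second total counts, array-wide or per electrode
    chunk_len_s: int = 300

    @property
    def chunks(self):
        n = len(self.bins) // self.chunk_len_s
        usable = self.bins[: n * self.chunk_len_s]
        return usable.reshape(n, self.chunk_len_s) if n else usable.reshape(0, 0)

    @property
    def total(self):
        return int(self.bins.sum())


def bin_and_chunk(spike_times_s, duration_s, bin_s=1.0, chunk_len_s=300):
    """Sum spike times into fixed bins and group bins into chunks."""
    spike_times_s = np.asarray(spike_times_s, dtype=float)
    n_bins = int(np.ceil(duration_s / bin_s))
    counts, _ = np.histogram(spike_times_s, bins=n_bins, range=(0, n_bins * bin_s))
    return BinnedActivity(bins=counts, chunk_len_s=int(chunk_len_s))


def array_spike_density(per_electrode_times, duration_s):
    """Array-wide spike rate (spikes/s summed over electrodes)."""
    total = sum(len(t) for t in per_electrode_times)
    return total / duration_s


def normalize_to_baseline(epoch_densities, baseline_key="baseline"):
    """Fold changes and percent increases relative to the baseline epoch.

    ``epoch_densities`` maps epoch label -> array-wide spike density.
    The baseline fold change is 1 by construction; a zero baseline is
    flagged as undefined (NaN folds) rather than raising.
    """
    base = epoch_densities[baseline_key]
    out = {}
    for label, dens in epoch_densities.items():
        if base == 0:
            fold = np.nan
        else:
            fold = dens / base
        out[label] = {
            "density_hz": dens,
            "fold_change": fold,
            "percent_increase": 100.0 * (fold - 1.0) if np.isfinite(fold) else np.nan,
        }
    return out


def analyze_trace_set(trace_set, k=5.0, baseline_index=0):
    """End-to-end: detect on every (epoch, electrode), bin, normalize.

    ``trace_set`` is an object exposing ``spec`` (with epoch labels,
    duration, sampling rate, electrode count) and ``trace(epoch,
    electrode)``; traces are rendered one at a time so a full array
    recording never resides in memory.

    Returns (summary dict from :func:`normalize_to_baseline`, per-epoch
    detected spike counts frame).
    """
    spec = trace_set.spec
    densities = {}
    rows = []
    for ei, label in enumerate(spec.epoch_labels):
        per_el = []
        for el in range(spec.n_electrodes):
            times = detect_spikes(trace_set.trace(ei, el), spec.fs_hz, k=k)
            per_el.append(times)
            rows.append({"epoch": label, "electrode": el, "n_spikes": len(times)})
        densities[label] = array_spike_density(per_el, spec.epoch_duration_s)
    baseline_label = spec.epoch_labels[baseline_index]
    summary = normalize_to_baseline(densities, baseline_key=baseline_label)
    return summary, pd.DataFrame(rows)
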