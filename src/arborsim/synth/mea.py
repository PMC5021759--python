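"""Synthetic multi-electrode-array voltage traces.

Emulates a 64-electrode array sampled at 12.5 kHz recording a cultured
network across treatment epochs (baseline, 2 h, 12 h).  Each electrode
carries Poisson-timed extracellular spikes (a fixed biphasic waveform,
negative-going) embedded in Gaussian noise; the per-epoch firing rates
are the study conditions, e.g. a 6.34x baseline-to-12 h ratio for the
treated culture versus 1.32x for controls.

Traces are generated lazily per (epoch, electrode) from spawned seeds,
so a full array never needs to be held in memory at once; the true
spike-time table is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def default_waveform(fs_hz=12500.0):
    """Biphasic extracellular spike template, ~1.6 ms, unit negative peak."""
    t = np.arange(0, 0.0016, 1.0 / fs_hz)
    w = -np.exp(-((t - 0.0004) ** 2) / (2 * 0.00012**2)) + 0.35 * np.exp(
        -((t - 0.0009) ** 2) / (2 * 0.00025**2)
    )
    return w / np.abs(w.min())


@dataclass
class MEATraceSpec:
    """Study conditions for one synthetic MEA recording."""

    n_electrodes: int = 64
    fs_hz: float = 12500.0
    epoch_rates_hz: tuple = (2.0, 4.04, 12.68)   # per-electrode mean rates
    epoch_labels: tuple = ("baseline", "2h", "12h")
    epoch_duration_s: float = 90.0
    spike_amplitude: float = 8.0                 # in units of noise SD
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self):
        if any(r < 0 for r in self.epoch_rates_hz):
            raise ValueError("epoch rates must be non-negative")
        if self.epoch_duration_s <= 0:
            raise ValueError("epoch durations must be positive")
        wf = default_waveform(self.fs_hz)
        if len(wf) >= self.epoch_duration_s * self.fs_hz:
            raise ValueError("spike waveform longer than the epoch")
        if len(wf) < 4:
            raise ValueError("sampling rate too low for the spike waveform")
        return self


class ElectrodeTraceSet:
    """Lazily rendered synthetic MEA recording.

    ``trace(epoch_index, electrode)`` synthesizes one electrode's epoch
    deterministically; ``true_spikes`` lists every embedded spike
    (epoch, electrode, time_s).
    """

    def __init__(self, spec: MEATraceSpec):
        self.spec = spec.validate()
        self.waveform = default_waveform(spec.fs_hz) * (
            spec.spike_amplitude * spec.noise_sd
        )
        root = np.random.SeedSequence(spec.seed)
        n_ep = len(spec.epoch_rates_hz)
        self._seeds = np.reshape(
            root.spawn(n_ep * spec.n_electrodes), (n_ep, spec.n_electrodes)
        )
        rows = []
        for ei, rate in enumerate(spec.epoch_rates_hz):
            for el in range(spec.n_electrodes):
                times = self._spike_times(ei, el)
                for t in times:
                    rows.append((spec.epoch_labels[ei], el, t))
        self.true_spikes = pd.DataFrame(
            rows, columns=["epoch", "electrode", "time_s"]
        )

    def _rng(self, epoch_index, electrode, stream):
        ss = self._seeds[epoch_index][electrode]
        return np.random.default_rng(ss.spawn(2)[stream])

    def _spike_times(self, epoch_index, electrode):
        spec = self.spec
        rng = self._rng(epoch_index, electrode, 0)
        rate = spec.epoch_rates_hz[epoch_index]
        n = rng.poisson(rate * spec.epoch_duration_s)
        wf_s = len(self.waveform) / spec.fs_hz
        return np.sort(rng.uniform(0, spec.epoch_duration_s - wf_s, size=n))

    def trace(self, epoch_index, electrode):
        """Synthesize one electrode's voltage samples for one epoch."""
        spec = self.spec
        n_samp = int(round(spec.epoch_duration_s * spec.fs_hz))
        rng = self._rng(epoch_index, electrode, 1)
        v = rng.normal(0.0, spec.noise_sd, size=n_samp)
        for t in self._spike_times(epoch_index, electrode):
            i0 = int(round(t * spec.fs_hz))
            v[i0 : i0 + len(self.waveform)] += self.waveform[: n_samp - i0]
        return v

    def true_rate_ratio(self, epoch_index, baseline_index=0):
        """Array-wide embedded-spike rate ratio between two epochs."""
        lab = self.spec.epoch_labels
        counts = self.true_spikes.groupby("epoch")["time_s"].count()
        base = counts.get(lab[baseline_index], 0)
        if base == 0:
            raise ZeroDivisionError("no baseline spikes")
        return counts.get(lab[epoch_index], 0) / base


def generate_mea_traces(spec: MEATraceSpec):
    """Build the lazily rendered trace set (deterministic per seed)."""
    return ElectrodeTraceSet(spec)
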