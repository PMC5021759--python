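"""Annulus-profile containers and their tab-separated interchange format.

An :class:`AnnulusProfile` records, for one 6.25 um shell of one neuron,
the dendrite length, Sholl crossings, dye-fill volume, excitatory and
inhibitory puncta counts and their intensity spectra.  Nine profiles
make a :class:`NeuronMorphology`, the object exchanged between the
imaging side and the simulator side of the pipeline.

Intensity spectra are stored as counts at 16 discrete conductance
levels, 0.25 nS apart from 0.25 to 4.00 nS.  Normalized intensities
(AFU) map one-to-one onto conductance (1 AFU = 1 nS) and are rounded to
the nearest level, clipping at the 0.25 / 4 nS floor and cap under
which ~99% of normalized intensities fall.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ANNULUS_WIDTH_UM, N_ANNULI

#: Discrete conductance levels (nS) shared by intensity spectra and synapses.
CONDUCTANCE_LEVELS = np.round(np.arange(1, 17) * 0.25, 2)
N_LEVELS = len(CONDUCTANCE_LEVELS)


def afu_to_level(afu):
    """Index of the nearest conductance level for an AFU value (clipped)."""
    idx = np.round(np.asarray(afu, dtype=float) / 0.25).astype(int)
    return np.clip(idx, 1, N_LEVELS) - 1


@dataclass
class NeuronMorphology:
    """Per-annulus morphology and synapse distribution of one neuron.

    All arrays are indexed by annulus (length ``N_ANNULI``); histograms
    are (annulus, level).  Annulus 0 is the soma shell.
    """

    neuron_id: str
    group: str = ""
    length_um: np.ndarray = field(default_factory=lambda: np.zeros(N_ANNULI))
    crossings: np.ndarray = field(default_factory=lambda: np.zeros(N_ANNULI, int))
    volume_um3: np.ndarray = field(default_factory=lambda: np.zeros(N_ANNULI))
    e_hist: np.ndarray = field(
        default_factory=lambda: np.zeros((N_ANNULI, N_LEVELS), int)
    )
    i_hist: np.ndarray = field(
        default_factory=lambda: np.zeros((N_ANNULI, N_LEVELS), int)
    )

    # -- derived totals ----------------------------------------------------
    @property
    def e_counts(self):
        return self.e_hist.sum(axis=1)

    @property
    def i_counts(self):
        return self.i_hist.sum(axis=1)

    @property
    def total_length_um(self):
        """Total dendrite length: annuli 1..8 (annulus 0 is the soma)."""
        return float(self.length_um[1:].sum())

    @property
    def total_crossings(self):
        return int(self.crossings[1:].sum())

    @property
    def total_e(self):
        return int(self.e_hist.sum())

    @property
    def total_i(self):
        return int(self.i_hist.sum())

    @property
    def total_synapses(self):
        return self.total_e + self.total_i

    def densities_per_um(self):
        """E and I puncta per um of dendrite, per annulus (NaN where no length)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            de = np.where(self.length_um > 0, self.e_counts / self.length_um, np.nan)
            di = np.where(self.length_um > 0, self.i_counts / self.length_um, np.nan)
        return de, di

    def validate(self):
        for name in ("length_um", "volume_um3"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.crossings < 0) or np.any(self.e_hist < 0) or np.any(self.i_hist < 0):
            raise ValueError("counts must be non-negative")
        return self


# ---------------------------------------------------------------------------
# TSV interchange

_HIST_COLS_E = [f"e_ns_{lv:.2f}" for lv in CONDUCTANCE_LEVELS]
_HIST_COLS_I = [f"i_ns_{lv:.2f}" for lv in CONDUCTANCE_LEVELS]


def profiles_to_frame(neurons):
    """One row per (neuron, annulus); histogram levels as wide columns."""
    rows = []
    for n in neurons:
        for k in range(N_ANNULI):
            row = {
                "neuron": n.neuron_id,
                "group": n.group,
                "annulus": k,
                "inner_radius_um": k * ANNULUS_WIDTH_UM,
                "length_um": n.length_um[k],
                "crossings": int(n.crossings[k]),
                "volume_um3": n.volume_um3[k],
                "e_count": int(n.e_hist[k].sum()),
                "i_count": int(n.i_hist[k].sum()),
            }
            row.update({c: int(v) for c, v in zip(_HIST_COLS_E, n.e_hist[k])})
            row.update({c: int(v) for c, v in zip(_HIST_COLS_I, n.i_hist[k])})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df):
    """Inverse of :func:`profiles_to_frame`."""
    out = []
    for nid, sub in df.groupby("neuron", sort=False):
        sub = sub.sort_values("annulus")
        m = NeuronMorphology(
            neuron_id=str(nid),
            group=str(sub["group"].iloc[0]),
            length_um=sub["length_um"].to_numpy(float),
            crossings=sub["crossings"].to_numpy(int),
            volume_um3=sub["volume_um3"].to_numpy(float),
            e_hist=sub[_HIST_COLS_E].to_numpy(int),
            i_hist=sub[_HIST_COLS_I].to_numpy(int),
        )
        out.append(m.validate())
    return out


def write_profiles(path, neurons, header_comment=None):
    df = profiles_to_frame(neurons)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_profiles(path):
    df = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_profiles(df)
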