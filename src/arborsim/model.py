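"""Morphologically constrained multi-compartment model construction.

An annulus profile is converted into a compartment chain under the
topology scheme: every Sholl crossing in annulus k becomes one
dendritic compartment of length 6.25 um attached (round-robin) to a
parent compartment in annulus k-1; the annulus-0 compartment is the
soma; an identical axon (100 um x 1 um) and apical dendrite (250 um by
default, swept) attach to the soma.  Compartment diameters invert the
cylinder volume relation d = 2*sqrt(V'/(pi*6.25)) with V' the annulus
dye-fill volume split across that annulus's compartments, so modeled
dendritic volume per annulus equals the measured volume exactly.  A
config switch restores the literal total-volume reading.

Synapses: total count per annulus is the sum of excitatory and
inhibitory punctae, the E/I split is the punctae ratio, and peak
conductance maps 1 AFU -> 1 nS, clipped to [0.25, 4] nS.  The model
stores the (annulus, type, conductance-level) weight table; placement
onto compartments is uniform and happens at stimulus-draw time.

Spatial discretization follows the d-lambda rule: nseg is the smallest
odd integer >= L / (0.1 * lambda_100), with lambda_100 the 100 Hz AC
length constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ANNULUS_WIDTH_UM, N_ANNULI
from .profiles import CONDUCTANCE_LEVELS, N_LEVELS, NeuronMorphology

COMPARTMENT_LENGTH_UM = ANNULUS_WIDTH_UM
AXON_LENGTH_UM, AXON_DIAM_UM = 100.0, 1.0
DEFAULT_APICAL_LENGTH_UM = 250.0
APICAL_DIAM_UM = 2.0
CONDUCTANCE_FLOOR_NS, CONDUCTANCE_CAP_NS = 0.25, 4.0
MIN_DIAM_UM = 0.2  # floor for degenerate (near-zero-volume) annuli


class TopologyError(ValueError):
    """Raised for inconsistent profiles (e.g. orphan annuli)."""


@dataclass
class Compartment:
    id: int
    role: str                   # soma | dendrite | apical | axon
    annulus: int                # -1 for axon/apical
    length_um: float
    diam_um: float
    parent: int                 # -1 for the soma
    nseg: int = 1


@dataclass
class ModelNeuron:
    """Compartment chain plus the synapse weight table.

    ``synapse_counts[annulus, type, level]`` holds integer punctae
    counts (type 0 = excitatory, 1 = inhibitory; levels are the shared
    0.25-4 nS grid).
    """

    neuron_id: str
    group: str
    compartments: list
    synapse_counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_ANNULI, 2, N_LEVELS), dtype=int)
    )

    @property
    def total_synapses(self):
        return int(self.synapse_counts.sum())

    @property
    def annulus_fractions(self):
        tot = self.synapse_counts.sum()
        per = self.synapse_counts.sum(axis=(1, 2))
        return per / tot if tot else per.astype(float)

    def e_fraction(self, annulus):
        per = self.synapse_counts[annulus].sum(axis=1)
        tot = per.sum()
        return per[0] / tot if tot else np.nan

    def dendrites_in_annulus(self, k):
        return [c for c in self.compartments if c.role == "dendrite" and c.annulus == k]

    @property
    def soma(self):
        return self.compartments[0]


def _cyl_diam(volume_um3, length_um):
    return 2.0 * np.sqrt(max(volume_um3, 0.0) / (np.pi * length_um))


def build_topology(profile: NeuronMorphology, apical_length_um=DEFAULT_APICAL_LENGTH_UM,
                   split_volume=True):
    """Construct the compartment chain for one annulus profile.

    ``split_volume=True`` divides each annulus's dye-fill volume across
    its compartments before the cylinder inversion (volume conserving);
    False applies the inversion to the total annulus volume.

    Raises :class:`TopologyError` when crossings appear in an annulus
    whose inner neighbor has none.
    """
    cr = np.asarray(profile.crossings, dtype=int)
    occ = np.flatnonzero(cr[1:]) + 1
    for k in occ:
        if k > 1 and cr[k - 1] == 0:
            raise TopologyError(
                f"orphan branch: annulus {k} has crossings but annulus {k-1} has none"
            )

    comps = []
    soma_d = _cyl_diam(profile.volume_um3[0], COMPARTMENT_LENGTH_UM)
    soma_d = max(soma_d, 1.0)
    comps.append(Compartment(0, "soma", 0, COMPARTMENT_LENGTH_UM, soma_d, -1))

    prev_ids = [0]
    for k in range(1, N_ANNULI):
        n_k = int(cr[k])
        if n_k == 0:
            break
        vol_each = profile.volume_um3[k] / n_k if split_volume else profile.volume_um3[k]
        d = max(_cyl_diam(vol_each, COMPARTMENT_LENGTH_UM), MIN_DIAM_UM)
        ids_here = []
        for j in range(n_k):
            cid = len(comps)
            parent = prev_ids[j % len(prev_ids)]  # round-robin attachment
            comps.append(
                Compartment(cid, "dendrite", k, COMPARTMENT_LENGTH_UM, d, parent)
            )
            ids_here.append(cid)
        prev_ids = ids_here

    comps.append(
        Compartment(len(comps), "axon", -1, AXON_LENGTH_UM, AXON_DIAM_UM, 0)
    )
    comps.append(
        Compartment(len(comps), "apical", -1, float(apical_length_um),
                    APICAL_DIAM_UM, 0)
    )
    return ModelNeuron(
        neuron_id=profile.neuron_id, group=profile.group, compartments=comps
    )


def lambda_100(diam_um, ra_ohm_cm, cm_uf_cm2, freq_hz=100.0):
    """AC length constant at ``freq_hz`` in um (NEURON's lambda_f)."""
    return 1e5 * np.sqrt(diam_um / (4 * np.pi * freq_hz * ra_ohm_cm * cm_uf_cm2))


def assign_nseg(model: ModelNeuron, ra_ohm_cm, cm_uf_cm2, d_lambda=0.1):
    """Set each compartment's segment count by the d-lambda rule.

    nseg is the smallest odd integer >= L / (d_lambda * lambda_100).
    """
    if ra_ohm_cm <= 0 or cm_uf_cm2 <= 0:
        raise ValueError("axial resistivity and capacitance must be positive")
    for c in model.compartments:
        lam = lambda_100(c.diam_um, ra_ohm_cm, cm_uf_cm2)
        n = int(np.ceil(c.length_um / (d_lambda * lam)))
        c.nseg = max(1, n + (1 - n % 2))
    return model


def map_synapses(model: ModelNeuron, profile: NeuronMorphology):
    """Attach the profile's synapse weight table to the model.

    Counts in annuli with no dendritic compartment (and no soma match)
    are reassigned to the nearest inner annulus that has one, so every
    recorded punctum can be placed.
    """
    if profile.neuron_id != model.neuron_id:
        raise TopologyError("profile / topology neuron mismatch")
    counts = np.zeros((N_ANNULI, 2, N_LEVELS), dtype=int)
    counts[:, 0, :] = profile.e_hist
    counts[:, 1, :] = profile.i_hist

    have = {0}
    for c in model.compartments:
        if c.role == "dendrite":
            have.add(c.annulus)
    for k in range(N_ANNULI - 1, -1, -1):
        if k not in have and counts[k].any():
            dest = max(j for j in have if j <= k)
            counts[dest] += counts[k]
            counts[k] = 0
    model.synapse_counts = counts
    return model


def build_model(profile, apical_length_um=DEFAULT_APICAL_LENGTH_UM,
                ra_ohm_cm=150.0, cm_uf_cm2=1.0, d_lambda=0.1, split_volume=True):
    """Topology + nseg + synapse table in one call."""
    m = build_topology(profile, apical_length_um, split_volume=split_volume)
    assign_nseg(m, ra_ohm_cm, cm_uf_cm2, d_lambda)
    return map_synapses(m, profile)


def conductance_ns(level_index):
    """Peak conductance for a level index, clipped to the 0.25-4 nS range."""
    return float(
        np.clip(CONDUCTANCE_LEVELS[level_index], CONDUCTANCE_FLOOR_NS,
                CONDUCTANCE_CAP_NS)
    )
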