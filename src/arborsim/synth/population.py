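"""Synthetic neuron populations: direct annulus profiles and rendered phantoms.

Two ways to obtain +/- treatment populations:

* :func:`generate_population` draws 9-annulus profiles directly (no
  imaging), for simulator-side work where rendering is irrelevant.
  Group contrasts are configured as multipliers on dendrite length,
  complexity (crossings), puncta counts and inhibitory-marker
  intensity, defaulting to the effect sizes the pipeline is built to
  resolve: x1.24 length, x1.30 complexity, balanced E/I addition and
  elevated inhibitory intensity.

* :func:`sample_phantom_population` draws per-neuron phantom specs for
  the rendered-imaging benchmark.  Between-neuron dispersion defaults
  to a tight 5% CV there: the phantom benchmark isolates pipeline
  measurement error rather than biological variability.

Per-neuron excitatory and inhibitory totals share a common size factor,
so I totals scale linearly with E totals across a population with a
configurable slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..geometry import ANNULUS_WIDTH_UM, N_ANNULI
from ..profiles import CONDUCTANCE_LEVELS, N_LEVELS, NeuronMorphology, afu_to_level
from .phantom import (
    PhantomSpec,
    add_twigs,
    branch_truth,
    place_puncta_on_branches,
    sample_branch_tree,
)

#: Baseline mean Sholl-crossing profile (annulus 0 = soma, no crossings).
#: Scaled to a cultured cortical arbor (~0.8 mm dendrite, ~500 punctae).
BASE_CROSSINGS = np.array([0, 15, 18, 21, 18, 15, 12, 9, 6], dtype=float)

#: Dendrite path tortuosity: realized length per annulus per crossing,
#: as a multiple of the 6.25 um shell width.
BASE_TORTUOSITY = 1.15

TUBE_XSECTION_UM2 = np.pi * 0.5**2  # constant-radius dendrite model
SOMA_VOLUME_UM3 = 4 / 3 * np.pi * 5.0**3


def _lognormal_levels(rng, n, median=1.0, sigma=0.35):
    """Draw AFU values and return counts at the 16 conductance levels."""
    if n == 0:
        return np.zeros(N_LEVELS, dtype=int)
    vals = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    hist = np.bincount(afu_to_level(vals), minlength=N_LEVELS)
    return hist.astype(int)


def stochastic_round(rng, x):
    """Round to an integer with expectation exactly x (per element)."""
    x = np.asarray(x, dtype=float)
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(int)


def proportional_counts(weights, total):
    """Integer allocation proportional to weights (largest remainder)."""
    weights = np.asarray(weights, dtype=float)
    total = int(round(total))
    if total <= 0 or weights.sum() <= 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    out = np.floor(quota).astype(int)
    rem = total - out.sum()
    if rem > 0:
        order = np.argsort(-(quota - out), kind="stable")
        out[order[:rem]] += 1
    return out


def _repair_support(counts):
    """Ensure no empty annulus sits inside the occupied radial range."""
    counts = counts.copy()
    occ = np.flatnonzero(counts[1:]) + 1
    if len(occ):
        counts[occ[0] : occ[-1] + 1] = np.maximum(counts[occ[0] : occ[-1] + 1], 1)
    return counts


@dataclass
class PopulationSpec:
    """Study conditions for a pair of +/- treatment populations."""

    n_per_group: int = 63
    base_crossings: np.ndarray = field(default_factory=lambda: BASE_CROSSINGS.copy())
    tortuosity: float = BASE_TORTUOSITY
    e_density_per_um: float = 0.45
    i_density_per_um: float = 0.15
    cv: float = 0.25                      # between-neuron size dispersion
    length_mult: float = 1.24
    crossings_mult: float = 1.30
    count_mult: float = 1.30              # applied to both E and I (balanced)
    i_intensity_mult: float = 1.30        # inhibitory-marker intensity shift
    e_intensity_mult: float = 1.0
    afu_sigma: float = 0.35
    seed: int = 0

    def validate(self):
        for name in ("length_mult", "crossings_mult", "count_mult",
                     "i_intensity_mult", "e_intensity_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cv < 0 or self.n_per_group < 2:
            raise ValueError("need cv >= 0 and n_per_group >= 2")
        return self


def _draw_profile(rng, spec: PopulationSpec, treated: bool, neuron_id, group):
    ml = spec.length_mult if treated else 1.0
    mc = spec.crossings_mult if treated else 1.0
    mn = spec.count_mult if treated else 1.0
    mi = spec.i_intensity_mult if treated else 1.0
    me = spec.e_intensity_mult if treated else 1.0

    size = max(0.2, 1.0 + spec.cv * rng.standard_normal())
    crossings = _repair_support(
        stochastic_round(rng, spec.base_crossings * mc * size)
    )
    crossings[0] = 0
    length = np.zeros(N_ANNULI)
    length[1:] = (
        spec.base_crossings[1:] * spec.tortuosity * ANNULUS_WIDTH_UM * ml * size
    )
    volume = length * TUBE_XSECTION_UM2
    volume[0] = SOMA_VOLUME_UM3

    e_mean = length * spec.e_density_per_um * mn
    i_mean = length * spec.i_density_per_um * mn
    e_counts = rng.poisson(e_mean)
    i_counts = rng.poisson(i_mean)

    m = NeuronMorphology(neuron_id=neuron_id, group=group)
    m.length_um = length
    m.crossings = crossings
    m.volume_um3 = volume
    for k in range(N_ANNULI):
        m.e_hist[k] = _lognormal_levels(rng, int(e_counts[k]), median=me,
                                        sigma=spec.afu_sigma)
        m.i_hist[k] = _lognormal_levels(rng, int(i_counts[k]), median=mi,
                                        sigma=spec.afu_sigma)
    return m.validate()


def generate_population(spec: PopulationSpec, label_a="-BDNF", label_b="+BDNF"):
    """Draw the two labeled populations of 9-annulus profiles.

    Deterministic per ``spec.seed``.  Returns (group_a, group_b) lists
    of :class:`NeuronMorphology`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a = [
        _draw_profile(rng, spec, False, f"{label_a}_{i:03d}", label_a)
        for i in range(spec.n_per_group)
    ]
    b = [
        _draw_profile(rng, spec, True, f"{label_b}_{i:03d}", label_b)
        for i in range(spec.n_per_group)
    ]
    return a, b


def worked_example_profile():
    """A deterministic 1500-synapse profile for the activation protocol.

    10% of the synapses sit in the 56 um annulus (index 8), 60% of that
    annulus is excitatory, and 20% of its excitatory punctae carry a
    normalized intensity of 1.5 (-> 1.5 nS): the configuration used to
    illustrate the stochastic-activation bookkeeping.
    """
    p = NeuronMorphology(neuron_id="worked-example")
    p.crossings = np.array([0, 3, 3, 3, 3, 3, 3, 3, 3])
    p.length_um = p.crossings * ANNULUS_WIDTH_UM * 1.0
    p.volume_um3 = np.where(p.crossings > 0, 20.0, 0.0)
    p.volume_um3[0] = SOMA_VOLUME_UM3
    lvl_1 = int(afu_to_level(1.0))
    lvl_15 = int(afu_to_level(1.5))
    for k in range(1, 8):
        p.e_hist[k, lvl_1] = 120
        p.i_hist[k, lvl_1] = 73 if k <= 6 else 72
    p.e_hist[8, lvl_15] = 18      # 20% of the annulus's 90 E punctae
    p.e_hist[8, lvl_1] = 72
    p.i_hist[8, lvl_1] = 60
    assert p.total_synapses == 1500
    return p.validate()


# ---------------------------------------------------------------------------
# rendered phantom populations


@dataclass
class ImagingPopulationSpec:
    """Study conditions for the rendered phantom benchmark.

    Arbors default to six occupied annuli (radius <= 37.5 um) so a
    population renders and segments in minutes; profiles still carry
    all nine annuli.
    """

    n_per_group: int = 20
    base_crossings: np.ndarray = field(
        default_factory=lambda: np.array([0, 4, 5, 5, 4, 3, 0, 0, 0], dtype=float)
    )
    twig_fraction: float = 0.35           # share of extra length carried by twigs
    e_density_per_um: float = 0.30
    i_density_per_um: float = 0.10
    cv: float = 0.03
    length_mult: float = 1.24
    crossings_mult: float = 1.30
    count_mult: float = 1.30
    i_intensity_mult: float = 1.30
    afu_sigma: float = 0.35
    soma_radius_um: float = 4.0
    noise_sd: float = 20.0
    margin_um: float = 4.0
    n_z: int = 12
    seed: int = 0


def sample_phantom_spec(rng, pop: ImagingPopulationSpec, treated: bool, seed):
    """Draw one neuron's :class:`PhantomSpec` under the population conditions."""
    ml = pop.length_mult if treated else 1.0
    mc = pop.crossings_mult if treated else 1.0
    mn = pop.count_mult if treated else 1.0
    mi = pop.i_intensity_mult if treated else 1.0

    size = max(0.5, 1.0 + pop.cv * rng.standard_normal())
    # largest-remainder allocation keeps the realized group contrast at
    # the configured multiplier without per-annulus rounding noise
    total_crossings = pop.base_crossings[1:].sum() * mc * size
    crossings = np.zeros(N_ANNULI, dtype=int)
    crossings[1:] = proportional_counts(pop.base_crossings[1:], total_crossings)
    crossings = _repair_support(crossings)
    crossings[0] = 0
    occupied = np.flatnonzero(crossings)
    k_max = int(occupied.max()) if len(occupied) else 0
    radius_um = (k_max + 1) * ANNULUS_WIDTH_UM + pop.margin_um

    n_xy = int(np.ceil(2 * radius_um / 0.25))
    shape = (pop.n_z, n_xy, n_xy)
    center = np.array([(pop.n_z - 1) / 2 * 1.0, radius_um, radius_um])

    # per-annulus length targets; twigs absorb the difference between the
    # target and the structural (radial) length realized by the tree
    target_len = (
        pop.base_crossings
        * ANNULUS_WIDTH_UM
        * (1.0 + pop.twig_fraction)
        * ml
        * size
    )
    structural = sample_branch_tree(
        rng, crossings, center, pop.soma_radius_um, twig_budget_um=None
    )
    s_len, _ = branch_truth(structural, center)
    twig_budget = np.maximum(0.0, target_len - s_len)
    twig_budget[0] = 0.0
    branches = add_twigs(rng, structural, center, twig_budget)

    total_len = branch_truth(branches, center)[0][1:].sum()
    n_e = int(rng.poisson(total_len * pop.e_density_per_um * mn))
    n_i = int(rng.poisson(total_len * pop.i_density_per_um * mn))

    def afu_sampler(rng_, ch, n):
        med = mi if ch == "VGAT" else 1.0
        return rng_.lognormal(np.log(med), pop.afu_sigma, size=n)

    puncta = place_puncta_on_branches(
        rng, branches, {"VGlut1": n_e, "VGAT": n_i}, afu_sampler
    )
    return PhantomSpec(
        shape=shape,
        soma_center_um=center,
        soma_radius_um=pop.soma_radius_um,
        branches=branches,
        puncta=puncta,
        noise_sd=pop.noise_sd,
        seed=int(seed),
    )


def sample_phantom_population(pop: ImagingPopulationSpec,
                              label_a="-BDNF", label_b="+BDNF"):
    """Per-neuron phantom specs for both groups, deterministic per seed.

    Returns two lists of (neuron_id, PhantomSpec).
    """
    rng = np.random.default_rng(pop.seed)
    out = {label_a: [], label_b: []}
    for label, treated in ((label_a, False), (label_b, True)):
        for i in range(pop.n_per_group):
            seed = int(rng.integers(0, 2**31 - 1))
            spec = sample_phantom_spec(rng, pop, treated, seed)
            out[label].append((f"{label}_{i:03d}", spec))
    return out[label_a], out[label_b]
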