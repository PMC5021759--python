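"""Stochastic synaptic bombardment of compartmental models and AP counting.

A stimulation protocol activates a fraction of a model neuron's
synapses once each, at uniformly random times inside a temporal
integration window.  Active synapses are allocated across the model's
(annulus, type, conductance-level) weight table by a multinomial draw,
so the active set follows the measured synapse distribution: a
1500-synapse model at strength 0.2 activates exactly 300 synapses, an
annulus holding 10% of the synapses receives 30 of them on average,
and if 60% of that annulus is excitatory, 18 of those are excitatory
on average.

The membrane model is Hodgkin-Huxley Na/K on the soma and axon with
passive dendrites whose leak is scaled by a dendrite-excitability
knob; synapses are double-exponential conductances reversing at 0 mV
(excitatory) and -70 mV (inhibitory).  An action potential is a strict
upward crossing of -35 mV at the distal end of the axon inside the
integration window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._hines import hh_steady_state, integrate
from .model import ModelNeuron, conductance_ns
from .profiles import CONDUCTANCE_LEVELS, N_LEVELS
from .geometry import N_ANNULI


class CableInstabilityError(RuntimeError):
    pass


@dataclass
class BiophysicsConfig:
    """Membrane, axial and synaptic parameters.

    Units: capacitance uF/cm^2, resistivity Ohm*cm, conductance
    densities S/cm^2, times ms, voltages mV.  ``dendrite_excitability``
    divides the dendritic leak density (larger = more excitable
    dendrites).  The HH leak reversal is calibrated at build time so
    the resting state is an exact fixed point at ``v_rest``.
    """

    cm_uf_cm2: float = 1.0
    ra_ohm_cm: float = 150.0
    g_pas_s_cm2: float = 1e-3
    v_rest_mv: float = -65.0
    dendrite_excitability: float = 1.0
    gna_s_cm2: float = 0.2
    gk_s_cm2: float = 0.036
    gl_hh_s_cm2: float = 3e-4
    ena_mv: float = 50.0
    ek_mv: float = -77.0
    tau_rise_e_ms: float = 0.5
    tau_decay_e_ms: float = 3.0
    tau_rise_i_ms: float = 1.0
    tau_decay_i_ms: float = 8.0
    e_rev_e_mv: float = 0.0
    e_rev_i_mv: float = -70.0
    dt_ms: float = 0.025
    ap_threshold_mv: float = -35.0
    tail_ms: float = 20.0

    def validate(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        for r, d in ((self.tau_rise_e_ms, self.tau_decay_e_ms),
                     (self.tau_rise_i_ms, self.tau_decay_i_ms)):
            if not 0 < r < d:
                raise ValueError("synaptic rise must be positive and < decay")
        for name in ("cm_uf_cm2", "ra_ohm_cm", "g_pas_s_cm2", "gna_s_cm2",
                     "gk_s_cm2", "gl_hh_s_cm2", "dendrite_excitability"):
            if getattr(self, name) < 0 or (
                name in ("cm_uf_cm2", "ra_ohm_cm") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be non-negative (cm, Ra positive)")
        return self

    def el_hh_mv(self):
        """Leak reversal putting the HH membrane at rest exactly at v_rest."""
        if self.gl_hh_s_cm2 == 0:
            return self.v_rest_mv
        v = self.v_rest_mv
        m, h, n = hh_steady_state(v)
        ina = self.gna_s_cm2 * m**3 * h * (v - self.ena_mv)
        ik = self.gk_s_cm2 * n**4 * (v - self.ek_mv)
        return v + (ina + ik) / self.gl_hh_s_cm2


@dataclass
class StimulusProtocol:
    """Fraction of synapses activated once each within a window."""

    strength: float = 0.2
    window_ms: float = 100.0
    seed: int = 0

    def validate(self):
        if not 0 < self.strength <= 1:
            raise ValueError("stimulation strength must be in (0, 1]")
        if self.window_ms <= 0:
            raise ValueError("integration window must be positive")
        return self


@dataclass
class SynapticEvents:
    """Active-synapse draw: one row per activation."""

    annulus: np.ndarray       # int
    is_e: np.ndarray          # bool
    conductance_ns: np.ndarray
    compartment: np.ndarray   # compartment id
    position: np.ndarray      # [0, 1) along the compartment
    onset_ms: np.ndarray

    def __len__(self):
        return len(self.onset_ms)

    def count_in_annulus(self, k, e_only=False):
        sel = self.annulus == k
        if e_only:
            sel &= self.is_e
        return int(sel.sum())


def draw_active_synapses(model: ModelNeuron, protocol: StimulusProtocol, rng=None):
    """Multinomial allocation of active synapses over the weight table.

    n_active = round(strength * total synapses); actives are allocated
    across (annulus, type, conductance-level) cells with probabilities
    proportional to the cell counts, placed uniformly on that annulus's
    compartments (soma for annulus 0) and fired once at a uniform time
    in [0, window).  Deterministic for a fixed protocol seed.
    """
    protocol.validate()
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    counts = model.synapse_counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("model has no synapses")
    n_active = int(round(protocol.strength * total))
    flat = counts.ravel()
    draw = rng.multinomial(n_active, flat / total) if n_active else np.zeros_like(
        flat, dtype=int
    )
    ann, typ, lvl = np.unravel_index(np.arange(flat.size), counts.shape)

    annuli = np.repeat(ann, draw)
    is_e = np.repeat(typ, draw) == 0
    g = np.array([conductance_ns(l) for l in np.repeat(lvl, draw)])

    comp_ids = np.empty(len(annuli), dtype=int)
    for k in np.unique(annuli):
        dend = model.dendrites_in_annulus(k)
        pool = np.array([c.id for c in dend]) if dend else np.array([model.soma.id])
        sel = annuli == k
        comp_ids[sel] = pool[rng.integers(len(pool), size=sel.sum())]
    pos = rng.uniform(0, 1, size=len(annuli))
    onset = rng.uniform(0, protocol.window_ms, size=len(annuli))
    order = np.argsort(onset, kind="stable")
    return SynapticEvents(
        annulus=annuli[order], is_e=is_e[order], conductance_ns=g[order],
        compartment=comp_ids[order], position=pos[order], onset_ms=onset[order],
    )


def expected_allocation(model: ModelNeuron, strength):
    """Deterministic expected active counts per (annulus, type, level).

    Returns (expected floats, nearest-integer rounding); the rounded
    table realizes statements like "4 of the 18 active excitatory
    synapses in that annulus carry 1.5 nS".
    """
    counts = model.synapse_counts.astype(float)
    total = counts.sum()
    n_active = round(strength * total)
    exp = counts / total * n_active
    return exp, np.round(exp).astype(int)


@dataclass
class SimulationResult:
    model_id: str
    strength: float
    window_ms: float
    seed: int
    ap_count: int
    rate_hz: float
    combo_id: str = ""
    trace: np.ndarray | None = None


def count_aps(trace, threshold_mv=-35.0, dt_ms=None, window_ms=None):
    """Strict upward threshold crossings of a uniformly sampled trace.

    A crossing is sample i with v[i] > threshold and v[i-1] <=
    threshold; a grazing touch equal to the threshold never counts.
    When ``dt_ms``/``window_ms`` are given, only crossings at times
    <= window are counted.
    """
    v = np.asarray(trace, dtype=float)
    up = (v[1:] > threshold_mv) & (v[:-1] <= threshold_mv)
    if dt_ms is not None and window_ms is not None:
        t = (np.arange(1, len(v))) * dt_ms
        up &= t <= window_ms
    return int(up.sum())


# ---------------------------------------------------------------------------
# discretization to segment arrays


def _discretize(model: ModelNeuron, bio: BiophysicsConfig):
    """Flatten compartments into per-segment arrays for the integrator."""
    seg_parent = []
    g_ax = []
    c_nf = []
    g_leak = []
    e_leak = []
    gna = []
    gk = []
    first_seg = {}
    half_r = []  # MOhm-free half axial resistance, Ohm

    el_hh = bio.el_hh_mv()
    for comp in model.compartments:
        s = comp.nseg
        l_cm = comp.length_um / s * 1e-4
        r_cm = comp.diam_um / 2 * 1e-4
        area = np.pi * comp.diam_um * 1e-4 * l_cm
        rh = bio.ra_ohm_cm * (l_cm / 2) / (np.pi * r_cm**2)
        passive = comp.role in ("dendrite", "apical")
        for j in range(s):
            idx = len(seg_parent)
            if j == 0:
                if comp.parent < 0:
                    seg_parent.append(-1)
                    g_ax.append(0.0)
                else:
                    pcomp = model.compartments[comp.parent]
                    pseg = first_seg[comp.parent] + pcomp.nseg - 1
                    seg_parent.append(pseg)
                    g_ax.append(1e6 / (rh + half_r[pseg]))
                first_seg[comp.id] = idx
            else:
                seg_parent.append(idx - 1)
                g_ax.append(1e6 / (rh + half_r[idx - 1]))
            half_r.append(rh)
            c_nf.append(bio.cm_uf_cm2 * area * 1e3)
            if passive:
                g_leak.append(
                    bio.g_pas_s_cm2 / bio.dendrite_excitability * area * 1e6
                )
                e_leak.append(bio.v_rest_mv)
                gna.append(0.0)
                gk.append(0.0)
            else:
                g_leak.append(bio.gl_hh_s_cm2 * area * 1e6)
                e_leak.append(el_hh)
                gna.append(bio.gna_s_cm2 * area * 1e6)
                gk.append(bio.gk_s_cm2 * area * 1e6)
    arrays = dict(
        parent=np.asarray(seg_parent, dtype=np.int64),
        g_ax=np.asarray(g_ax),
        c_nf=np.asarray(c_nf),
        g_leak=np.asarray(g_leak),
        e_leak=np.asarray(e_leak),
        gna=np.asarray(gna),
        gk=np.asarray(gk),
        first_seg=first_seg,
    )
    # distal axon segment: recording site
    axon = [c for c in model.compartments if c.role == "axon"][0]
    arrays["rec_node"] = first_seg[axon.id] + axon.nseg - 1
    return arrays


def _dexp_peak_factor(tau_r, tau_d):
    """Normalization so the double exponential peaks at the set conductance."""
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))


def simulate(model: ModelNeuron, events: SynapticEvents, bio: BiophysicsConfig,
             window_ms=100.0, strength=np.nan, seed=0, keep_trace=False,
             combo_id=""):
    """Integrate the cable under an event set and count axonal APs.

    The membrane is integrated over [0, window + tail] from the
    calibrated resting state; APs are counted within the window.
    """
    bio.validate()
    arrays = _discretize(model, bio)
    dt = bio.dt_ms
    n_steps = int(np.ceil((window_ms + bio.tail_ms) / dt))
    n = len(arrays["parent"])

    # static part of the backward-Euler diagonal
    c_over_dt = arrays["c_nf"] / dt
    diag_static = c_over_dt + arrays["g_leak"] + arrays["g_ax"]
    np.add.at(
        diag_static,
        arrays["parent"][arrays["parent"] >= 0],
        arrays["g_ax"][arrays["parent"] >= 0],
    )

    fe_r = np.exp(-dt / bio.tau_rise_e_ms)
    fe_d = np.exp(-dt / bio.tau_decay_e_ms)
    fi_r = np.exp(-dt / bio.tau_rise_i_ms)
    fi_d = np.exp(-dt / bio.tau_decay_i_ms)
    fac_e = _dexp_peak_factor(bio.tau_rise_e_ms, bio.tau_decay_e_ms)
    fac_i = _dexp_peak_factor(bio.tau_rise_i_ms, bio.tau_decay_i_ms)

    if len(events):
        if events.onset_ms.min() < 0 or events.onset_ms.max() >= window_ms:
            raise ValueError("event onsets must lie within [0, window)")
        nodes = np.empty(len(events), dtype=np.int64)
        for i in range(len(events)):
            comp = model.compartments[int(events.compartment[i])]
            j = min(comp.nseg - 1, int(events.position[i] * comp.nseg))
            nodes[i] = arrays["first_seg"][comp.id] + j
        ev_step = np.floor(events.onset_ms / dt).astype(np.int64)
        order = np.argsort(ev_step, kind="stable")
        ev_step = ev_step[order]
        ev_node = nodes[order]
        # nS -> uS, with the peak-normalization factor folded in
        ev_w = (events.conductance_ns[order] * 1e-3) * np.where(
            events.is_e[order], fac_e, fac_i
        )
        ev_is_e = events.is_e[order].astype(np.bool_)
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_node = np.empty(0, dtype=np.int64)
        ev_w = np.empty(0)
        ev_is_e = np.empty(0, dtype=np.bool_)

    trace, ok = integrate(
        arrays["parent"], arrays["g_ax"], diag_static, c_over_dt,
        arrays["g_leak"], arrays["e_leak"], arrays["gna"], arrays["gk"],
        bio.ena_mv, bio.ek_mv,
        fe_r, fe_d, fi_r, fi_d, bio.e_rev_e_mv, bio.e_rev_i_mv,
        ev_step, ev_node, ev_w, ev_is_e,
        dt, n_steps, arrays["rec_node"], bio.v_rest_mv,
    )
    if not ok:
        raise CableInstabilityError(
            f"numerical divergence (|V| > 200 mV); reduce dt from {dt} ms"
        )
    count = count_aps(trace, bio.ap_threshold_mv, dt_ms=dt, window_ms=window_ms)
    return SimulationResult(
        model_id=model.neuron_id,
        strength=float(strength),
        window_ms=float(window_ms),
        seed=int(seed),
        ap_count=count,
        rate_hz=count / (window_ms / 1000.0),
        combo_id=combo_id,
        trace=trace if keep_trace else None,
    )


def run_protocol(model, protocol: StimulusProtocol, bio: BiophysicsConfig,
                 keep_trace=False, combo_id=""):
    """Draw active synapses under the protocol and simulate."""
    events = draw_active_synapses(model, protocol)
    return simulate(
        model, events, bio, window_ms=protocol.window_ms,
        strength=protocol.strength, seed=protocol.seed,
        keep_trace=keep_trace, combo_id=combo_id,
    )
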