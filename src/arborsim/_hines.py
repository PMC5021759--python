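"""Branched-cable integrator core.

Backward-Euler voltage update on the tree of segments (Hines O(N)
elimination) staggered with exponential-Euler channel gates, the
scheme NEURON-style simulators default to for stiff branched cables.
Synaptic double-exponential conductances are aggregated per segment and
receptor class into two decaying states, so cost is independent of the
number of active synapses.

The hot loop is JIT-compiled with numba when available and falls back
to the identical pure-Python implementation otherwise.
"""

from __future__ import annotations

import numpy as np


def _integrate_py(
    parent, g_ax, diag_static, c_over_dt, g_leak, e_leak,
    gna_bar, gk_bar, ena, ek,
    fe_r, fe_d, fi_r, fi_d, e_rev_e, e_rev_i,
    ev_step, ev_node, ev_w, ev_is_e,
    dt, n_steps, rec_node, v_init,
):
    n = parent.shape[0]
    v = np.full(n, v_init)
    # gate steady states at v_init
    m, h, ngate = _hh_inf(v, v_init)
    ae = np.zeros(n)
    be = np.zeros(n)
    ai = np.zeros(n)
    bi = np.zeros(n)
    d = np.empty(n)
    b = np.empty(n)
    rec = np.empty(n_steps + 1)
    rec[0] = v[rec_node]
    ptr = 0
    n_ev = ev_step.shape[0]
    for step in range(1, n_steps + 1):
        # ---- HH gates (exponential Euler at the current voltage)
        for i in range(n):
            if gna_bar[i] > 0.0 or gk_bar[i] > 0.0:
                vi = v[i]
                am = _vtrap(0.1, vi + 40.0, 10.0)
                bm = 4.0 * np.exp(-(vi + 65.0) / 18.0)
                ah = 0.07 * np.exp(-(vi + 65.0) / 20.0)
                bh = 1.0 / (1.0 + np.exp(-(vi + 35.0) / 10.0))
                an = _vtrap(0.01, vi + 55.0, 10.0)
                bn = 0.125 * np.exp(-(vi + 65.0) / 80.0)
                m[i] = _gate_step(m[i], am, bm, dt)
                h[i] = _gate_step(h[i], ah, bh, dt)
                ngate[i] = _gate_step(ngate[i], an, bn, dt)
        # ---- synaptic state decay and event insertion
        for i in range(n):
            ae[i] *= fe_r
            be[i] *= fe_d
            ai[i] *= fi_r
            bi[i] *= fi_d
        while ptr < n_ev and ev_step[ptr] < step:
            node = ev_node[ptr]
            w = ev_w[ptr]
            if ev_is_e[ptr]:
                ae[node] += w
                be[node] += w
            else:
                ai[node] += w
                bi[node] += w
            ptr += 1
        # ---- assemble backward-Euler system
        for i in range(n):
            ge = be[i] - ae[i]
            gi = bi[i] - ai[i]
            gna = gna_bar[i] * m[i] * m[i] * m[i] * h[i]
            gk = gk_bar[i] * ngate[i] ** 4
            d[i] = diag_static[i] + gna + gk + ge + gi
            b[i] = (
                c_over_dt[i] * v[i]
                + g_leak[i] * e_leak[i]
                + gna * ena
                + gk * ek
                + ge * e_rev_e
                + gi * e_rev_i
            )
        # ---- Hines elimination (children ordered after parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / d[i]
            d[p] -= f * g_ax[i]
            b[p] += f * b[i]
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + g_ax[i] * v[parent[i]]) / d[i]
        rec[step] = v[rec_node]
        if step % 200 == 0:
            for i in range(n):
                if abs(v[i]) > 200.0:
                    return rec, False
    return rec, True


def _vtrap_py(a, x, scale):
    # a * x / (1 - exp(-x/scale)), stable near x = 0
    if abs(x / scale) < 1e-6:
        return a * scale * (1.0 + x / (2.0 * scale))
    return a * x / (1.0 - np.exp(-x / scale))


def _gate_step_py(x, alpha, beta, dt):
    tau = 1.0 / (alpha + beta)
    inf = alpha * tau
    return inf + (x - inf) * np.exp(-dt / tau)


def _hh_inf_py(v, v_init):
    n = v.shape[0]
    m = np.empty(n)
    h = np.empty(n)
    ng = np.empty(n)
    for i in range(n):
        vi = v[i]
        am = _vtrap(0.1, vi + 40.0, 10.0)
        bm = 4.0 * np.exp(-(vi + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(vi + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(vi + 35.0) / 10.0))
        an = _vtrap(0.01, vi + 55.0, 10.0)
        bn = 0.125 * np.exp(-(vi + 65.0) / 80.0)
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)
        ng[i] = an / (an + bn)
    return m, h, ng


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _vtrap = njit(cache=False)(_vtrap_py)
    _gate_step = njit(cache=False)(_gate_step_py)
    _hh_inf = njit(cache=False)(_hh_inf_py)
    integrate = njit(cache=False)(_integrate_py)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _vtrap = _vtrap_py
    _gate_step = _gate_step_py
    _hh_inf = _hh_inf_py
    integrate = _integrate_py
    HAVE_NUMBA = False


def hh_steady_state(v):
    """Steady-state HH gate values at a single voltage (for calibration)."""
    am = _vtrap_py(0.1, v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = _vtrap_py(0.01, v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)
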