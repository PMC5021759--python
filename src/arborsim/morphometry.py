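"""Annulus binning, per-group summaries and the statistical comparisons.

This module turns segmentation output (mask, Sholl statistics, measured
punctae, distance map) into :class:`~arborsim.profiles.NeuronMorphology`
objects, fits the excitatory/inhibitory balance line, and runs the
normality-screened two-sample comparison used throughout: Student's t
when both samples pass Shapiro-Wilk, a rank test otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ANNULUS_WIDTH_UM, N_ANNULI, annulus_index
from .profiles import NeuronMorphology, afu_to_level


def bin_annuli(neuron_mask, sholl, punctae_table, dmap, voxel_size,
               neuron_id="n0", group=""):
    """Assemble a :class:`NeuronMorphology` from one neuron's measurements.

    Parameters
    ----------
    neuron_mask : NeuronMask
    sholl : ShollResult
        Per-annulus skeleton lengths and crossings.
    punctae_table : DataFrame
        Combined measured puncta rows with columns ``channel`` ("VGlut1"
        or "VGAT"), ``dist_um``, ``afu`` and ``colocalized``; only
        colocalized punctae are counted.
    dmap : ndarray
        Soma-centered distance map on the same grid.
    voxel_size : (dz, dy, dx) um

    Punctae beyond the outermost annulus are attributed to it with a
    warning (the models carry nine regions).
    """
    m = NeuronMorphology(neuron_id=neuron_id, group=group)
    m.length_um = np.asarray(sholl.length_um, dtype=float).copy()
    m.crossings = np.asarray(sholl.crossings, dtype=int).copy()

    vox_vol = float(np.prod(voxel_size))
    kvol = annulus_index(dmap[neuron_mask.mask])
    np.add.at(m.volume_um3, kvol, vox_vol)

    tab = punctae_table
    if len(tab):
        tab = tab[tab["colocalized"]]
    for _, row in tab.iterrows():
        d = float(row["dist_um"])
        if d >= N_ANNULI * ANNULUS_WIDTH_UM:
            warnings.warn(
                f"punctum at {d:.1f} um beyond annulus {N_ANNULI - 1}; "
                "assigned to the outermost annulus"
            )
        k = int(annulus_index(d))
        lvl = int(afu_to_level(row["afu"]))
        if str(row["channel"]).lower().startswith("vglut") or row["channel"] == "E":
            m.e_hist[k, lvl] += 1
        else:
            m.i_hist[k, lvl] += 1
    return m.validate()


def profile_from_stacks(vols, neuron_id="n0", group="", control_means=None):
    """Full imaging stream for one neuron: stacks -> NeuronMorphology.

    ``vols`` maps channel -> VolumeImage for "GFP", "VGlut1", "VGAT".
    ``control_means`` optionally maps channel -> session control mean
    raw intensity for AFU normalization; without it, each channel
    self-normalizes to its own colocalized-punctum mean.
    """
    from .puncta import colocalize, detect_puncta, measure
    from .segmentation import (
        distance_transform,
        locate_soma_center,
        segment_neuron,
        skeletonize_and_sholl,
    )

    gfp = vols["GFP"]
    mask = segment_neuron(gfp)
    soma = locate_soma_center(gfp, refine_mask=mask)
    dmap = distance_transform(soma, gfp.shape, gfp.voxel_size)
    sholl = skeletonize_and_sholl(mask, soma)
    tables = []
    for ch in ("VGlut1", "VGAT"):
        ps = detect_puncta(vols[ch])
        colocalize(ps, mask)
        measure(ps, vols[ch], dmap)
        tab = ps.table.copy()
        if len(tab):
            if control_means is not None:
                denom = control_means[ch]
            else:
                on = tab[tab["colocalized"]]
                denom = on["raw_mean"].mean() if len(on) else tab["raw_mean"].mean()
            tab["afu"] = tab["raw_mean"] / denom
        else:
            tab["afu"] = np.empty(0)
        tables.append(tab)
    punctae = pd.concat(tables, ignore_index=True)
    return bin_annuli(mask, sholl, punctae, dmap, gfp.voxel_size,
                      neuron_id=neuron_id, group=group)


def ei_balance_fit(neurons):
    """Least-squares line of total inhibitory vs total excitatory punctae.

    Returns (slope, intercept, r).  Raises ``ValueError`` for degenerate
    input (fewer than 3 neurons or constant E totals).
    """
    e = np.array([n.total_e for n in neurons], dtype=float)
    i = np.array([n.total_i for n in neurons], dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 neurons for the E/I balance fit")
    if np.ptp(e) == 0:
        raise ValueError("undefined slope: excitatory totals are constant")
    res = stats.linregress(e, i)
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    test: str
    normal: bool


def compare_groups(a, b, paired=False, alpha_normal=0.05):
    """Normality-screened two-sample comparison.

    Shapiro-Wilk is run on each sample; if neither rejects normality at
    ``alpha_normal`` the comparison is a Student's t-test (paired or
    unpaired), otherwise a rank test: Wilcoxon signed-rank when paired,
    Mann-Whitney U when unpaired.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per sample")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal sample sizes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = (np.ptp(a) > 0 and stats.shapiro(a).pvalue >= alpha_normal) and (
            np.ptp(b) > 0 and stats.shapiro(b).pvalue >= alpha_normal
        )
        if paired and np.allclose(a, b):
            # identical paired samples: no variation to test
            return TestResult(0.0, 1.0, "t (paired)", True)
        if norm:
            if paired:
                r = stats.ttest_rel(a, b)
                name = "t (paired)"
            else:
                r = stats.ttest_ind(a, b)
                name = "t (unpaired)"
        else:
            if paired:
                r = stats.wilcoxon(a, b, zero_method="wilcox")
                name = "wilcoxon signed-rank"
            else:
                r = stats.mannwhitneyu(a, b)
                name = "mann-whitney"
    return TestResult(float(r.statistic), float(r.pvalue), name, bool(norm))


def percent_change(mean_b, mean_a):
    """100 * (mean_b - mean_a) / mean_a."""
    if mean_a == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return 100.0 * (mean_b - mean_a) / mean_a


def group_summary(neurons_a, neurons_b, label_a="-BDNF", label_b="+BDNF"):
    """Per-group totals, per-annulus means +/- SEM and group comparisons.

    Returns a dict with a per-neuron totals frame, a per-annulus means
    frame and test results plus percent changes for the headline totals
    (dendrite length, complexity, E count, I count).
    """
    def totals_frame(neurons, label):
        return pd.DataFrame(
            {
                "neuron": [n.neuron_id for n in neurons],
                "group": label,
                "total_length_um": [n.total_length_um for n in neurons],
                "total_crossings": [n.total_crossings for n in neurons],
                "total_e": [n.total_e for n in neurons],
                "total_i": [n.total_i for n in neurons],
            }
        )

    ta = totals_frame(neurons_a, label_a)
    tb = totals_frame(neurons_b, label_b)

    def annulus_means(neurons, label):
        rows = []
        for k in range(N_ANNULI):
            for metric, getter in [
                ("length_um", lambda n: n.length_um[k]),
                ("crossings", lambda n: n.crossings[k]),
                ("e_count", lambda n: n.e_counts[k]),
                ("i_count", lambda n: n.i_counts[k]),
            ]:
                vals = np.array([getter(n) for n in neurons], dtype=float)
                rows.append(
                    {
                        "group": label,
                        "annulus": k,
                        "metric": metric,
                        "mean": vals.mean(),
                        "sem": vals.std(ddof=1) / np.sqrt(len(vals))
                        if len(vals) > 1
                        else np.nan,
                        "n": len(vals),
                    }
                )
        return pd.DataFrame(rows)

    tests = {}
    changes = {}
    for col in ("total_length_um", "total_crossings", "total_e", "total_i"):
        tests[col] = compare_groups(ta[col], tb[col])
        changes[col] = percent_change(tb[col].mean(), ta[col].mean())
    return {
        "totals": pd.concat([ta, tb], ignore_index=True),
        "annulus_means": pd.concat(
            [annulus_means(neurons_a, label_a), annulus_means(neurons_b, label_b)],
            ignore_index=True,
        ),
        "tests": tests,
        "percent_change": changes,
    }
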