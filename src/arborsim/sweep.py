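"""Unconstrained-parameter sweeps and average-parameter substitution.

The sweep varies the parameters the imaging data cannot constrain
(stimulation strength, apical-dendrite length, excitatory and
inhibitory decay constants, integration window, dendrite excitability)
over value lists sharing a middle baseline.  The default one-at-a-time
scheme gives 1 + 5 params x 4 off-middle values = 21 combinations,
crossed with 5 stimulation strengths: 105 combinations, i.e. 6615
simulations for a 63-model group.  A full-grid scheme is also
available.

Substitution experiments replace one morphological parameter of every
model in the recipient group with the donor group's per-annulus
average (producing "hybrid" models), re-simulate at middle parameter
values, and compare rates to the unsubstituted models with a paired
normality-screened test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cable import BiophysicsConfig, StimulusProtocol, run_protocol
from .geometry import N_ANNULI
from .model import build_model
from .morphometry import compare_groups
from .profiles import N_LEVELS, NeuronMorphology

SUBSTITUTABLE = (
    "dendrite_counts",
    "total_synapses",
    "ei_ratio",
    "e_intensity",
    "i_intensity",
    "fill_volume",
)


@dataclass
class SweepConfig:
    """Value lists (odd lengths; the middle entry is the baseline)."""

    strengths: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    apical_lengths_um: tuple = (100.0, 175.0, 250.0, 325.0, 400.0)
    tau_decay_e_ms: tuple = (1.5, 2.0, 3.0, 4.5, 6.0)
    tau_decay_i_ms: tuple = (4.0, 6.0, 8.0, 12.0, 16.0)
    windows_ms: tuple = (50.0, 75.0, 100.0, 150.0, 200.0)
    excitabilities: tuple = (0.5, 0.75, 1.0, 1.5, 2.0)
    scheme: str = "one-at-a-time"
    seed: int = 0

    _PARAMS = ("apical_lengths_um", "tau_decay_e_ms", "tau_decay_i_ms",
               "windows_ms", "excitabilities")

    def validate(self):
        for name in self._PARAMS + ("strengths",):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"empty value list: {name}")
            if name != "strengths" and len(vals) % 2 == 0:
                raise ValueError(f"{name} needs an odd length so a middle exists")
        if self.scheme not in ("one-at-a-time", "full-grid"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        return self

    def middle(self, name):
        vals = getattr(self, name)
        return vals[len(vals) // 2]

    def combos(self):
        """Explicit combination list: dicts of parameter values + combo_id."""
        self.validate()
        base = {name: self.middle(name) for name in self._PARAMS}
        rows = []
        if self.scheme == "one-at-a-time":
            variations = [("middle", dict(base))]
            for name in self._PARAMS:
                for v in getattr(self, name):
                    if v == self.middle(name):
                        continue
                    d = dict(base)
                    d[name] = v
                    variations.append((f"{name}={v:g}", d))
        else:
            variations = []
            for values in itertools.product(
                *[getattr(self, n) for n in self._PARAMS]
            ):
                d = dict(zip(self._PARAMS, values))
                tag = ",".join(f"{n}={v:g}" for n, v in d.items())
                variations.append((tag, d))
        for strength in self.strengths:
            for tag, d in variations:
                rows.append(
                    {"combo_id": f"s={strength:g}|{tag}", "strength": strength, **d}
                )
        return rows

    def n_combos(self):
        return len(self.combos())


def expected_combo_count(n_params, n_values, n_strengths, scheme="one-at-a-time"):
    """Closed-form combination count for the accounting identity."""
    if scheme == "one-at-a-time":
        return (1 + n_params * (n_values - 1)) * n_strengths
    return n_values**n_params * n_strengths


@dataclass
class SweepResult:
    table: pd.DataFrame          # model_id, group, combo_id, seed, strength, rate
    n_combos: int
    n_models: dict

    def model_means(self):
        return (
            self.table.groupby(["group", "model_id"])["rate_hz"]
            .mean()
            .reset_index()
        )

    def combo_group_means(self):
        return (
            self.table.groupby(["combo_id", "group"])["rate_hz"]
            .mean()
            .unstack("group")
        )


def run_sweep(profiles_a, profiles_b, config: SweepConfig, bio: BiophysicsConfig,
              labels=("-BDNF", "+BDNF"), n_repeats=1):
    """Simulate every (model, combination) for both groups.

    Models are rebuilt per apical length (a build-time parameter);
    per-run seeds are spawned from ``config.seed`` so each (group,
    model, combo, repeat) has an independent, reproducible stream.
    """
    combos = config.combos()
    rows = []
    groups = {labels[0]: profiles_a, labels[1]: profiles_b}
    for label, profiles in groups.items():
        for mi, prof in enumerate(profiles):
            model_cache = {}
            for ci, combo in enumerate(combos):
                ap = combo["apical_lengths_um"]
                if ap not in model_cache:
                    model_cache[ap] = build_model(
                        prof, apical_length_um=ap, ra_ohm_cm=bio.ra_ohm_cm,
                        cm_uf_cm2=bio.cm_uf_cm2,
                    )
                model = model_cache[ap]
                b = replace(
                    bio,
                    tau_decay_e_ms=combo["tau_decay_e_ms"],
                    tau_decay_i_ms=combo["tau_decay_i_ms"],
                    dendrite_excitability=combo["excitabilities"],
                )
                for rep in range(n_repeats):
                    # stimulus seeds are shared between groups (paired
                    # draws): identical populations give identical rates
                    seed = int(
                        np.random.SeedSequence(
                            (config.seed, mi, ci, rep)
                        ).generate_state(1)[0] % (2**31)
                    )
                    proto = StimulusProtocol(
                        strength=combo["strength"],
                        window_ms=combo["windows_ms"],
                        seed=seed,
                    )
                    res = run_protocol(model, proto, b, combo_id=combo["combo_id"])
                    rows.append(
                        {
                            "model_id": prof.neuron_id,
                            "group": label,
                            "combo_id": combo["combo_id"],
                            "seed": seed,
                            "strength": combo["strength"],
                            "window_ms": combo["windows_ms"],
                            "ap_count": res.ap_count,
                            "rate_hz": res.rate_hz,
                        }
                    )
    table = pd.DataFrame(rows)
    return SweepResult(
        table=table,
        n_combos=len(combos),
        n_models={labels[0]: len(profiles_a), labels[1]: len(profiles_b)},
    )


def rank_models(result: SweepResult, group=None):
    """Model ids in descending order of mean rate (ties by id)."""
    means = result.model_means()
    if group is not None:
        means = means[means["group"] == group]
    means = means.sort_values(
        ["rate_hz", "model_id"], ascending=[False, True], kind="stable"
    )
    return means["model_id"].tolist()


def percent_difference_map(result: SweepResult, labels=("-BDNF", "+BDNF"),
                           min_firing_fraction=0.5):
    """Per-combo and per-ranked-pair percent differences between groups.

    A combination where fewer than half of all models fire at least one
    AP is flagged not-compared; a compared combination with a zero
    reference mean is flagged undefined.
    """
    la, lb = labels
    tab = result.table
    per_combo = []
    for combo_id, sub in tab.groupby("combo_id", sort=False):
        fired = (sub.groupby(["group", "model_id"])["ap_count"].max() >= 1)
        frac = fired.mean()
        ma = sub[sub["group"] == la]["rate_hz"].mean()
        mb = sub[sub["group"] == lb]["rate_hz"].mean()
        if frac < min_firing_fraction:
            flag, pct = "not_compared", np.nan
        elif ma == 0:
            flag, pct = "undefined", np.nan
        else:
            flag, pct = "ok", 100.0 * (mb - ma) / ma
        per_combo.append(
            {"combo_id": combo_id, "mean_a": ma, "mean_b": mb,
             "fraction_firing": frac, "pct_difference": pct, "flag": flag}
        )
    per_combo = pd.DataFrame(per_combo)

    ranks_a = rank_models(result, la)
    ranks_b = rank_models(result, lb)
    pairs = []
    means = tab.groupby(["group", "model_id", "combo_id"])["rate_hz"].mean()
    for r, (ida, idb) in enumerate(zip(ranks_a, ranks_b)):
        for combo_id in per_combo["combo_id"]:
            ra = means.get((la, ida, combo_id), np.nan)
            rb = means.get((lb, idb, combo_id), np.nan)
            pct = 100.0 * (rb - ra) / ra if ra else np.nan
            pairs.append(
                {"rank": r, "model_a": ida, "model_b": idb,
                 "combo_id": combo_id, "pct_difference": pct}
            )
    return per_combo, pd.DataFrame(pairs)


# ---------------------------------------------------------------------------
# substitution ("hybrid" models)


def _apportion(weights, total):
    """Integer allocation proportional to weights (largest remainder)."""
    weights = np.asarray(weights, dtype=float)
    total = int(total)
    if total == 0:
        return np.zeros_like(weights, dtype=int)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    quota = weights / weights.sum() * total
    out = np.floor(quota).astype(int)
    rem = total - out.sum()
    if rem > 0:
        order = np.argsort(-(quota - out), kind="stable")
        out[order[:rem]] += 1
    return out


@dataclass
class GroupAverage:
    """Per-annulus averages of a donor group, for substitution."""

    crossings: np.ndarray
    synapse_totals: np.ndarray        # E+I per annulus
    e_fraction: np.ndarray            # per annulus (NaN where empty)
    e_level_dist: np.ndarray          # (annulus, level) probabilities
    i_level_dist: np.ndarray
    volume_um3: np.ndarray


def group_average(profiles):
    n = len(profiles)
    crossings = np.mean([p.crossings for p in profiles], axis=0)
    totals = np.mean(
        [p.e_counts + p.i_counts for p in profiles], axis=0
    )
    e_sum = np.sum([p.e_hist for p in profiles], axis=0).astype(float)
    i_sum = np.sum([p.i_hist for p in profiles], axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_frac = e_sum.sum(axis=1) / (e_sum.sum(axis=1) + i_sum.sum(axis=1))
        e_dist = e_sum / e_sum.sum(axis=1, keepdims=True)
        i_dist = i_sum / i_sum.sum(axis=1, keepdims=True)
    vol = np.mean([p.volume_um3 for p in profiles], axis=0)
    return GroupAverage(crossings, totals, e_frac, np.nan_to_num(e_dist),
                        np.nan_to_num(i_dist), vol)


def substitute_profile(profile: NeuronMorphology, donor: GroupAverage, param):
    """Replace exactly one morphological parameter with the donor average.

    All non-substituted per-annulus marginals are preserved exactly.
    Substituted crossings that would orphan outer annuli are repaired
    by truncation with a warning.
    """
    if param not in SUBSTITUTABLE:
        raise ValueError(f"unknown substitution parameter {param!r}")
    out = NeuronMorphology(
        neuron_id=profile.neuron_id,
        group=profile.group + f"|sub:{param}",
        length_um=profile.length_um.copy(),
        crossings=profile.crossings.copy(),
        volume_um3=profile.volume_um3.copy(),
        e_hist=profile.e_hist.copy(),
        i_hist=profile.i_hist.copy(),
    )
    if param == "dendrite_counts":
        cr = np.maximum(np.round(donor.crossings), 0).astype(int)
        cr[0] = 0
        for k in range(2, N_ANNULI):
            if cr[k] > 0 and cr[k - 1] == 0:
                warnings.warn(
                    "substituted crossings orphan outer annuli; truncating"
                )
                cr[k:] = 0
                break
        out.crossings = cr
    elif param == "total_synapses":
        for k in range(N_ANNULI):
            target = int(round(donor.synapse_totals[k]))
            cur = profile.e_hist[k].sum() + profile.i_hist[k].sum()
            flat = np.concatenate([profile.e_hist[k], profile.i_hist[k]]).astype(
                float
            )
            if cur == 0:
                # recipient had none here: use the donor's composition
                flat = np.concatenate(
                    [
                        donor.e_level_dist[k] * donor.e_fraction[k]
                        if np.isfinite(donor.e_fraction[k])
                        else np.zeros(N_LEVELS),
                        donor.i_level_dist[k]
                        * (1 - (donor.e_fraction[k] if np.isfinite(
                            donor.e_fraction[k]) else 0.0)),
                    ]
                )
            alloc = _apportion(flat, target)
            out.e_hist[k] = alloc[:N_LEVELS]
            out.i_hist[k] = alloc[N_LEVELS:]
    elif param == "ei_ratio":
        for k in range(N_ANNULI):
            total = profile.e_hist[k].sum() + profile.i_hist[k].sum()
            if total == 0 or not np.isfinite(donor.e_fraction[k]):
                continue
            te = int(round(donor.e_fraction[k] * total))
            out.e_hist[k] = _apportion(
                profile.e_hist[k]
                if profile.e_hist[k].sum()
                else donor.e_level_dist[k],
                te,
            )
            out.i_hist[k] = _apportion(
                profile.i_hist[k]
                if profile.i_hist[k].sum()
                else donor.i_level_dist[k],
                total - te,
            )
    elif param == "e_intensity":
        for k in range(N_ANNULI):
            n_k = profile.e_hist[k].sum()
            if n_k:
                out.e_hist[k] = _apportion(donor.e_level_dist[k], n_k)
    elif param == "i_intensity":
        for k in range(N_ANNULI):
            n_k = profile.i_hist[k].sum()
            if n_k:
                out.i_hist[k] = _apportion(donor.i_level_dist[k], n_k)
    elif param == "fill_volume":
        out.volume_um3 = donor.volume_um3.copy()
    return out.validate()


def substitute_and_run(recipient_profiles, donor_profiles, param,
                       bio: BiophysicsConfig, config: SweepConfig = None,
                       strengths=(1.0, 0.6, 0.2), seed=0, n_repeats=1):
    """Simulate recipient models with and without one substituted parameter.

    Unconstrained parameters sit at their middle values; each recipient
    model is its own control (per-model rates are averaged over
    ``n_repeats`` stimulus draws with seeds shared between conditions),
    compared with a paired normality-screened test per stimulation
    strength.

    Returns (per-run table, per-strength test frame).
    """
    config = (config or SweepConfig()).validate()
    donor = group_average(donor_profiles)
    window = config.middle("windows_ms")
    apical = config.middle("apical_lengths_um")
    b = replace(
        bio,
        tau_decay_e_ms=config.middle("tau_decay_e_ms"),
        tau_decay_i_ms=config.middle("tau_decay_i_ms"),
        dendrite_excitability=config.middle("excitabilities"),
    )
    rows = []
    for mi, prof in enumerate(recipient_profiles):
        hybrid = substitute_profile(prof, donor, param)
        m0 = build_model(prof, apical_length_um=apical, ra_ohm_cm=b.ra_ohm_cm,
                         cm_uf_cm2=b.cm_uf_cm2)
        m1 = build_model(hybrid, apical_length_um=apical, ra_ohm_cm=b.ra_ohm_cm,
                         cm_uf_cm2=b.cm_uf_cm2)
        for si, strength in enumerate(strengths):
            for rep in range(n_repeats):
                run_seed = int(
                    np.random.SeedSequence(
                        (seed, mi, si, rep)
                    ).generate_state(1)[0] % (2**31)
                )
                proto = StimulusProtocol(strength=strength, window_ms=window,
                                         seed=run_seed)
                for tag, model in (("original", m0), ("hybrid", m1)):
                    res = run_protocol(model, proto, b,
                                       combo_id=f"{param}|{tag}")
                    rows.append(
                        {
                            "model_id": prof.neuron_id,
                            "condition": tag,
                            "param": param,
                            "strength": strength,
                            "repeat": rep,
                            "rate_hz": res.rate_hz,
                            "ap_count": res.ap_count,
                        }
                    )
    table = pd.DataFrame(rows)
    tests = []
    for strength, sub in table.groupby("strength"):
        per_model = sub.groupby(["condition", "model_id"])["rate_hz"].mean()
        orig = per_model["original"].sort_index().to_numpy()
        hyb = per_model["hybrid"].sort_index().to_numpy()
        tr = compare_groups(orig, hyb, paired=True)
        tests.append(
            {
                "param": param,
                "strength": strength,
                "mean_original": orig.mean(),
                "mean_hybrid": hyb.mean(),
                "statistic": tr.statistic,
                "pvalue": tr.pvalue,
                "test": tr.test,
            }
        )
    return table, pd.DataFrame(tests)
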