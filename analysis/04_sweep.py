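#!/usr/bin/env python
"""Unconstrained-parameter sweep over both model populations.

Runs the default one-at-a-time scheme (105 combinations: 5 stimulation
strengths crossed with a middle baseline plus 4 off-middle values for
each of apical length, excitatory/inhibitory decay, window and dendrite
excitability) over a subset of models per group, then writes the
rate landscape (models x combinations), the model ranking by mean rate,
and the per-combination percent-difference map with the
fewer-than-half-firing combinations flagged as not compared.
"""

from pathlib import Path

import pandas as pd

from arborsim.cable import BiophysicsConfig
from arborsim.profiles import read_profiles
from arborsim.sweep import SweepConfig, percent_difference_map, rank_models, run_sweep

SEED = 20260929
N_MODELS = 16   # per group; the full populations scale linearly
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    profiles = read_profiles(OUT / "profiles.tsv")
    a = [p for p in profiles if p.group == "-BDNF"][:N_MODELS]
    b = [p for p in profiles if p.group == "+BDNF"][:N_MODELS]
    cfg = SweepConfig(seed=SEED)
    print(f"{cfg.n_combos()} combinations x {len(a) + len(b)} models "
          f"= {cfg.n_combos() * (len(a) + len(b))} simulations")
    res = run_sweep(a, b, cfg, BiophysicsConfig())
    res.table.to_csv(OUT / "sweep_runs.tsv", sep="\t", index=False)

    landscape = res.table.pivot_table(index="model_id", columns="combo_id",
                                      values="rate_hz")
    landscape.to_csv(OUT / "sweep_landscape.tsv", sep="\t")

    per_combo, pairs = percent_difference_map(res)
    per_combo.to_csv(OUT / "sweep_percent_difference.tsv", sep="\t",
                     index=False)
    pairs.to_csv(OUT / "sweep_ranked_pairs.tsv", sep="\t", index=False)
    ranking = rank_models(res)
    pd.Series(ranking, name="model_id").to_csv(OUT / "sweep_ranking.tsv",
                                               sep="\t", index=False)

    ok = per_combo[per_combo["flag"] == "ok"]
    print(f"rates span {res.table['rate_hz'].min():.0f}-"
          f"{res.table['rate_hz'].max():.0f} Hz")
    print(f"{len(ok)}/{len(per_combo)} combinations compared; "
          f"mean +BDNF/-BDNF difference {ok['pct_difference'].mean():+.1f}% "
          f"(range {ok['pct_difference'].min():+.1f}% to "
          f"{ok['pct_difference'].max():+.1f}%)")
    print(f"{(per_combo['flag'] == 'not_compared').sum()} combinations "
          "had fewer than half of the models firing and were not compared")


if __name__ == "__main__":
    main()
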