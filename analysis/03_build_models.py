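#!/usr/bin/env python
"""Build compartmental models for both profile populations.

Converts every annulus profile from step 01 into a compartment chain
(soma + one 6.25 um dendritic compartment per Sholl crossing + 100 um
axon + 250 um apical), applies the d-lambda discretization and attaches
the synapse weight tables.  Writes a per-model summary table.
"""

from pathlib import Path

import pandas as pd

from arborsim.model import build_model
from arborsim.profiles import read_profiles

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    profiles = read_profiles(OUT / "profiles.tsv")
    rows = []
    for p in profiles:
        m = build_model(p)
        rows.append(
            {
                "neuron": p.neuron_id,
                "group": p.group,
                "n_compartments": len(m.compartments),
                "n_segments": sum(c.nseg for c in m.compartments),
                "total_synapses": m.total_synapses,
                "e_fraction": m.synapse_counts[:, 0].sum() / m.total_synapses,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "model_summary.tsv", sep="\t", index=False)
    print(df.groupby("group")[
        ["n_compartments", "total_synapses", "e_fraction"]
    ].mean().round(2))
    print(f"\n{len(df)} models -> {OUT/'model_summary.tsv'}")


if __name__ == "__main__":
    main()
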