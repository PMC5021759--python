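#!/usr/bin/env python
"""Generate the synthetic study data: profile populations and phantoms.

Draws the two direct annulus-profile populations (63 neurons each, the
default treatment contrasts: x1.24 dendrite length, x1.30 complexity,
balanced synapse addition, elevated inhibitory-marker intensity) and a
small rendered phantom population for the imaging benchmark.  Profiles
go to results/profiles.tsv; phantom specs are regenerated on demand by
later steps (rendering is deterministic per seed), so only their
manifest is recorded here.
"""

import json
from pathlib import Path

import numpy as np

from arborsim.profiles import write_profiles
from arborsim.synth.population import (
    ImagingPopulationSpec,
    PopulationSpec,
    generate_population,
    sample_phantom_population,
)

SEED = 20260929
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    pop = PopulationSpec(n_per_group=63, seed=SEED)
    a, b = generate_population(pop)
    write_profiles(OUT / "profiles.tsv", a + b, f"seed={SEED}")
    print(f"wrote {len(a) + len(b)} profiles -> {OUT/'profiles.tsv'}")
    print(f"  -BDNF mean length {np.mean([p.total_length_um for p in a]):.0f} um, "
          f"synapses {np.mean([p.total_synapses for p in a]):.0f}")
    print(f"  +BDNF mean length {np.mean([p.total_length_um for p in b]):.0f} um, "
          f"synapses {np.mean([p.total_synapses for p in b]):.0f}")

    imaging = ImagingPopulationSpec(n_per_group=12, seed=SEED)
    ga, gb = sample_phantom_population(imaging)
    manifest = {
        "seed": SEED,
        "n_per_group": imaging.n_per_group,
        "groups": {
            "-BDNF": [nid for nid, _ in ga],
            "+BDNF": [nid for nid, _ in gb],
        },
    }
    (OUT / "phantom_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"phantom population manifest -> {OUT/'phantom_manifest.json'}")


if __name__ == "__main__":
    main()
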