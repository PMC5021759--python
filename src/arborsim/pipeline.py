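"""End-to-end pipeline driver: seeding, provenance and stage wiring.

One global seed fans out to per-stage seeds through a documented
counter scheme (``SeedSequence((global_seed, stage_index))``), so
stages draw from independent reproducible streams and a rerun with the
same configuration is bit-identical.  Every output file carries a
provenance header (config hash + seed); the run manifest records the
inputs, stage outputs and their content hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cable import BiophysicsConfig
from .mea import analyze_trace_set
from .profiles import write_profiles
from .sweep import SweepConfig, percent_difference_map, rank_models, run_sweep
from .synth.mea import MEATraceSpec, generate_mea_traces
from .synth.population import PopulationSpec, generate_population

STAGES = ("population", "sweep", "mea")


@dataclass
class PipelineConfig:
    """Demo-scale end-to-end run configuration."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_per_group: int = 5
    sweep: SweepConfig = None
    biophysics: BiophysicsConfig = None
    population: PopulationSpec = None
    mea: MEATraceSpec = None
    stages: tuple = STAGES

    def resolved(self):
        cfg = PipelineConfig(**{**asdict_shallow(self)})
        cfg.sweep = self.sweep or SweepConfig(
            strengths=(0.2, 0.6, 1.0),
            apical_lengths_um=(175.0, 250.0, 325.0),
            tau_decay_e_ms=(2.0, 3.0, 4.5),
            tau_decay_i_ms=(6.0, 8.0, 12.0),
            windows_ms=(75.0, 100.0, 150.0),
            excitabilities=(0.75, 1.0, 1.5),
            scheme="one-at-a-time",
        )
        cfg.biophysics = self.biophysics or BiophysicsConfig()
        cfg.population = self.population or PopulationSpec(
            n_per_group=self.n_per_group
        )
        cfg.mea = self.mea or MEATraceSpec(n_electrodes=8, epoch_duration_s=20.0)
        return cfg


def asdict_shallow(obj):
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


def stage_seed(global_seed, stage):
    """Documented fan-out: SeedSequence((global_seed, stage_index))."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence((global_seed, idx)).generate_state(1)[0] % (2**31)
    )


def _hash_file(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def provenance_header(config_hash, seed):
    return f"provenance: config={config_hash} seed={seed} arborsim={__version__}"


def run_pipeline(config: PipelineConfig):
    """Execute synth -> morpho summaries -> models -> sweep -> MEA report.

    Returns the manifest dict (also written to ``manifest.json``).
    Any stage failure aborts with the stage name attached.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(
        {
            "seed": cfg.seed,
            "n_per_group": cfg.n_per_group,
            "stages": list(cfg.stages),
            "sweep": asdict_shallow(cfg.sweep),
            "biophysics": asdict_shallow(cfg.biophysics),
        },
        default=str,
        sort_keys=True,
    )
    config_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    header = provenance_header(config_hash, cfg.seed)
    manifest = {
        "config_hash": config_hash,
        "seed": cfg.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }

    profiles_a = profiles_b = None
    for stage in cfg.stages:
        try:
            if stage == "population":
                pop = cfg.population
                pop.seed = stage_seed(cfg.seed, "population")
                profiles_a, profiles_b = generate_population(pop)
                path = out / "profiles.tsv"
                write_profiles(path, profiles_a + profiles_b, header)
                manifest["outputs"]["profiles"] = str(path)
            elif stage == "sweep":
                if profiles_a is None:
                    raise RuntimeError("sweep stage requires the population stage")
                sweep_cfg = cfg.sweep
                sweep_cfg.seed = stage_seed(cfg.seed, "sweep")
                result = run_sweep(profiles_a, profiles_b, sweep_cfg,
                                   cfg.biophysics)
                path = out / "sweep.tsv"
                with open(path, "w") as fh:
                    fh.write(f"# {header}\n")
                    result.table.to_csv(fh, sep="\t", index=False)
                per_combo, pairs = percent_difference_map(result)
                path2 = out / "percent_difference.tsv"
                with open(path2, "w") as fh:
                    fh.write(f"# {header}\n")
                    per_combo.to_csv(fh, sep="\t", index=False)
                ranking = rank_models(result)
                (out / "ranking.json").write_text(
                    json.dumps({"header": header, "ranking": ranking})
                )
                manifest["outputs"]["sweep"] = str(path)
                manifest["outputs"]["percent_difference"] = str(path2)
                manifest["outputs"]["ranking"] = str(out / "ranking.json")
            elif stage == "mea":
                spec = cfg.mea
                spec.seed = stage_seed(cfg.seed, "mea")
                traces = generate_mea_traces(spec)
                summary, counts = analyze_trace_set(traces)
                path = out / "mea_summary.tsv"
                rows = [
                    {"epoch": k, **v} for k, v in summary.items()
                ]
                with open(path, "w") as fh:
                    fh.write(f"# {header}\n")
                    pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
                manifest["outputs"]["mea_summary"] = str(path)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed ({config_hash})"
            ) from exc

    manifest["hashes"] = {
        name: _hash_file(p) for name, p in manifest["outputs"].items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_config(path):
    """Read a YAML pipeline configuration (flat keys only)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: v for k, v in data.items()
             if k in PipelineConfig.__dataclass_fields__}
    return PipelineConfig(**known)
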