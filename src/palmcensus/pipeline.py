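"""Reproducible orchestration: simulate → discount → group → census → compare.

`run_pipeline` is the programmatic entry point tying the modules
together for a whole synthetic study: several conditions, each with
several independent experiments of several fields, analysed with one
parameter set, aggregated per condition and written to disk together
with a machine-readable run manifest.  Identical configs produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path
from typing import Dict, Tuple

from . import __version__
from .association import AnalysisParams, analyze_field
from .census import CensusSummary, aggregate_condition, census_field, compare_conditions
from .io import write_census, write_field
from .simulate import SimConfig, field_seed, simulate_field

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one synthetic census run.

    ``conditions`` maps a condition name to the SimConfig used for its
    fields (densities / species mixes may differ between conditions);
    each condition is simulated as ``n_experiments`` independent
    experiments of ``n_fields_per_experiment`` fields.  ``seed`` drives
    every stream; per-field substreams are derived from it.
    """

    outdir: str
    conditions: Dict[str, SimConfig]
    analysis: AnalysisParams = dc_field(default_factory=AnalysisParams)
    n_experiments: int = 3
    n_fields_per_experiment: int = 2
    seed: int = 0
    write_fields: bool = True


@dataclass
class PipelineResult:
    summary: CensusSummary
    comparisons: Dict[str, Tuple[float, float]]
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full synthetic chain and write artifacts under ``outdir``.

    Writes per-field localization CSVs (optional), a census TSV + JSON
    sidecar, pairwise condition comparisons (Student's t) and a manifest
    recording parameters, seed and package version.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    field_metrics = []
    stream = 0
    for cond_idx, (condition, sim) in enumerate(sorted(config.conditions.items())):
        for exp in range(config.n_experiments):
            for f in range(config.n_fields_per_experiment):
                sub = field_seed(config.seed, stream)
                stream += 1
                cfg = replace(sim, seed=int(sub.integers(0, 2**31 - 1)))
                field, _truth = simulate_field(cfg)
                field.meta.update(
                    {"condition": condition, "experiment": f"exp{exp}", "field": f}
                )
                if config.write_fields:
                    write_field(
                        field, outdir / f"field_{condition}_exp{exp}_{f}.csv"
                    )
                groups = analyze_field(field, config.analysis)
                metrics = census_field(groups, config.analysis).to_metrics()
                field_metrics.append(
                    (f"{condition}_exp{exp}_f{f}", f"exp{exp}", condition, metrics)
                )

    summary = aggregate_condition(field_metrics)
    write_census(summary, outdir / "census.tsv")

    comparisons: Dict[str, Tuple[float, float]] = {}
    names = sorted(config.conditions)
    metric = "pct_molecules_in_heteromers"
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = summary.condition_values(names[i], metric)
            b = summary.condition_values(names[j], metric)
            if len(a) >= 2 and len(b) >= 2:
                try:
                    comparisons[f"{names[i]} vs {names[j]}"] = compare_conditions(a, b)
                except ValueError:
                    pass

    manifest = {
        "package": "palmcensus",
        "version": __version__,
        "seed": config.seed,
        "n_experiments": config.n_experiments,
        "n_fields_per_experiment": config.n_fields_per_experiment,
        "analysis": {
            k: (v.value if hasattr(v, "value") else v)
            for k, v in asdict(config.analysis).items()
        },
        "conditions": {
            name: {
                k: (
                    [[s["n_a"], s["n_b"], s["fraction"]] for s in v]
                    if k == "species"
                    else v
                )
                for k, v in asdict(sim).items()
            }
            for name, sim in sorted(config.conditions.items())
        },
        "comparisons": {
            k: {"t": t, "p": p} for k, (t, p) in sorted(comparisons.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(summary=summary, comparisons=comparisons, manifest=manifest)
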