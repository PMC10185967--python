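"""End-to-end pipeline: generate/load → score → stratify → mine → network → regress.

Every stage is a pure function of (input cohort, config); given the same
config and seed the written tables are byte-identical. A manifest records
the config hash, seed and record counts so a run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import group_comparison_pvalues, prevalence_table, read_cohort, write_cohort
from .eq5d import VALUE_SETS
from .network import build_network, export_graph
from .panel import HRQOL_GROUPS, POOR_CUTOFF, SEXES, StratumSpec
from .regression import fit_poor_hrqol_model, results_table, univariable_screen
from .rules import lift_matrix, mine_rules, top_rules, write_lift_matrix, write_rules
from .synthetic import SimulationConfig, generate_cohort

log = logging.getLogger("mmnet.pipeline")

DEFAULT_STRATA = [f"{s}:{h}" for s in SEXES for h in ("poor",)] + ["all:poor", "all:normal", "all:good"]


@dataclass
class PipelineConfig:
    """One run's inputs: exactly one of ``input_path`` / ``simulation``."""

    output_dir: str | Path
    input_path: Optional[str | Path] = None
    simulation: Optional[SimulationConfig] = None
    value_set: str = "korean_3l"
    poor_cutoff: float = POOR_CUTOFF
    strata: Sequence[str] = field(default_factory=lambda: list(DEFAULT_STRATA))
    top_k: int = 20
    min_support: float = 0.0
    edge_threshold: float = 0.0
    graph_format: str = "graphml"
    run_regression: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("configure exactly one of input_path / simulation")
        if self.simulation is not None and self.seed is None:
            self.seed = self.simulation.seed
        if self.value_set not in VALUE_SETS:
            raise ValueError(f"unknown value set {self.value_set!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        return cls(**raw)


def _parse_stratum(label: str) -> StratumSpec:
    sex, _, hrqol = label.partition(":")
    return StratumSpec(hrqol=hrqol or "all", sex=sex or "all")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest that is also written to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    manifest: dict = {"mmnet_version": __version__, "stages": []}
    try:
        if config.simulation is not None:
            stage = "simulate"
            sim = config.simulation
            if config.seed is not None and config.seed != sim.seed:
                sim = dataclasses.replace(sim, seed=config.seed)
            cohort = generate_cohort(sim)
            write_cohort(cohort, out / "cohort.csv")
            manifest["simulation_config_hash"] = sim.config_hash()
            manifest["seed"] = sim.seed
        else:
            cohort = read_cohort(config.input_path, poor_cutoff=config.poor_cutoff)
            manifest["input_path"] = str(config.input_path)
        manifest["n_records"] = len(cohort)
        manifest["stages"].append({"stage": stage, "n": len(cohort)})
        log.info("%s: %d records", stage, len(cohort))

        stage = "describe"
        for sex in ("all",) + SEXES:
            frames = []
            for grp in HRQOL_GROUPS:
                spec = StratumSpec(grp, sex)
                tab = prevalence_table(cohort, spec).add_prefix(f"{grp}_")
                frames.append(tab)
            desc = pd.concat(frames, axis=1)
            desc["p_value"] = group_comparison_pvalues(cohort, sex)
            desc.to_csv(out / f"prevalence_{sex}.csv")
        manifest["stages"].append({"stage": stage})

        stage = "rules"
        for label in config.strata:
            spec = _parse_stratum(label)
            rules = mine_rules(cohort, spec, min_support=config.min_support)
            write_rules(rules, out / f"rules_{spec.label}.csv")
            write_rules(top_rules(rules, config.top_k), out / f"top_rules_{spec.label}.csv")
            write_lift_matrix(lift_matrix(cohort, spec), out / f"lift_matrix_{spec.label}.csv")
            manifest["stages"].append({"stage": stage, "stratum": spec.label, "n_rules": len(rules)})

        stage = "network"
        for label in config.strata:
            spec = _parse_stratum(label)
            net = build_network(cohort, spec, edge_threshold=config.edge_threshold)
            suffix = "graphml" if config.graph_format == "graphml" else "edges.csv"
            export_graph(net, out / f"network_{spec.label}.{suffix}", format=config.graph_format)
            net.nodes.to_csv(out / f"network_{spec.label}.nodes.csv")
            manifest["stages"].append({"stage": stage, "stratum": spec.label})

        if config.run_regression:
            stage = "regress"
            multi = fit_poor_hrqol_model(cohort)
            uni = univariable_screen(cohort)
            tab = pd.concat(
                [results_table(uni).assign(model="univariable"),
                 results_table(multi).assign(model="multivariable")],
                ignore_index=True,
            )
            tab.to_csv(out / "regression.csv", index=False)
            manifest["stages"].append({"stage": stage, "n_used": multi.n_obs})
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
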