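"""End-to-end per-neuron wiring analysis.

For each compartment of a reconstruction: extract the critical-point
cloud, measure the real chord wiring length, search for the shortest and
the longest degree/role-respecting arborizations, and report the found
lengths as percentages of the real one.  Dendrites are always solved
whole; axons beyond 200 nodes go through the partitioning pipeline with
both partition methods, keeping the better result per direction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .morphology import extract_critical_cloud, parse_morphology, real_wiring_length
from .partition import DEFAULT_GROUP_SIZES, choose_axon_method, derive_seed
from .ssga import GAConfig, ssga_optimize

__all__ = ["AnalysisConfig", "CompartmentReport", "WiringReport",
           "analyze_neuron", "batch_analyze"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings for a full neuron analysis run."""

    ga: GAConfig = field(default_factory=GAConfig)
    axon_partition_threshold: int = 200
    repeats: int = 20
    junction_window: int = 10
    group_sizes: tuple = DEFAULT_GROUP_SIZES
    skip_dendrites: bool = False
    skip_axon: bool = False
    allow_multifurcations: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        ga = GAConfig.from_dict(raw.pop("ga", {}))
        part = raw.pop("partition", {})
        kw = {}
        for key, target in [
            ("repeats", "repeats"),
            ("junction_window", "junction_window"),
            ("group_sizes", "group_sizes"),
        ]:
            if key in part:
                kw[target] = part[key]
        kw.update(raw)
        if "group_sizes" in kw:
            kw["group_sizes"] = tuple(kw["group_sizes"])
        return cls(ga=ga, **kw)


@dataclass
class CompartmentReport:
    compartment: str
    n_points: int
    n_trees: int
    real_length_um: float
    best_min_length_um: float
    best_max_length_um: float
    min_to_real_percent: float
    max_to_real_percent: float
    method_chosen: str
    seeds: dict
    ga_settings: dict

    def as_row(self, neuron_label: str) -> dict:
        return {
            "neuron": neuron_label,
            "compartment": self.compartment,
            "trees": self.n_trees,
            "points": self.n_points,
            "real_length_um": round(self.real_length_um, 2),
            "min_length_um": round(self.best_min_length_um, 2),
            "max_length_um": round(self.best_max_length_um, 2),
            "min_to_real_percent": round(self.min_to_real_percent, 2),
            "max_to_real_percent": round(self.max_to_real_percent, 2),
            "method": self.method_chosen,
        }


@dataclass
class WiringReport:
    neuron_label: str
    compartments: dict[str, CompartmentReport]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "neuron_label": self.neuron_label,
            "compartments": {
                k: dataclasses.asdict(v) for k, v in self.compartments.items()
            },
            "warnings": self.warnings,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)


def _solve_compartment(cloud, config: AnalysisConfig, direction: str):
    seed = derive_seed(config.ga.seed, 1 if direction == "minimize" else 2)
    cfg = config.ga.with_(direction=direction, seed=seed)
    if (
        cloud.compartment == "axon"
        and cloud.n > config.axon_partition_threshold
    ):
        res = choose_axon_method(
            cloud,
            cfg,
            repeats=config.repeats,
            junction_window=config.junction_window,
            group_sizes=config.group_sizes,
        )
        return res.best_forest.total_length, res.method_chosen, seed
    res = ssga_optimize(cloud, cfg)
    return res.best_length, "unpartitioned", seed


def analyze_neuron(path_or_rec, config: AnalysisConfig | None = None) -> WiringReport:
    """Analyze one neuron file (SWC or Neurolucida ASCII) or parsed
    reconstruction; returns the per-compartment wiring report.  A missing
    compartment yields a warning and a partial report."""
    config = config or AnalysisConfig()
    if isinstance(path_or_rec, (str, os.PathLike)):
        rec = parse_morphology(str(path_or_rec))
    else:
        rec = path_or_rec
    report = WiringReport(neuron_label=rec.neuron_label, compartments={})
    wanted = []
    if not config.skip_dendrites:
        wanted.append("dendrites")
    if not config.skip_axon:
        wanted.append("axon")
    for comp in wanted:
        try:
            cloud = extract_critical_cloud(
                rec, comp, allow_multifurcations=config.allow_multifurcations
            )
        except ValueError as exc:
            msg = f"{comp}: {exc}"
            logger.warning("%s: %s", rec.neuron_label, msg)
            report.warnings.append(msg)
            continue
        real = real_wiring_length(cloud)
        best_min, method_min, seed_min = _solve_compartment(
            cloud, config, "minimize"
        )
        best_max, method_max, seed_max = _solve_compartment(
            cloud, config, "maximize"
        )
        report.compartments[comp] = CompartmentReport(
            compartment=comp,
            n_points=cloud.n,
            n_trees=cloud.t,
            real_length_um=real,
            best_min_length_um=best_min,
            best_max_length_um=best_max,
            min_to_real_percent=100.0 * best_min / real,
            max_to_real_percent=100.0 * best_max / real,
            method_chosen=method_min,
            seeds={"minimize": seed_min, "maximize": seed_max},
            ga_settings=dataclasses.asdict(config.ga),
        )
    return report


def batch_analyze(
    paths: list, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, list[WiringReport]]:
    """Analyze many neuron files; per-file failures are logged and the
    batch continues.  Returns a per-compartment table with a trailing
    aggregate row of arithmetic means, plus the individual reports."""
    if not paths:
        raise ValueError("need at least one path")
    config = config or AnalysisConfig()
    rows = []
    reports = []
    for path in paths:
        try:
            rep = analyze_neuron(path, config)
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.error("failed on %s: %s", path, exc)
            continue
        reports.append(rep)
        for comp in rep.compartments.values():
            rows.append(comp.as_row(rep.neuron_label))
    table = pd.DataFrame(rows)
    if not table.empty:
        means = (
            table.groupby("compartment")
            .mean(numeric_only=True)
            .round(2)
            .reset_index()
        )
        means.insert(0, "neuron", "MEAN")
        means["method"] = ""
        table = pd.concat([table, means], ignore_index=True)
    return table, reports
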