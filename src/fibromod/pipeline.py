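"""Pipeline orchestration: stage chaining, run manifest and text report.

``run_pipeline`` executes the selected stages in method order

    simulate -> deg -> network -> phase-da -> project

writing each stage's artifacts as TSV under the configured output directory
and recording a manifest (config echo, file digests, row counts, warnings).
Identical config and seed give byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import pandas as pd

from . import deg as deg_mod
from . import network as net_mod
from . import phase as phase_mod
from . import project as proj_mod
from . import simulate as sim_mod
from .config import RunConfig

logger = logging.getLogger("fibromod")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages on synthetic data; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_echo(config),
        "stages": {},
        "warnings": [],
        "artifacts": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.time()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                rows = _STAGES[stage](config, state, outdir)
            for w in caught:
                manifest["warnings"].append(f"{stage}: {w.message}")
            manifest["stages"][stage] = {
                "rows": rows, "seconds": round(time.time() - t0, 3)}
            logger.info("stage %s done (%.2fs)", stage, time.time() - t0)
    except StageError:
        _finish(manifest, outdir)
        raise
    except Exception as exc:  # halt with the stage name
        _finish(manifest, outdir)
        raise StageError(stage, exc) from exc
    _finish(manifest, outdir)
    return manifest


def _finish(manifest: dict, outdir: Path) -> None:
    for p in sorted(outdir.glob("*.tsv")):
        manifest["artifacts"][p.name] = _digest(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _config_echo(config: RunConfig) -> dict:
    echo = {
        "seed": config.seed,
        "da_threshold": config.da_threshold,
        "stages": list(config.stages),
        "network": dataclasses.asdict(config.network),
        "projection": dataclasses.asdict(config.projection),
        "simulation": dataclasses.asdict(config.simulation),
    }
    return echo


# --- stages ---------------------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> int:
    expr, design, truth = sim_mod.simulate_invivo(config.simulation)
    sim_mod.write_invivo(outdir, expr, design, truth, config.simulation)
    state.update(expr=expr, design=design, truth=truth)
    return len(expr)


def _require(state: dict, key: str, stage: str) -> object:
    if key not in state:
        raise StageError(stage, RuntimeError(f"missing prerequisite {key!r} "
                                             f"(run earlier stages first)"))
    return state[key]


def _stage_deg(config: RunConfig, state: dict, outdir: Path) -> int:
    expr: pd.DataFrame = _require(state, "expr", "deg")  # type: ignore[assignment]
    design: pd.DataFrame = _require(state, "design", "deg")  # type: ignore[assignment]
    if config.simulation.count_mode:
        expr = deg_mod.cpm_log_normalize(expr)
    n = 0
    tables = {}
    for day in sorted(design["day"].unique()):
        sub = design[design["day"] == day]
        contrast = deg_mod.Contrast(
            treated=tuple(sub.loc[sub["group"] == "treated", "sample_id"]),
            control=tuple(sub.loc[sub["group"] == "control", "sample_id"]),
            label=f"day{day}",
        )
        table = deg_mod.differential_expression(expr, contrast)
        deg_mod.write_deg_table(table, outdir / f"deg_day{day}.tsv")
        tables[day] = table
        n += int(table["is_deg"].sum())
    state["deg_tables"] = tables
    state["normalized"] = expr
    return n


def _stage_network(config: RunConfig, state: dict, outdir: Path) -> int:
    expr: pd.DataFrame = state.get("normalized", state.get("expr"))
    if expr is None:
        raise StageError("network", RuntimeError("missing expression matrix"))
    filtered, dropped = net_mod.drop_zero_variance(expr)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance gene(s)")
    module_set = net_mod.detect_modules(filtered, config.network)
    net_mod.write_modules(module_set, outdir / "modules.tsv",
                          outdir / "eigengenes.tsv")
    state["modules"] = module_set
    return len(module_set.module_ids)


def _stage_phase_da(config: RunConfig, state: dict, outdir: Path) -> int:
    modules: net_mod.ModuleSet = _require(state, "modules", "phase-da")  # type: ignore[assignment]
    design: pd.DataFrame = _require(state, "design", "phase-da")  # type: ignore[assignment]
    phase_map = phase_mod.build_phase_map(design)
    report = phase_mod.phase_activity_report(modules, phase_map,
                                             config.da_threshold)
    report.to_csv(outdir / "phase_activity.tsv", sep="\t", index=False)
    state["phase_report"] = report
    return len(report)


def _stage_project(config: RunConfig, state: dict, outdir: Path) -> int:
    modules: net_mod.ModuleSet = _require(state, "modules", "project")  # type: ignore[assignment]
    truth: sim_mod.TruthLabels = _require(state, "truth", "project")  # type: ignore[assignment]
    import numpy as np

    rng = np.random.default_rng(config.seed + 77)
    panel = sim_mod.default_panel(truth, rng, all_genes=list(truth.labels.index))
    compounds = {"fibrogen": "fibrosis", "inflammin": "inflammation",
                 "blandol": "inert"}
    concentrations = [1.0, 3.0, 10.0, 30.0, 100.0]
    dataset = sim_mod.simulate_invitro(config.simulation, truth, panel,
                                       compounds, concentrations)
    conditions = []
    for (compound, conc), counts in dataset.counts.items():
        design = dataset.designs[(compound, conc)]
        normalized = deg_mod.cpm_log_normalize(counts)
        contrast = deg_mod.Contrast(
            treated=tuple(design.loc[design["group"] == "treated", "sample_id"]),
            control=tuple(design.loc[design["group"] == "control", "sample_id"]),
            label=f"{compound}@{conc}",
        )
        table = deg_mod.differential_expression(normalized, contrast)
        conditions.append(proj_mod.ConditionDEG(compound, conc, table))
    module_genes = {m: modules.module_genes(m) for m in modules.module_ids}
    kme = modules.kme.dropna().to_dict()
    result = proj_mod.project_modules(module_genes, panel, conditions,
                                      config.projection, kme)
    result.activation.to_csv(outdir / "projection_activation.tsv", sep="\t",
                             index=False)
    result.trends.to_csv(outdir / "projection_trends.tsv", sep="\t", index=False)
    result.recurrent.to_csv(outdir / "projection_recurrent.tsv", sep="\t",
                            index=False)
    state["projection"] = result
    return len(result.activation)


_STAGES = {
    "simulate": _stage_simulate,
    "deg": _stage_deg,
    "network": _stage_network,
    "phase-da": _stage_phase_da,
    "project": _stage_project,
}


# --- report ---------------------------------------------------------------


def write_report(outdir: str | Path, path: str | Path | None = None) -> str:
    """Human-readable summary of a pipeline run from its artifacts.

    Missing artifacts mark their section absent rather than failing, so
    partial runs still produce a report.  Regeneration is idempotent.
    """
    outdir = Path(outdir)
    lines = ["fibromod run report", "==================="]

    phase_path = outdir / "phase_activity.tsv"
    lines.append("")
    lines.append("Module phase activity")
    lines.append("---------------------")
    if phase_path.exists():
        report = pd.read_csv(phase_path, sep="\t")
        sel = report[report["selected"]]
        lines.append(f"modules: {len(report)}, selected (DA-based): {len(sel)}")
        cols = ["module_id", "DA_inflammatory", "DA_acute", "DA_late",
                "hub_gene", "assigned_phases"]
        have = [c for c in cols if c in report.columns]
        lines.append(sel.loc[:, have].to_string(index=False))
    else:
        lines.append("[absent]")

    act_path = outdir / "projection_activation.tsv"
    lines.append("")
    lines.append("Projection: module activation per compound")
    lines.append("-------------------------------------------")
    if act_path.exists():
        act = pd.read_csv(act_path, sep="\t")
        summary = (act[act["evaluable"] == True]  # noqa: E712
                   .groupby(["compound", "module_id"])["activated"].any()
                   .groupby("compound").sum().astype(int))
        lines.append("modules activated at any concentration:")
        lines.append(summary.to_string())
    else:
        lines.append("[absent]")

    text = "\n".join(lines) + "\n"
    target = Path(path) if path is not None else outdir / "report.txt"
    target.write_text(text)
    return text
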