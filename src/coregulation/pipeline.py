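"""End-to-end orchestration: config, file loading, result tables.

A :class:`RunConfig` names either a directory of input files (parameter
table, abundance, edge lists, group files, hub lists, optional id mapping)
or a synthetic world configuration. The run functions assemble a
:class:`~coregulation.model.CoregulationModel`, regenerate controls from
recorded seeds, and emit tidy CSV tables plus a JSON manifest, so a rerun
of the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .interactions import (
    GroupTable,
    InteractionSet,
    apply_id_mapping,
    expand_group_pairs,
    read_edge_list,
    read_group_table,
    read_id_mapping,
)
from .model import CoregulationModel, DEFAULT_PARAMETERS
from .nullmodels import shuffle_operons
from .params import ParamsTable, read_params_table
from .synthetic import WorldConfig, simulate_world

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs, with all seeds explicit.

    Exactly one of ``input_dir`` (real-data mode: files by conventional
    names, see :func:`load_inputs`) or ``world`` (synthetic mode) must be
    set.
    """

    world: WorldConfig | None = None
    input_dir: str | None = None
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS
    fold_change_parameter: str = "R"
    n_random: int = 3000
    bootstrap_reps: int = 2000
    bootstrap_method: str = "normal"
    level: float = 0.95
    control_seed: int = 0
    analysis_seed: int = 0
    output_dir: str = "results"
    id_mapping: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        world = raw.pop("world", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "parameters"})
        if "parameters" in raw:
            cfg.parameters = tuple(raw["parameters"])
        if world is not None:
            if "planted_parameters" in world:
                world["planted_parameters"] = tuple(world["planted_parameters"])
            cfg.world = WorldConfig(**world)
        if cfg.world is None and cfg.input_dir is None:
            raise ValueError("config must set either 'world' or 'input_dir'")
        return cfg


@dataclass
class LoadedInputs:
    """The assembled inputs of one species/run."""

    table: ParamsTable
    sets: dict[str, InteractionSet]
    complexes: GroupTable
    operons: GroupTable
    hubs: dict[str, tuple[str, ...]]


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Assemble the parameter table and interaction sets for a run.

    Synthetic mode simulates the configured world; file mode reads
    ``params.tsv``, ``abundance.tsv``, ``binary_edges.tsv``,
    ``complexes.tsv``, ``operons.tsv`` and ``hubs_party.txt`` /
    ``hubs_date.txt`` from ``input_dir`` (missing optional files are
    skipped). ``R`` and ``B`` are derived after loading.
    """
    if config.world is not None:
        world = simulate_world(config.world)
        table = world.analysis_table()
        sets: dict[str, InteractionSet] = {
            "co-complex": expand_group_pairs(world.complexes, "co-complex"),
            "binary": world.binary.relabel("binary"),
        }
        operons = world.operons
        complexes = world.complexes
        hubs = dict(world.hubs)
    else:
        root = Path(config.input_dir)
        table = read_params_table(root / "params.tsv")
        ab_path = root / "abundance.tsv"
        if ab_path.exists():
            table = table.with_abundance(ab_path)
        table = table.with_total_production().with_production_rate()
        mapping = read_id_mapping(config.id_mapping) if config.id_mapping else None
        sets = {}
        complexes = read_group_table(root / "complexes.tsv") if (root / "complexes.tsv").exists() else GroupTable({})
        operons = read_group_table(root / "operons.tsv") if (root / "operons.tsv").exists() else GroupTable({})
        if len(complexes):
            sets["co-complex"] = expand_group_pairs(complexes, "co-complex")
        bin_path = root / "binary_edges.tsv"
        if bin_path.exists():
            binary = read_edge_list(bin_path, label="binary")
            if mapping:
                binary = apply_id_mapping(binary, mapping)
            sets["binary"] = binary
        hubs = {}
        for cls_name, fname in (("party", "hubs_party.txt"), ("date", "hubs_date.txt")):
            p = root / fname
            if p.exists():
                with open(p) as fh:
                    hubs[cls_name] = tuple(line.strip() for line in fh if line.strip())

    if len(operons):
        operon_pairs = expand_group_pairs(operons, "operon")
        if len(operon_pairs):
            sets["operon"] = operon_pairs
    return LoadedInputs(table=table, sets=sets, complexes=complexes,
                        operons=operons, hubs=hubs)


def _build_model(config: RunConfig, inputs: LoadedInputs) -> CoregulationModel:
    model = CoregulationModel(inputs.table, inputs.sets, parameters=config.parameters)
    model.add_controls(n_random=config.n_random, seed=config.control_seed)
    if len(inputs.operons) and "operon" in inputs.sets:
        model.interaction_sets["shuffled-operon"] = shuffle_operons(
            inputs.operons, seed=config.control_seed
        )
    return model


def run_correlation_survey(config: RunConfig, inputs: LoadedInputs | None = None) -> pd.DataFrame:
    """Per-(set, parameter) Spearman correlations with CIs (tidy table)."""
    inputs = inputs or load_inputs(config)
    model = _build_model(config, inputs)
    results = model.fit(seed=config.analysis_seed, level=config.level)
    return results.frame


def run_fold_change_analysis(config: RunConfig, inputs: LoadedInputs | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change summaries per set and all pairwise set differences.

    Returns ``(summaries, differences)``; differences cover medians and
    log-sd for every ordered pair of sets, so the two control sets are
    compared in both directions.
    """
    inputs = inputs or load_inputs(config)
    model = _build_model(config, inputs)
    fc = model.fit_fold_change(
        parameter=config.fold_change_parameter, reps=config.bootstrap_reps,
        method=config.bootstrap_method, level=config.level,
        seed=config.analysis_seed,
    )
    diffs = pd.concat(
        [fc.all_differences("median"), fc.all_differences("sd")],
        ignore_index=True,
    )
    return fc.frame, diffs


def run_hub_analysis(config: RunConfig, inputs: LoadedInputs | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hub-class correlations and party-minus-date Zou intervals."""
    inputs = inputs or load_inputs(config)
    if not inputs.hubs.get("party") or not inputs.hubs.get("date"):
        raise ValueError("hub analysis needs both party and date hub lists")
    model = _build_model(config, inputs)
    networks = [n for n in ("co-complex", "binary") if n in model.interaction_sets]
    hub_res = model.fit_hubs(
        party=inputs.hubs["party"], date=inputs.hubs["date"],
        networks=networks, parameters=config.parameters,
        control_seed=config.control_seed, fit_seed=config.analysis_seed,
        level=config.level,
    )
    return hub_res.correlations, hub_res.difference_frame


def complex_profile(inputs: LoadedInputs, group_id: str,
                    parameters: tuple[str, ...] = ("R",)) -> pd.DataFrame:
    """Per-member parameter profile of one complex or operon.

    The table lists every member with its requested parameters (absent
    stays absent) and appends min/median/max summary rows per parameter —
    the generic machinery behind per-complex production-rate case studies.
    """
    groups = inputs.complexes if group_id in inputs.complexes else inputs.operons
    members = groups.members(group_id)  # KeyError if unknown in both
    frame = pd.DataFrame(index=pd.Index(members, name="gene_id"))
    for p in parameters:
        frame[p] = inputs.table.values_for(p, members)
    summary = pd.DataFrame(
        {p: [np.nanmin(frame[p]), np.nanmedian(frame[p]), np.nanmax(frame[p])]
         if frame[p].notna().any() else [np.nan] * 3
         for p in parameters},
        index=pd.Index(["min", "median", "max"], name="gene_id"),
    )
    return pd.concat([frame, summary])


def run_all(config: RunConfig) -> dict[str, str]:
    """Run every analysis surface and write CSVs plus a JSON manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)

    survey = run_correlation_survey(config, inputs)
    fc_frame, fc_diffs = run_fold_change_analysis(config, inputs)
    written = {
        "correlations": outdir / "correlations.csv",
        "fold_change": outdir / "fold_change.csv",
        "fold_change_differences": outdir / "fold_change_differences.csv",
    }
    survey.to_csv(written["correlations"], index=False)
    fc_frame.to_csv(written["fold_change"], index=False)
    fc_diffs.to_csv(written["fold_change_differences"], index=False)

    if inputs.hubs.get("party") and inputs.hubs.get("date"):
        hub_corr, hub_diff = run_hub_analysis(config, inputs)
        written["hub_correlations"] = outdir / "hub_correlations.csv"
        written["hub_differences"] = outdir / "hub_differences.csv"
        hub_corr.to_csv(written["hub_correlations"], index=False)
        hub_diff.to_csv(written["hub_differences"], index=False)

    manifest = {
        "parameters": list(config.parameters),
        "fold_change_parameter": config.fold_change_parameter,
        "n_random": config.n_random,
        "bootstrap_reps": config.bootstrap_reps,
        "bootstrap_method": config.bootstrap_method,
        "level": config.level,
        "control_seed": config.control_seed,
        "analysis_seed": config.analysis_seed,
        "synthetic": config.world is not None,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    if config.world is not None:
        from .synthetic import _config_to_jsonable

        manifest["world"] = _config_to_jsonable(config.world)
    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    return {k: str(v) for k, v in written.items()}
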