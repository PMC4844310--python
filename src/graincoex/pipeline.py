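"""Configured, logged orchestration: simulate -> screen -> rank -> evaluate.

A run is described by a :class:`RunConfig` (YAML key/value file or built in
code). Every stage writes deterministic TSV outputs plus a JSON run report
echoing the configuration and listing each output file with its row count,
so a run can be audited and reproduced byte-for-byte from config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as gio
from .io import Atlas, MutualRankRecord
from .mutualrank import (mutual_rank_records, select_candidates,
                         MIN_PAIRS_DEFAULT, COMBINE_POLICY_DEFAULT)
from .simulate import (SyntheticAtlasSpec, PlantedTruth, make_atlas,
                       write_atlas, recovery_metrics)
from .specificity import SpecificityRule, screen_family

logger = logging.getLogger("graincoex")

__all__ = ["RunConfig", "PipelineError", "load_config", "load_atlas",
           "run_simulate", "run_screen", "run_rank", "run_evaluate", "run_all"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``experiments`` maps accession -> {"matrix": path, "samples": path};
    empty when the atlas is simulated in-process from ``seed``.
    """

    baits: list[str]
    experiments: dict[str, dict[str, str]] = field(default_factory=dict)
    family: list[str] = field(default_factory=list)
    thresholds: list[float] = field(default_factory=lambda: [20.0, 50.0])
    combine_policy: str = COMBINE_POLICY_DEFAULT
    min_pairs: int = MIN_PAIRS_DEFAULT
    target_tissues: list[str] = field(default_factory=lambda: ["endosperm", "caryopsis"])
    expression_floor: float | None = None
    exclusivity_ratio: float = 0.15
    peak_window: list[str] = field(default_factory=lambda: ["3-4 DAP"])
    duplicate_rule: str = "max_mean"
    missing_token: str = "NA"
    seed: int = 0
    out_dir: str = "graincoex_out"

    def __post_init__(self) -> None:
        if not self.baits:
            raise gio.ValidationError("config needs at least one bait")
        if any(t <= 0 for t in self.thresholds):
            raise gio.ValidationError("MR thresholds must be positive")

    def rule(self) -> SpecificityRule:
        return SpecificityRule(
            target_tissues=frozenset(self.target_tissues),
            expression_floor=self.expression_floor,
            exclusivity_ratio=self.exclusivity_ratio,
            peak_window=frozenset(self.peak_window),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise gio.ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def load_atlas(config: RunConfig) -> Atlas:
    """Read all configured experiments from disk into one atlas."""
    experiments = []
    for acc, paths in config.experiments.items():
        try:
            sheet = gio.read_sample_sheet(paths["samples"])
            exp = gio.read_expression_matrix(
                paths["matrix"], acc, samples=sheet,
                missing_token=config.missing_token,
                duplicate_rule=config.duplicate_rule)
        except (OSError, ValueError) as exc:
            raise PipelineError("load", f"{acc}: {exc}") from exc
        experiments.append(exp)
    if not experiments:
        raise PipelineError("load", "no experiments configured; simulate first "
                                    "or point the config at matrix/sample files")
    return Atlas(experiments)


def _report(config: RunConfig, stage: str, outputs: dict[str, dict],
            extra: dict | None = None, complete: bool = True) -> dict:
    report = {
        "stage": stage,
        "complete": complete,
        "config": asdict(config),
        "outputs": outputs,
    }
    if extra:
        report.update(extra)
    return report


def run_simulate(config: RunConfig,
                 spec: SyntheticAtlasSpec | None = None) -> tuple[Atlas, PlantedTruth]:
    """Generate the default synthetic atlas (seeded from the config) and
    write it to <out_dir>/atlas in the package's TSV formats."""
    spec = spec or SyntheticAtlasSpec(seed=config.seed, baits=tuple(config.baits))
    logger.info("simulate: seed=%d, %d designs, %d background genes",
                spec.seed, len(spec.designs), spec.n_background_genes)
    atlas, truth = make_atlas(spec)
    out = Path(config.out_dir) / "atlas"
    manifest = write_atlas(atlas, truth, out)
    config.experiments = {
        acc: {"matrix": m["matrix"], "samples": m["samples"]}
        for acc, m in manifest["experiments"].items()
    }
    gio.write_run_report(_report(config, "simulate", manifest["experiments"]),
                         Path(config.out_dir) / "simulate.report.json")
    return atlas, truth


def run_screen(config: RunConfig, atlas: Atlas | None = None) -> Path:
    """Exclusivity screen of the configured gene family; writes
    specificity.tsv and its report."""
    atlas = atlas or load_atlas(config)
    family = config.family or sorted(
        {g for e in atlas.experiments for g in e.gene_ids})
    rule = config.rule()
    logger.info("screen: %d family members, target tissues %s, ratio %.3g",
                len(family), sorted(rule.target_tissues), rule.exclusivity_ratio)
    try:
        calls = screen_family(atlas, family, rule)
    except ValueError as exc:
        raise PipelineError("screen", str(exc)) from exc
    out = Path(config.out_dir) / "specificity.tsv"
    gio.write_specificity_table(calls, out)
    gio.write_run_report(
        _report(config, "screen",
                {"specificity": {"path": str(out), "rows": len(calls)}},
                extra={"n_exclusive": sum(1 for c in calls if c.exclusive)}),
        Path(config.out_dir) / "screen.report.json")
    return out


def run_rank(config: RunConfig, atlas: Atlas | None = None
             ) -> tuple[list[MutualRankRecord], dict[float, "object"]]:
    """Mutual-rank meta-analysis: full MR table plus one candidate table per
    configured threshold."""
    atlas = atlas or load_atlas(config)
    logger.info("rank: baits=%s, combine=%s, min_pairs=%d, thresholds=%s "
                "(ties: average rank; self excluded; strict '<' at threshold)",
                config.baits, config.combine_policy, config.min_pairs,
                config.thresholds)
    missing = [b for b in config.baits
               if all(b not in e.gene_ids for e in atlas.experiments)]
    if missing:
        raise PipelineError("rank", f"baits absent from every experiment: {missing}")
    records = mutual_rank_records(atlas, config.baits,
                                  min_pairs=config.min_pairs,
                                  policy=config.combine_policy)
    out_dir = Path(config.out_dir)
    full = out_dir / "mutual_ranks.tsv"
    gio.write_candidate_table(records, full)
    outputs = {"mutual_ranks": {"path": str(full), "rows": len(records)}}
    candidate_sets = {}
    for thr in config.thresholds:
        cs = select_candidates(records, config.baits, thr)
        candidate_sets[thr] = cs
        path = out_dir / f"candidates_mr{int(thr) if thr == int(thr) else thr}.tsv"
        rows = [MutualRankRecord(b, g, {}, cs.members.at[g, b], 0)
                for g in cs.gene_ids for b in cs.baits]
        gio.write_candidate_table(rows, path)
        outputs[f"candidates_mr<{thr:g}"] = {"path": str(path), "rows": len(cs)}
    gio.write_run_report(_report(config, "rank", outputs),
                         out_dir / "rank.report.json")
    return records, candidate_sets


def run_evaluate(config: RunConfig, truth: PlantedTruth,
                 candidate_sets: dict | None = None,
                 atlas: Atlas | None = None) -> dict:
    """Precision/recall of each candidate table against planted truth."""
    if candidate_sets is None:
        _, candidate_sets = run_rank(config, atlas)
    metrics = {}
    for thr, cs in candidate_sets.items():
        precision, recall = recovery_metrics(cs, truth)
        metrics[f"mr<{thr:g}"] = {
            "precision": precision, "recall": recall,
            "n_candidates": len(cs),
        }
    out = Path(config.out_dir) / "evaluation.json"
    gio.write_run_report(_report(config, "evaluate", {
        "evaluation": {"path": str(out), "rows": len(metrics)}},
        extra={"metrics": metrics}), out)
    return metrics


def run_all(config: RunConfig,
            spec: SyntheticAtlasSpec | None = None,
            truth: PlantedTruth | None = None) -> dict:
    """simulate (when no experiments configured) -> screen -> rank ->
    evaluate (when truth is known); returns the overall run report."""
    outputs: dict[str, dict] = {}
    complete = False
    try:
        if config.experiments:
            atlas = load_atlas(config)
        else:
            atlas, truth = run_simulate(config, spec)
        screen_path = run_screen(config, atlas)
        outputs["specificity"] = {"path": str(screen_path)}
        records, candidate_sets = run_rank(config, atlas)
        outputs["n_mr_records"] = {"rows": len(records)}
        metrics = None
        if truth is not None:
            metrics = run_evaluate(config, truth, candidate_sets, atlas)
        complete = True
    finally:
        report = _report(config, "all", outputs, complete=complete,
                         extra={"metrics": metrics} if complete else None)
        gio.write_run_report(report, Path(config.out_dir) / "run.report.json")
    return report
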