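"""Tissue/stage expression-exclusivity screen and condition profiles.

Classifies genes as expressed exclusively during caryopsis development with
endosperm-restricted expression and a defined developmental peak (days after
pollination). "Expressed" is decided on condition-group means (mean over
replicates of one (tissue, stage, genotype) group), never on single samples:
a gene is *exclusive* when its best target-tissue group mean rises clearly
above an expression floor while every off-target group mean stays within a
tolerated fraction of that rise.

Also provides the per-gene condition profile (group mean +/- standard error)
and the wild-type vs mutant genotype contrast used for per-gene comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Atlas, ExpressionExperiment, ValidationError

__all__ = [
    "SpecificityRule",
    "ConditionProfile",
    "SpecificityCall",
    "GroupComparison",
    "condition_profile",
    "classify_specificity",
    "screen_family",
    "compare_genotypes",
]

DEFAULT_TARGET_TISSUES = frozenset({"endosperm", "caryopsis"})

# Canonical developmental windows used when rendering labels: fine-grained
# time-course stages (e.g. "6 DAP") collapse onto these for reporting, so a
# label reads "3-4 DAP, 5-10 DAP, endosperm" rather than listing every day.
REPORT_WINDOWS: tuple[tuple[str, float, float], ...] = (
    ("before anthesis", -math.inf, 0.0),
    ("1-2 DAP", 0.0, 2.5),
    ("3-4 DAP", 2.5, 4.75),
    ("5-10 DAP", 4.75, 10.5),
    ("11-20 DAP", 10.5, 20.5),
    (">20 DAP", 20.5, math.inf),
)


def _report_window(stage_pos: float) -> str:
    for label, lo, hi in REPORT_WINDOWS:
        if lo <= stage_pos < hi:
            return label
    return f"{stage_pos:g} DAP"


@dataclass(frozen=True)
class SpecificityRule:
    """Parameters operationalizing "expressed exclusively during caryopsis
    development".

    expression_floor
        Minimum log2 group mean to call a gene expressed. ``None`` means
        auto: the 25th percentile of each experiment's value distribution
        (robust to array background level).
    exclusivity_ratio
        Largest tolerated ratio of (off-target rise above floor) to (best
        target rise above floor); 0 demands literally no off-target signal.
    peak_window
        Stage labels where the peak is expected (informational; the peak
        itself is the argmax over target-group means).
    """

    target_tissues: frozenset[str] = DEFAULT_TARGET_TISSUES
    expression_floor: float | None = None
    exclusivity_ratio: float = 0.15
    peak_window: frozenset[str] = frozenset({"3-4 DAP"})

    def __post_init__(self) -> None:
        if not (0.0 <= self.exclusivity_ratio < 1.0):
            raise ValidationError("exclusivity_ratio must be in [0, 1)")
        if not self.target_tissues:
            raise ValidationError("target_tissues must be non-empty")
        if not self.peak_window:
            raise ValidationError("peak_window must be non-empty")

    def floor_for(self, experiment: ExpressionExperiment) -> float:
        if self.expression_floor is not None:
            return float(self.expression_floor)
        vals = experiment.values.to_numpy(dtype=float)
        return float(np.nanpercentile(vals, 25.0))


@dataclass
class ConditionProfile:
    """Per-(tissue, stage, genotype) mean, SE and replicate count of one gene.

    ``groups`` has columns tissue, stage, genotype, stage_pos, mean, se, n;
    SE is NaN (reported not-available) when n == 1. Groups whose replicates
    are all missing are omitted.
    """

    gene: str
    accession: str
    groups: pd.DataFrame


def condition_profile(experiment: ExpressionExperiment, gene: str) -> ConditionProfile:
    """Group-wise mean +/- standard error profile of one gene."""
    if gene not in experiment.values.index:
        raise KeyError(f"gene {gene!r} absent from {experiment.accession}")
    x = experiment.values.loc[gene]
    ann = experiment.annotations_for()
    rows = []
    for (tissue, stage, genotype), members in ann.groupby(
            ["tissue", "stage", "genotype"], sort=False):
        vals = x.loc[members.index].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = vals.size
        if n == 0:
            continue
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({
            "tissue": tissue, "stage": stage, "genotype": genotype,
            "stage_pos": float(members["stage_pos"].iloc[0]),
            "mean": float(vals.mean()), "se": se, "n": int(n),
        })
    return ConditionProfile(gene, experiment.accession, pd.DataFrame(
        rows, columns=["tissue", "stage", "genotype", "stage_pos", "mean", "se", "n"]))


@dataclass
class SpecificityCall:
    """Verdict of the exclusivity screen for one gene.

    ``status`` is "ok", "indeterminate" (gene never measured alongside
    off-target tissue, so exclusivity cannot be decided) or "not_measured".
    ``label`` renders Table-style as "<peak stage>[, <secondary stage>...],
    <tissue>" for exclusive genes.
    """

    gene: str
    exclusive: bool | None
    expressed_groups: list[tuple[str, str]] = field(default_factory=list)
    peak_stage: str | None = None
    label: str | None = None
    status: str = "ok"


def _collect_group_means(
    atlas_or_profiles: Atlas | Iterable[ConditionProfile],
    gene: str | None,
    rule: SpecificityRule,
) -> tuple[pd.DataFrame, bool]:
    """Flatten per-experiment profiles to (group, mean, floor) rows.

    Returns the table plus a flag telling whether any contributing
    experiment contains off-target tissue (needed for determinacy).
    """
    frames = []
    saw_off_target_design = False
    if isinstance(atlas_or_profiles, Atlas):
        profiles = []
        for exp in atlas_or_profiles.experiments:
            exp_tissues = set(exp.samples["tissue"])
            if exp_tissues - rule.target_tissues:
                has_off = True
            else:
                has_off = False
            if gene in exp.values.index:
                prof = condition_profile(exp, gene)
                prof.groups = prof.groups.assign(floor=rule.floor_for(exp))
                profiles.append(prof)
                saw_off_target_design = saw_off_target_design or has_off
        frames = [p.groups for p in profiles]
    else:
        for prof in atlas_or_profiles:
            g = prof.groups
            if "floor" not in g.columns:
                raise ValueError("profiles must carry a 'floor' column; build "
                                 "them via classify-from-atlas or annotate floors")
            frames.append(g)
            if set(g["tissue"]) - rule.target_tissues:
                saw_off_target_design = True
    if not frames:
        return pd.DataFrame(columns=["tissue", "stage", "stage_pos", "mean", "floor"]), False
    return pd.concat(frames, ignore_index=True), saw_off_target_design


def classify_specificity(
    source: Atlas | Iterable[ConditionProfile],
    gene: str,
    rule: SpecificityRule | None = None,
) -> SpecificityCall:
    """Exclusivity call for one gene over all experiments of an atlas.

    exclusive = yes iff the best target-tissue group mean exceeds the floor
    and every off-target group mean stays below
    ``floor + exclusivity_ratio * (best_target_mean - floor)``.
    The peak stage is the argmax over target group means; ties break toward
    the earlier stage (developmental peaks are reported at onset).
    """
    rule = rule or SpecificityRule()
    groups, saw_off_target = _collect_group_means(source, gene, rule)
    if groups.empty:
        return SpecificityCall(gene, None, status="not_measured")
    if not saw_off_target:
        return SpecificityCall(gene, None, status="indeterminate")

    is_target = groups["tissue"].isin(rule.target_tissues)
    target = groups[is_target]
    off = groups[~is_target]
    if target.empty:
        return SpecificityCall(gene, False, status="ok",
                               label=None, expressed_groups=[])

    best_idx = None
    best_key = None
    for idx, row in target.iterrows():
        key = (-(row["mean"] - row["floor"]), row["stage_pos"])
        if best_key is None or key < best_key:
            best_key, best_idx = key, idx
    best = target.loc[best_idx]
    best_rise = float(best["mean"] - best["floor"])

    expressed_target = target[target["mean"] > target["floor"]]
    expressed_groups = sorted(
        {(r["tissue"], r["stage"]) for _, r in expressed_target.iterrows()},
        key=lambda ts: float(target[target["stage"] == ts[1]]["stage_pos"].iloc[0]),
    )

    exclusive = best_rise > 0 and bool(
        (off["mean"] <= off["floor"] + rule.exclusivity_ratio * best_rise).all()
    )

    peak_stage = None
    label = None
    if best_rise > 0:
        # peak = argmax of target means, earliest stage on ties
        tie_tol = 1e-9
        tied = target[np.abs(target["mean"] - best["mean"]) <= tie_tol]
        peak_row = tied.loc[tied["stage_pos"].idxmin()]
        peak_stage = str(peak_row["stage"])
        peak_window = _report_window(float(peak_row["stage_pos"]))
        windows = []
        for _, r in expressed_target.sort_values("stage_pos").iterrows():
            w = _report_window(float(r["stage_pos"]))
            if w not in windows:
                windows.append(w)
        if peak_window in windows:
            windows.remove(peak_window)
        label = ", ".join([peak_window, *windows, str(best["tissue"])])

    return SpecificityCall(
        gene, exclusive, expressed_groups=expressed_groups,
        peak_stage=peak_stage if exclusive else peak_stage,
        label=label if exclusive else label, status="ok",
    )


def screen_family(
    atlas: Atlas,
    family: Sequence[str],
    rule: SpecificityRule | None = None,
) -> list[SpecificityCall]:
    """Exclusivity screen over a gene family; one call per member.

    Members absent from every experiment come back with status
    "not_measured"; members never observed alongside off-target tissue are
    "indeterminate" (never silently exclusive).
    """
    if not family:
        raise ValueError("family must be non-empty")
    rule = rule or SpecificityRule()
    return [classify_specificity(atlas, gene, rule) for gene in family]


@dataclass
class GroupComparison:
    """Mean +/- SE of one gene in two genotype groups and their linear ratio."""

    gene: str
    group_a: str
    mean_a: float
    se_a: float
    n_a: int
    group_b: str
    mean_b: float
    se_b: float
    n_b: int
    ratio: float  # linear-scale B/A


def compare_genotypes(
    experiment: ExpressionExperiment,
    gene: str,
    genotype_a: str,
    genotype_b: str,
    log2_input: bool = True,
) -> GroupComparison:
    """Wild-type vs mutant style contrast: per-genotype mean, SE and the
    linear fold ratio B/A (2**(meanB - meanA) on log2 input)."""
    if gene not in experiment.values.index:
        raise KeyError(f"gene {gene!r} absent from {experiment.accession}")
    x = experiment.values.loc[gene]
    ann = experiment.annotations_for()
    stats = {}
    for label in (genotype_a, genotype_b):
        members = ann.index[ann["genotype"] == label]
        if len(members) == 0:
            raise KeyError(f"genotype {label!r} absent from {experiment.accession}")
        vals = x.loc[members].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise KeyError(f"genotype {label!r} has no measured replicates for {gene!r}")
        se = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
        stats[label] = (float(vals.mean()), se, int(vals.size))
    (ma, sa, na), (mb, sb, nb) = stats[genotype_a], stats[genotype_b]
    ratio = float(2.0 ** (mb - ma)) if log2_input else float(mb / ma)
    return GroupComparison(gene, genotype_a, ma, sa, na,
                           genotype_b, mb, sb, nb, ratio)
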