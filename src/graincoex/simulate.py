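"""Synthetic multi-experiment expression atlases with a planted coexpressed,
endosperm-exclusive gene module.

The generator emulates a meta-analysis setting where several microarray
experiments of heterogeneous design (one tissue-diverse atlas, one dense
early grain time-course, one reproductive series) are mined jointly. A small
module of genes — including the baits — is planted so that it is (a)
expressed only in endosperm/caryopsis samples with a peak at 3-4 days after
pollination (DAP), declining by 10 DAP, and (b) tightly mutually correlated
through a shared per-sample latent factor with loading set by ``rho``
(pairwise residual correlation concentrates near ``rho``). Background genes
receive independent random group profiles. All values are on a log2
(RMA-like) scale; replicate noise is Gaussian in log2 units.

At ``rho = 0`` nothing is planted to co-vary with the baits: the baits keep
the endosperm-peak profile but the remaining module genes degenerate to
independent background-like genes — the null control for candidate counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Atlas, ExpressionExperiment, ValidationError, parse_stage
from .mutualrank import CandidateSet

__all__ = [
    "GroupDesign",
    "ExperimentDesign",
    "SyntheticAtlasSpec",
    "PlantedTruth",
    "default_designs",
    "make_atlas",
    "write_atlas",
    "recovery_metrics",
]


@dataclass(frozen=True)
class GroupDesign:
    """One condition group of an experiment design."""

    tissue: str
    stage: str
    genotype: str = "wild type"
    n_replicates: int = 3


@dataclass(frozen=True)
class ExperimentDesign:
    accession: str
    groups: tuple[GroupDesign, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError(f"{self.accession}: designs need >= 2 groups")
        if any(g.n_replicates < 1 for g in self.groups):
            raise ValidationError(f"{self.accession}: 0-replicate group in design")


def default_designs() -> tuple[ExperimentDesign, ...]:
    """Three heterogeneous designs mirroring a typical public-atlas mix:

    - ``TISSUE_ATLAS``: tissue-diverse survey (leaf, root, seedling, embryo,
      endosperm) — the design that makes exclusivity decidable;
    - ``GRAIN_TIMECOURSE``: dense daily endosperm series 1-10 DAP;
    - ``REPRO_SERIES``: reproductive development from before anthesis to
      late grain-fill.
    """
    atlas = ExperimentDesign("TISSUE_ATLAS", (
        GroupDesign("leaf", "vegetative"),
        GroupDesign("root", "vegetative"),
        GroupDesign("seedling", "vegetative"),
        GroupDesign("shoot", "vegetative"),
        GroupDesign("embryo", "3-4 DAP"),
        GroupDesign("embryo", "5-10 DAP"),
        GroupDesign("endosperm", "3-4 DAP"),
        GroupDesign("endosperm", "5-10 DAP"),
    ))
    timecourse = ExperimentDesign("GRAIN_TIMECOURSE", tuple(
        GroupDesign("endosperm", f"{d} DAP", n_replicates=2) for d in range(1, 11)
    ))
    repro = ExperimentDesign("REPRO_SERIES", (
        GroupDesign("panicle", "before anthesis"),
        GroupDesign("stigma", "anthesis"),
        GroupDesign("endosperm", "1 DAP"),
        GroupDesign("endosperm", "3-4 DAP"),
        GroupDesign("endosperm", "5-10 DAP"),
        GroupDesign("caryopsis", "15 DAP"),
        GroupDesign("caryopsis", "20 DAP"),
    ))
    return (atlas, timecourse, repro)


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Parameters of the simulated atlas.

    n_module_genes counts the whole planted module *including* the baits.
    ``rho`` is the target pairwise correlation of module residuals (latent
    factor loading sqrt(rho)); ``leakage`` is the fraction of the peak
    amplitude that bleeds into off-target tissues (0 = perfectly exclusive);
    ``noise_sd`` is the replicate-level Gaussian sd in log2 units;
    ``baseline`` the unexpressed log2 level and ``amplitude`` the peak rise
    above it.
    """

    designs: tuple[ExperimentDesign, ...] = field(default_factory=default_designs)
    n_background_genes: int = 500
    baits: tuple[str, ...] = ("BAIT_YUC", "BAIT_IAA", "BAIT_INH")
    n_module_genes: int = 6
    rho: float = 0.95
    leakage: float = 0.0
    noise_sd: float = 0.2
    baseline: float = 4.0
    amplitude: float = 6.0
    peak_dap: float = 3.5
    decline_dap: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValidationError("rho must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_module_genes < len(self.baits):
            raise ValidationError("module must contain at least the baits")
        if self.leakage < 0:
            raise ValidationError("leakage must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of the planted module."""

    module_genes: list[str]          # includes baits
    baits: list[str]
    exclusive_flags: dict[str, bool]
    profiles: dict[str, str]         # per-gene human-readable intent

    @property
    def non_bait_module(self) -> list[str]:
        return [g for g in self.module_genes if g not in self.baits]


TARGET_TISSUES = {"endosperm", "caryopsis"}


def _stage_template(dap: float, peak: float, decline: float) -> float:
    """Unimodal 0..1 stage curve: rises to 1 at ``peak`` DAP, back to 0 by
    ``decline`` DAP (piecewise linear on the DAP axis)."""
    if dap <= 0:
        return 0.0
    if dap <= peak:
        return dap / peak
    if dap >= decline:
        return 0.0
    return (decline - dap) / (decline - peak)


def make_atlas(spec: SyntheticAtlasSpec) -> tuple[Atlas, PlantedTruth]:
    """Generate the atlas and its planted truth, deterministic under
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    baits = list(spec.baits)
    module = baits + [f"MOD_{i:02d}" for i in range(1, spec.n_module_genes - len(baits) + 1)]
    background = [f"BG_{i:04d}" for i in range(1, spec.n_background_genes + 1)]
    genes = module + background

    # planted module behaves as background when rho == 0 (null control)
    planted = module if spec.rho > 0 else baits
    scales = {g: spec.amplitude * rng.uniform(0.8, 1.2) for g in module}

    # Background genes get assorted but non-grain-specific profiles: each has
    # a "home" off-target tissue where it sits at its full per-gene level
    # e_g; in every other tissue it gets a uniformly scaled base level that
    # varies *smoothly* along the DAP axis (developmental expression is
    # autocorrelated, not independent per stage). Group means are cached per
    # (gene, tissue, stage) so a gene is consistent across experiments.
    off_target_tissues = sorted({
        g.tissue for d in spec.designs for g in d.groups
        if g.tissue not in TARGET_TISSUES
    })
    non_planted = [g for g in genes if g not in planted]
    bg_level = {g: float(rng.uniform(2.0, 6.0)) for g in non_planted}
    bg_home = {
        g: (off_target_tissues[int(rng.integers(len(off_target_tissues)))]
            if off_target_tissues else None)
        for g in non_planted
    }
    bg_group_means: dict[tuple[str, str, str], float] = {}

    def background_mean(gene: str, tissue: str, stage: str) -> float:
        key = (gene, tissue, stage)
        if key not in bg_group_means:
            if tissue == bg_home[gene]:
                level = bg_level[gene]
            else:
                level = float(rng.uniform(0.0, 1.0)) * bg_level[gene]
            bg_group_means[key] = spec.baseline + level
        return bg_group_means[key]

    experiments = []
    for design in spec.designs:
        sample_rows = []
        for g in design.groups:
            for rep in range(1, g.n_replicates + 1):
                sample_rows.append({
                    "sample_id": f"{design.accession}_{g.tissue}_{g.stage}_{g.genotype}_r{rep}"
                        .replace(" ", ""),
                    "tissue": g.tissue, "stage": g.stage,
                    "genotype": g.genotype, "replicate": rep,
                    "stage_pos": parse_stage(g.stage),
                })
        samples = pd.DataFrame(sample_rows).set_index("sample_id")
        n_s = len(samples)

        # deterministic group-mean layer
        means = np.empty((len(genes), n_s))
        for gi, gene in enumerate(genes):
            for si, (sid, srow) in enumerate(samples.iterrows()):
                tissue, stage = srow["tissue"], srow["stage"]
                if gene in planted:
                    if tissue in TARGET_TISSUES:
                        t = _stage_template(srow["stage_pos"], spec.peak_dap,
                                            spec.decline_dap)
                        means[gi, si] = spec.baseline + scales[gene] * t
                    else:
                        means[gi, si] = spec.baseline + spec.leakage * scales[gene]
                else:
                    means[gi, si] = background_mean(gene, tissue, stage)

        # noise layer: shared latent factor across planted module + residual
        factor = rng.normal(0.0, 1.0, size=n_s)
        noise = rng.normal(0.0, 1.0, size=(len(genes), n_s))
        values = means.copy()
        a = spec.noise_sd * math.sqrt(spec.rho)
        b = spec.noise_sd * math.sqrt(1.0 - spec.rho)
        for gi, gene in enumerate(genes):
            if gene in planted:
                values[gi] += a * factor + b * noise[gi]
            else:
                values[gi] += spec.noise_sd * noise[gi]

        experiments.append(ExpressionExperiment(
            design.accession,
            pd.DataFrame(values, index=genes, columns=samples.index),
            samples,
        ))

    exclusive = {g: (g in planted and spec.leakage == 0.0) for g in genes}
    profiles = {}
    for g in genes:
        if g in planted:
            profiles[g] = (f"endosperm-exclusive, peak {spec.peak_dap} DAP, "
                           f"decline by {spec.decline_dap} DAP")
        elif g in module:
            profiles[g] = "background-like (null module member, rho=0)"
        else:
            profiles[g] = "independent background"
    truth = PlantedTruth(module, baits, exclusive, profiles)
    return Atlas(experiments), truth


def write_atlas(atlas: Atlas, truth: PlantedTruth, out_dir: str | Path) -> dict:
    """Write matrices + sample sheets in the package's TSV formats plus
    truth.json; returns a manifest of written paths."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"experiments": {}}
    for exp in atlas.experiments:
        mpath = out / f"{exp.accession}.matrix.tsv"
        spath = out / f"{exp.accession}.samples.tsv"
        vals = exp.values.copy()
        vals.index.name = "gene_id"
        vals.to_csv(mpath, sep="\t", float_format="%.6g", na_rep="NA")
        sheet = exp.samples.reset_index()[
            ["sample_id", "tissue", "stage", "genotype", "replicate"]]
        sheet.to_csv(spath, sep="\t", index=False)
        manifest["experiments"][exp.accession] = {
            "matrix": str(mpath), "samples": str(spath),
            "n_genes": len(exp.gene_ids), "n_samples": len(exp.sample_ids),
        }
    tpath = out / "truth.json"
    with open(tpath, "w", encoding="utf-8") as fh:
        json.dump({
            "module_genes": truth.module_genes,
            "baits": truth.baits,
            "exclusive_flags": truth.exclusive_flags,
            "profiles": truth.profiles,
        }, fh, indent=2)
    manifest["truth"] = str(tpath)
    return manifest


def recovery_metrics(
    candidates: CandidateSet | Sequence[str],
    truth: PlantedTruth,
) -> tuple[float | None, float]:
    """Precision/recall of a candidate set against the planted module.

    Recall is over non-bait module genes (baits are the query, never a
    discovery). Precision is None (undefined) for an empty candidate set.
    """
    found = set(candidates.gene_ids if isinstance(candidates, CandidateSet)
                else candidates)
    module = set(truth.non_bait_module)
    hits = found & set(truth.module_genes)
    precision = None if not found else len(hits) / len(found)
    recall = 0.0 if not module else len(hits & module) / len(module)
    return precision, recall
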