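"""Mutual-rank coexpression statistics against bait genes.

The mutual rank (MR) of a gene pair (a, b) within one experiment is

    MR(a, b) = sqrt( rank_a(b) * rank_b(a) )

where rank_a(b) is the position of b when all other genes are ordered by
decreasing Pearson correlation with a (self excluded, ties as average ranks).
MR is symmetric, bounded by 1 <= MR <= G-1 for G rankable genes, and low MR
means strong mutual coexpression. Per-experiment MRs against each bait are
combined across experiments (worst-case ``max`` by default; geometric mean
available) and genes whose combined MR falls under a threshold for *every*
bait form the candidate set.

Correlations are computed at replicate level on pairwise-complete samples;
genes with zero variance or fewer than ``min_pairs`` complete pairs are
excluded from ranking in that experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import Atlas, ExpressionExperiment, MutualRankRecord

__all__ = [
    "UndefinedCorrelationError",
    "MIN_PAIRS_DEFAULT",
    "COMBINE_POLICY_DEFAULT",
    "CorrelationVector",
    "CandidateSet",
    "pearson",
    "correlation_matrix",
    "correlation_vector",
    "rank_matrix",
    "mutual_rank_matrix",
    "mutual_rank",
    "bait_mr_series",
    "combine_across_experiments",
    "mutual_rank_records",
    "select_candidates",
]

MIN_PAIRS_DEFAULT = 4


class UndefinedCorrelationError(ValueError):
    """Raised when r is requested for a pair with zero variance or too few pairs."""


def pearson(x: Sequence[float], y: Sequence[float], min_pairs: int = 3) -> float:
    """Product-moment correlation on pairwise-complete observations.

    Raises :class:`UndefinedCorrelationError` for fewer than ``min_pairs``
    complete pairs or zero variance in either series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        raise UndefinedCorrelationError(f"only {x.size} complete pairs (< {min_pairs})")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


@dataclass
class CorrelationVector:
    """Per-gene correlations with one bait in one experiment."""

    accession: str
    bait: str
    r: pd.Series                      # index: gene id, value: Pearson r
    n_pairs: pd.Series                # complete observations used per pair
    excluded: dict[str, str] = field(default_factory=dict)  # gene -> reason


def correlation_matrix(
    experiment: ExpressionExperiment, min_pairs: int = MIN_PAIRS_DEFAULT
) -> pd.DataFrame:
    """All-pairs pairwise-complete Pearson matrix over rankable genes.

    Genes with zero variance (over their own complete samples) are dropped;
    individual pairs with fewer than ``min_pairs`` complete observations get
    NaN. The diagonal is NaN (self-pairs never enter a ranking).
    """
    X = experiment.values.to_numpy(dtype=float)
    genes = np.asarray(experiment.gene_ids)
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(X, axis=1)
    counts = np.sum(~np.isnan(X), axis=1)
    rankable = (variances > 0) & (counts >= min_pairs)
    X = X[rankable]
    genes = genes[rankable]

    if np.isnan(X).any():
        df = pd.DataFrame(X.T, columns=genes)
        C = df.corr(method="pearson", min_periods=min_pairs).to_numpy()
        # pairwise-complete subsets can still be degenerate; corr() yields NaN there
    else:
        if X.shape[0] == 0:
            C = np.empty((0, 0))
        else:
            C = np.corrcoef(X)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, np.nan)
    return pd.DataFrame(C, index=genes, columns=genes)


def correlation_vector(
    experiment: ExpressionExperiment, bait: str, min_pairs: int = MIN_PAIRS_DEFAULT
) -> CorrelationVector:
    """Pearson r of every other gene against ``bait`` with exclusion reasons."""
    if bait not in experiment.values.index:
        raise KeyError(f"bait {bait!r} absent from {experiment.accession}")
    b = experiment.values.loc[bait].to_numpy(dtype=float)
    r: dict[str, float] = {}
    n: dict[str, int] = {}
    excluded: dict[str, str] = {}
    for gene in experiment.gene_ids:
        if gene == bait:
            continue
        g = experiment.values.loc[gene].to_numpy(dtype=float)
        ok = ~(np.isnan(b) | np.isnan(g))
        n_pairs = int(ok.sum())
        if n_pairs < min_pairs:
            excluded[gene] = f"only {n_pairs} complete pairs"
            continue
        try:
            r[gene] = pearson(b, g, min_pairs=min_pairs)
            n[gene] = n_pairs
        except UndefinedCorrelationError as exc:
            excluded[gene] = str(exc)
    return CorrelationVector(experiment.accession, bait,
                             pd.Series(r, dtype=float), pd.Series(n, dtype=int),
                             excluded)


def rank_matrix(corr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise descending-correlation ranks with average-rank ties.

    Entry (a, b) is rank_a(b): the rank of gene b among gene a's correlation
    partners (1 = most correlated). NaN correlations stay NaN and do not
    consume ranks.
    """
    C = corr.to_numpy(dtype=float)
    R = np.full_like(C, np.nan)
    for i in range(C.shape[0]):
        row = C[i]
        ok = ~np.isnan(row)
        if ok.any():
            R[i, ok] = rankdata(-row[ok], method="average")
    return pd.DataFrame(R, index=corr.index, columns=corr.columns)


def mutual_rank_matrix(
    experiment: ExpressionExperiment, min_pairs: int = MIN_PAIRS_DEFAULT
) -> pd.DataFrame:
    """Full symmetric MR matrix, MR = sqrt(rank_a(b) * rank_b(a))."""
    corr = correlation_matrix(experiment, min_pairs)
    R = rank_matrix(corr).to_numpy()
    return pd.DataFrame(np.sqrt(R * R.T), index=corr.index, columns=corr.columns)


def mutual_rank(
    experiment: ExpressionExperiment, bait: str, gene: str,
    min_pairs: int = MIN_PAIRS_DEFAULT,
) -> float:
    """MR of one pair in one experiment; NaN when either gene is unrankable."""
    corr = correlation_matrix(experiment, min_pairs)
    if bait not in corr.index or gene not in corr.index:
        return math.nan
    R = rank_matrix(corr)
    return float(math.sqrt(R.at[bait, gene] * R.at[gene, bait]))


def bait_mr_series(
    experiment: ExpressionExperiment, bait: str,
    min_pairs: int = MIN_PAIRS_DEFAULT,
    corr: pd.DataFrame | None = None,
) -> pd.Series:
    """MR of every rankable gene against ``bait`` in one experiment.

    Accepts a precomputed correlation matrix to amortize the all-pairs cost
    over several baits.
    """
    if corr is None:
        corr = correlation_matrix(experiment, min_pairs)
    if bait not in corr.index:
        raise KeyError(f"bait {bait!r} not rankable in {experiment.accession}")
    C = corr.to_numpy(dtype=float)
    genes = corr.index.to_numpy()
    bi = int(np.flatnonzero(genes == bait)[0])

    bait_row = C[bi]
    ok = ~np.isnan(bait_row)
    rank_bait_to_gene = np.full(len(genes), np.nan)
    rank_bait_to_gene[ok] = rankdata(-bait_row[ok], method="average")

    rank_gene_to_bait = np.full(len(genes), np.nan)
    for j in np.flatnonzero(ok):
        row = C[j]
        okj = ~np.isnan(row)
        ranks = rankdata(-row[okj], method="average")
        pos = np.flatnonzero(np.flatnonzero(okj) == bi)
        if pos.size:
            rank_gene_to_bait[j] = ranks[pos[0]]

    mr = np.sqrt(rank_bait_to_gene * rank_gene_to_bait)
    out = pd.Series(mr, index=genes).drop(bait)
    return out.dropna()


COMBINE_POLICY_DEFAULT = "max"


def combine_across_experiments(
    per_experiment: Mapping[str, float],
    policy: str = COMBINE_POLICY_DEFAULT,
) -> float:
    """Summarize per-experiment MRs into one combined MR.

    ``max`` (default) takes the worst (largest) MR — a gene must show close
    correspondence with the bait in *every* contributing experiment, which
    keeps single-experiment chance correlates out of joint-threshold sets;
    ``geometric_mean`` averages in log space, a softer consistency demand.
    """
    vals = [v for v in per_experiment.values() if not math.isnan(v)]
    if not vals:
        raise ValueError("no per-experiment MR values to combine")
    if policy == "geometric_mean":
        return float(math.exp(sum(math.log(v) for v in vals) / len(vals)))
    if policy == "max":
        return float(max(vals))
    raise ValueError(f"unknown combination policy {policy!r}")


def mutual_rank_records(
    atlas: Atlas,
    baits: Sequence[str],
    min_pairs: int = MIN_PAIRS_DEFAULT,
    policy: str = COMBINE_POLICY_DEFAULT,
    min_coverage: int | None = None,
) -> list[MutualRankRecord]:
    """Per-(bait, gene) MRs across all experiments, with combined MR.

    ``min_coverage`` defaults, per bait, to the number of experiments in
    which that bait is rankable: a gene must be scoreable everywhere the
    bait is for its combined MR to be reported (genes failing it keep their
    per-experiment MRs but get combined = NaN).
    """
    per_bait: dict[str, dict[str, dict[str, float]]] = {b: {} for b in baits}
    bait_n_exp: dict[str, int] = {b: 0 for b in baits}
    for exp in atlas.experiments:
        corr = correlation_matrix(exp, min_pairs)
        for bait in baits:
            if bait not in corr.index:
                continue
            bait_n_exp[bait] += 1
            series = bait_mr_series(exp, bait, min_pairs, corr=corr)
            for gene, mr in series.items():
                per_bait[bait].setdefault(gene, {})[exp.accession] = float(mr)

    records: list[MutualRankRecord] = []
    for bait in baits:
        required = bait_n_exp[bait] if min_coverage is None else min_coverage
        for gene, per_exp in per_bait[bait].items():
            coverage = len(per_exp)
            combined = (combine_across_experiments(per_exp, policy)
                        if coverage >= max(required, 1) else math.nan)
            records.append(MutualRankRecord(bait, gene, per_exp, combined, coverage))
    return records


@dataclass
class CandidateSet:
    """Genes whose combined MR beats ``threshold`` against every bait."""

    baits: list[str]
    threshold: float
    members: pd.DataFrame  # index gene_id, one combined-MR column per bait

    @property
    def gene_ids(self) -> list[str]:
        return list(self.members.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members.index

    def __len__(self) -> int:
        return len(self.members)


def select_candidates(
    records: Iterable[MutualRankRecord],
    baits: Sequence[str],
    threshold: float,
) -> CandidateSet:
    """Joint-threshold selection: combined MR strictly below ``threshold``
    for EVERY bait; baits excluded; sorted ascending by max-over-baits MR,
    ties lexicographic by gene id."""
    baits = list(baits)
    by_gene: dict[str, dict[str, float]] = {}
    for r in records:
        if r.bait in baits and not math.isnan(r.combined):
            by_gene.setdefault(r.gene, {})[r.bait] = r.combined
    rows = {
        g: mrs for g, mrs in by_gene.items()
        if g not in baits
        and len(mrs) == len(baits)
        and all(mrs[b] < threshold for b in baits)
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=baits, dtype=float)
    df.index.name = "gene_id"
    if len(df):
        order = sorted(df.index, key=lambda g: (df.loc[g].max(), g))
        df = df.loc[order]
    return CandidateSet(baits, float(threshold), df)
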