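"""Reading, validation and harmonization of expression experiments.

Input contract: expression matrices are tab-delimited, already normalized on a
log2 scale (RMA-style); the first column holds gene (locus) identifiers and the
header row holds sample identifiers. No normalization is performed here. Sample
sheets are tab-delimited with columns ``sample_id``, ``tissue``, ``stage``,
``genotype`` and (optionally) ``replicate``.

Developmental stages are free-text labels ordered by their position on the
days-after-pollination (DAP) axis: plain numbers ("7 DAP"), intervals ordered
by their midpoint ("3-4 DAP" -> 3.5), or entries of a configurable vocabulary
("before anthesis" -> -1).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionExperiment",
    "Atlas",
    "MutualRankRecord",
    "DEFAULT_STAGE_VOCABULARY",
    "stage_position",
    "parse_stage",
    "read_expression_matrix",
    "read_sample_sheet",
    "collapse_duplicates",
    "write_candidate_table",
    "read_candidate_table",
    "write_specificity_table",
    "write_run_report",
]


class FormatError(ValueError):
    """Malformed file structure (header, cell contents)."""


class ValidationError(ValueError):
    """Structurally well-formed input violating a semantic invariant."""


# Named (non-numeric) stage labels and their position on the DAP axis.
# "before anthesis" sits ahead of pollination, hence the negative position.
DEFAULT_STAGE_VOCABULARY: dict[str, float] = {
    "before anthesis": -1.0,
    "anthesis": 0.0,
    "vegetative": -2.0,
    "mature": 30.0,
}

_DAP_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:-|–|\s+to\s+)\s*(\d+(?:\.\d+)?)\s*DAP\s*$", re.I)
_DAP_SINGLE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*DAP\s*$", re.I)


def parse_stage(label: str, vocabulary: Mapping[str, float] | None = None) -> float:
    """Return the DAP-axis position of a stage label.

    Interval labels such as "3-4 DAP" or "5-10 DAP" map to their midpoint
    (3.5 and 7.5); plain "7 DAP" maps to 7.0; other labels are looked up in
    ``vocabulary`` (case-insensitive).
    """
    vocab = DEFAULT_STAGE_VOCABULARY if vocabulary is None else vocabulary
    m = _DAP_SINGLE_RE.match(label)
    if m:
        return float(m.group(1))
    m = _DAP_RE.match(label)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    key = label.strip().lower()
    for k, v in vocab.items():
        if k.lower() == key:
            return float(v)
    try:
        return float(label)
    except ValueError:
        raise ValidationError(f"unknown stage label {label!r}: not numeric, not a DAP "
                              f"interval, and not in the stage vocabulary") from None


def stage_position(label: str, vocabulary: Mapping[str, float] | None = None) -> float:
    """Alias of :func:`parse_stage` kept for readability at call sites."""
    return parse_stage(label, vocabulary)


REQUIRED_SHEET_COLUMNS = ("sample_id", "tissue", "stage", "genotype")


@dataclass
class ExpressionExperiment:
    """One experiment: a genes x samples log2 expression matrix plus annotations.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    missing measurements are NaN. ``samples`` is a DataFrame indexed by
    sample_id with columns tissue, stage, genotype, replicate and the derived
    numeric ``stage_pos`` used to order stages.
    """

    accession: str
    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"{self.accession}: duplicate gene ids {dup[:5]}")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"{self.accession}: duplicate sample ids {dup[:5]}")
        missing = [s for s in cols if s not in self.samples.index]
        if missing:
            raise ValidationError(
                f"{self.accession}: samples absent from sample sheet: {missing[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError(f"{self.accession}: non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def annotations_for(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return self.samples.loc[ids]

    def canonical(self) -> "ExpressionExperiment":
        """Sorted copy (genes and samples lexicographic) for order-insensitive comparison."""
        v = self.values.sort_index(axis=0).sort_index(axis=1)
        return ExpressionExperiment(self.accession, v, self.samples.sort_index())


@dataclass
class Atlas:
    """A collection of harmonized experiments sharing a gene-id namespace."""

    experiments: list[ExpressionExperiment]

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValidationError("an atlas needs at least one experiment")
        accs = [e.accession for e in self.experiments]
        if len(set(accs)) != len(accs):
            raise ValidationError(f"duplicate experiment accessions: {accs}")

    @property
    def accessions(self) -> list[str]:
        return [e.accession for e in self.experiments]

    def gene_universe(self) -> pd.DataFrame:
        """Union of gene ids with one boolean presence column per accession."""
        genes: set[str] = set()
        for e in self.experiments:
            genes.update(e.gene_ids)
        universe = sorted(genes)
        data = {e.accession: [g in set(e.gene_ids) for g in universe]
                for e in self.experiments}
        return pd.DataFrame(data, index=pd.Index(universe, name="gene_id"))

    def get(self, accession: str) -> ExpressionExperiment:
        for e in self.experiments:
            if e.accession == accession:
                return e
        raise KeyError(accession)


@dataclass
class MutualRankRecord:
    """Mutual ranks of one (bait, gene) pair across experiments.

    ``per_experiment`` maps accession -> MR in that experiment; ``combined``
    is the cross-experiment summary (NaN when the coverage requirement is not
    met), ``coverage`` the number of contributing experiments.
    """

    bait: str
    gene: str
    per_experiment: dict[str, float] = field(default_factory=dict)
    combined: float = float("nan")
    coverage: int = 0

    def __post_init__(self) -> None:
        for acc, mr in self.per_experiment.items():
            if mr < 1.0 - 1e-9:
                raise ValidationError(f"MR({self.bait},{self.gene})[{acc}]={mr} < 1")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[], encoding="utf-8")


def read_expression_matrix(
    path: str | Path,
    accession: str,
    samples: pd.DataFrame | None = None,
    missing_token: str = "NA",
    duplicate_rule: str = "max_mean",
) -> ExpressionExperiment:
    """Read a tab-delimited genes x samples matrix into an experiment.

    The first header field must be ``gene_id``; the remaining fields are
    sample ids. Cells equal to ``missing_token`` become NaN (flagged missing);
    any other non-numeric cell raises :class:`FormatError`. Duplicate gene
    rows are resolved by :func:`collapse_duplicates` with ``duplicate_rule``.
    ``samples`` may be omitted for matrix-only workflows, in which case a
    minimal single-group sample sheet is synthesised.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene_id":
        raise FormatError(f"{path}: first header field must be 'gene_id', "
                          f"got {header[0]!r}" if header else f"{path}: empty file")
    seen: set[str] = set()
    dup = sorted({c for c in header[1:] if c in seen or seen.add(c)})
    if dup:
        raise ValidationError(f"{path}: repeated sample column(s) {dup}")
    raw = _read_tsv(path)
    raw.columns = header  # undo pandas' duplicate-name mangling safeguard
    values = raw.set_index("gene_id").iloc[:, :]
    values.index.name = None

    def _to_float(cell: str) -> float:
        if cell == missing_token or cell == "":
            return math.nan
        try:
            return float(cell)
        except ValueError:
            raise FormatError(f"{path}: non-numeric cell {cell!r} "
                              f"(missing token is {missing_token!r})") from None

    values = values.map(_to_float).astype(float)

    if samples is None:
        samples = pd.DataFrame(
            {"tissue": "unspecified", "stage": "0 DAP", "stage_pos": 0.0,
             "genotype": "wild type",
             "replicate": range(1, len(values.columns) + 1)},
            index=pd.Index(values.columns, name="sample_id"),
        )
    if values.index.duplicated().any():
        values = collapse_duplicates(values, duplicate_rule)
    return ExpressionExperiment(accession, values, samples)


def read_sample_sheet(
    path: str | Path,
    stage_vocabulary: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Read and validate a sample sheet, inferring stage order and replicates.

    Returns a DataFrame indexed by sample_id with columns tissue, stage,
    genotype, replicate (auto-numbered 1..k within each (tissue, stage,
    genotype) group when the column is absent) and numeric ``stage_pos``.
    """
    sheet = _read_tsv(path)
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"{path}: duplicate sample ids {dup}")
    sheet = sheet.set_index("sample_id")
    sheet["stage_pos"] = [parse_stage(s, stage_vocabulary) for s in sheet["stage"]]
    if "replicate" in sheet.columns and (sheet["replicate"] != "").all():
        sheet["replicate"] = sheet["replicate"].astype(int)
    else:
        sheet["replicate"] = (
            sheet.groupby(["tissue", "stage", "genotype"], sort=False).cumcount() + 1
        )
    if (sheet["replicate"] < 1).any():
        raise ValidationError(f"{path}: replicate indices must be >= 1")
    return sheet


def collapse_duplicates(values: pd.DataFrame, rule: str = "max_mean") -> pd.DataFrame:
    """Resolve duplicate gene rows (array probe-set -> locus many-to-one).

    ``max_mean`` keeps, per gene, the row with the highest mean over samples
    (the convention for retaining the strongest probe set); ``first`` keeps
    the first row in file order; ``error`` refuses duplicates.
    """
    if rule not in {"max_mean", "first", "error"}:
        raise ValueError(f"unknown duplicate rule {rule!r}")
    dup_mask = values.index.duplicated(keep=False)
    if not dup_mask.any():
        return values
    if rule == "error":
        dup = sorted(values.index[values.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene rows present: {dup[:5]}")
    if rule == "first":
        return values[~values.index.duplicated(keep="first")]
    # max_mean: stable argmax of row means within each gene id
    means = values.mean(axis=1, skipna=True).to_numpy()
    keep = np.zeros(len(values), dtype=bool)
    for gene in values.index.unique():
        locs = np.flatnonzero(values.index == gene)
        keep[locs[np.argmax(means[locs])]] = True
    return values.iloc[np.flatnonzero(keep)]


# ---------------------------------------------------------------------------
# Result-table writers/readers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else _FLOAT_FMT % x


def write_candidate_table(records: Iterable[MutualRankRecord], path: str | Path) -> None:
    """Write mutual-rank records as TSV: bait_id, gene_id, one mr_<accession>
    column per experiment, combined_mr, coverage.

    Rows are ordered by ascending combined MR, ties broken by (bait_id,
    gene_id) lexicographic; records with no combined MR sort last.
    """
    records = list(records)
    accessions = sorted({acc for r in records for acc in r.per_experiment})
    header = ["bait_id", "gene_id"] + [f"mr_{a}" for a in accessions] + [
        "combined_mr", "coverage"]

    def sort_key(r: MutualRankRecord):
        c = r.combined if not math.isnan(r.combined) else math.inf
        return (c, r.bait, r.gene)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for r in sorted(records, key=sort_key):
            row = [r.bait, r.gene]
            row += [_fmt(r.per_experiment.get(a, math.nan)) for a in accessions]
            row += [_fmt(r.combined), str(r.coverage)]
            fh.write("\t".join(row) + "\n")


def read_candidate_table(path: str | Path) -> list[MutualRankRecord]:
    """Inverse of :func:`write_candidate_table`."""
    tab = _read_tsv(path)
    acc_cols = [c for c in tab.columns if c.startswith("mr_")]
    out: list[MutualRankRecord] = []
    for _, row in tab.iterrows():
        per = {c[3:]: float(row[c]) for c in acc_cols if row[c] != "NA"}
        combined = math.nan if row["combined_mr"] == "NA" else float(row["combined_mr"])
        out.append(MutualRankRecord(row["bait_id"], row["gene_id"], per,
                                    combined, int(row["coverage"])))
    return out


def write_specificity_table(calls: Iterable, path: str | Path) -> None:
    """Write specificity calls as TSV with columns gene_id, exclusive,
    peak_stage, label, status; ordered by gene_id."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\texclusive\tpeak_stage\tlabel\tstatus\n")
        for c in sorted(calls, key=lambda c: c.gene):
            fh.write("\t".join([
                c.gene,
                {True: "yes", False: "no", None: "NA"}[c.exclusive],
                c.peak_stage or "NA",
                c.label or "NA",
                c.status,
            ]) + "\n")


def write_run_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
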