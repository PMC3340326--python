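"""Readers and writers for the five file dialects the pipeline consumes and emits.

All formats are plain tab-separated text:

* **Expression**: first column ``feature_id``, remaining columns sample ids,
  values are normalized log2-scale intensities.  A companion two-column file
  (``sample_id``, ``group``) assigns every sample to a strain/group.
* **Gene sets**: standard GMT (set name, description/category, then members).
* **Gene annotations**: headerless 4-column BED-like TSV
  (chromosome, start, end, gene_id).  Coordinates are **1-based, fully
  closed** intervals: start and end are the first (5') and last (3')
  transcript nucleotides, both included.  Minus-strand style records with
  start > end are silently canonicalized; strand is not modeled because the
  overlap rule downstream is strand-agnostic.
* **QTL table**: header ``qtl_name trait chromosome peak_bp flank_start_bp
  flank_end_bp``; missing values are empty fields.  Each record needs a peak
  position or both flanking positions.
* **Results**: versioned TSV (first line ``# qtlgsa-results-v1``) with a fixed
  column order, sorted by combined max sub-set p-value then set name so
  downstream diffs are bit-stable.

No computation happens here beyond invariant validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESULTS_HEADER_TAG = "# qtlgsa-results-v1"

#: Fixed leading columns of the results table; one ``sub_p__<cmp>`` /
#: ``whole_p__<cmp>`` pair per comparison follows.
RESULTS_BASE_COLUMNS = (
    "set_name",
    "category",
    "n_genes",
    "n_in_qtl",
    "direction",
    "max_sub_p",
    "max_whole_p",
    "rank",
    "critical_value",
    "significant",
)


class FormatError(ValueError):
    """An input file violates its format contract or a record invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A normalized expression matrix with sample-to-group labels.

    Parameters
    ----------
    values:
        features x samples DataFrame of finite floats; the index holds
        feature ids (probe sets or genes), the columns sample ids.
    sample_groups:
        mapping sample_id -> group label (strain); every sample must be
        labelled.
    """

    def __init__(self, values: pd.DataFrame, sample_groups: Mapping[str, str]):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value at feature {values.index[i]!r}, "
                f"sample {values.columns[j]!r}"
            )
        missing = [s for s in values.columns if s not in sample_groups]
        if missing:
            raise FormatError(f"sample without group label: {missing[0]!r}")
        self.values = values.astype(float)
        self.sample_groups = {s: sample_groups[s] for s in values.columns}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids carrying the given group label, in column order."""
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy())
            and self.sample_groups == other.sample_groups
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_features} features x {self.n_samples} samples)"


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic interval of a gene: 1-based closed transcript span."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if not self.chromosome:
            raise FormatError(f"gene {self.gene_id!r}: empty chromosome")
        if self.start_bp < 0 or self.end_bp < 0:
            raise FormatError(f"gene {self.gene_id!r}: negative coordinate")
        if self.start_bp > self.end_bp:
            raise FormatError(
                f"gene {self.gene_id!r}: start > end after canonicalization"
            )


@dataclass(frozen=True)
class QTLRecord:
    """A trait-linked QTL: peak position and/or flanking-marker interval."""

    qtl_name: str
    trait: str
    chromosome: str
    peak_bp: int | None = None
    flank_start_bp: int | None = None
    flank_end_bp: int | None = None

    def __post_init__(self):
        has_flanks = self.flank_start_bp is not None and self.flank_end_bp is not None
        if self.peak_bp is None and not has_flanks:
            raise FormatError(
                f"QTL {self.qtl_name!r}: needs a peak position or both flanks"
            )
        if has_flanks and self.flank_start_bp > self.flank_end_bp:
            raise FormatError(f"QTL {self.qtl_name!r}: flank_start_bp > flank_end_bp")


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: category label plus unique member gene ids."""

    set_name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"gene set {self.set_name!r}: duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class IntersectionResult:
    """Per-pathway outcome of the QTL-intersection significance procedure.

    ``sub_p`` / ``whole_p`` map comparison name -> p-value of the QTL
    sub-set (pathway ∩ Q) and of the whole measured pathway, for the
    direction variant reported in ``direction``.  ``max_sub_p`` and
    ``max_whole_p`` are the maxima over comparisons; ``rank`` and
    ``critical_value`` come from the combined step on those maxima.
    """

    set_name: str
    category: str
    n_genes: int
    n_in_qtl: int
    direction: str
    max_sub_p: float
    max_whole_p: float
    rank: int
    critical_value: float
    significant: bool
    sub_p: dict[str, float] = field(default_factory=dict)
    whole_p: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.n_in_qtl <= self.n_genes:
            raise ValueError(
                f"{self.set_name}: n_in_qtl={self.n_in_qtl} outside [0, {self.n_genes}]"
            )
        for p in (self.max_sub_p, self.max_whole_p, *self.sub_p.values(), *self.whole_p.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.set_name}: p-value {p} outside [0, 1]")
        if self.significant and not (
            self.max_sub_p < self.critical_value and self.max_sub_p < self.max_whole_p
        ):
            raise ValueError(
                f"{self.set_name}: flagged significant but max_sub_p does not beat "
                "the critical value and the whole-pathway p"
            )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path, group_map) -> ExpressionMatrix:
    """Read an expression TSV plus its sample->group assignment.

    ``group_map`` is either a mapping sample_id -> group or the path of a
    two-column TSV with header ``sample_id``, ``group``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"non-numeric expression value at feature {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise FormatError(f"missing expression value at feature {row!r}, sample {col!r}")
        df[col] = coerced
    if not isinstance(group_map, Mapping):
        group_map = read_group_map(group_map)
    return ExpressionMatrix(df, group_map)


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'sample_id' and 'group'")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id in group map: {dup!r}")
    return dict(zip(df["sample_id"], df["group"]))


def write_expression(expr: ExpressionMatrix, path, groups_path=None) -> None:
    """Write the matrix as TSV; optionally the group map alongside."""
    out = expr.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    if groups_path is not None:
        pd.DataFrame(
            {"sample_id": list(expr.sample_groups), "group": list(expr.sample_groups.values())}
        ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: ``set_name TAB category TAB member TAB member...``

    Duplicate members on a line are dropped (first occurrence kept) with a
    logged warning.  The description field is stored verbatim as the
    category label.
    """
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, category, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "gene set %r: %d duplicate member(s) dropped", name, len(members) - len(unique)
                )
            if name in seen_names:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen_names.add(name)
            sets.append(GeneSet(name, category, tuple(unique)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_name, gs.category, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Read headerless 4-column (chromosome, start, end, gene_id) annotations.

    Coordinates are 1-based closed; records with start > end (minus-strand
    convention) are canonicalized to start <= end.
    """
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 fields")
            chrom, start_s, end_s, gene_id = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from None
            if start < 0 or end < 0:
                raise FormatError(f"{path}: line {lineno}: negative coordinate for {gene_id!r}")
            if start > end:
                start, end = end, start
            out.append(GeneAnnotation(gene_id, chrom, start, end))
    return out


def write_gene_annotations(annotations: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.chromosome}\t{a.start_bp}\t{a.end_bp}\t{a.gene_id}\n")


# ---------------------------------------------------------------------------
# QTL table
# ---------------------------------------------------------------------------

_QTL_COLUMNS = ["qtl_name", "trait", "chromosome", "peak_bp", "flank_start_bp", "flank_end_bp"]


def read_qtl_table(path) -> list[QTLRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _QTL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    def _int_or_none(v):
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return int(float(v))

    records = []
    for _, row in df.iterrows():
        records.append(
            QTLRecord(
                qtl_name=row["qtl_name"],
                trait=row["trait"],
                chromosome=row["chromosome"],
                peak_bp=_int_or_none(row["peak_bp"]),
                flank_start_bp=_int_or_none(row["flank_start_bp"]),
                flank_end_bp=_int_or_none(row["flank_end_bp"]),
            )
        )
    return records


def write_qtl_table(records: Iterable[QTLRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_QTL_COLUMNS) + "\n")
        for r in records:
            vals = [
                r.qtl_name,
                r.trait,
                r.chromosome,
                "" if r.peak_bp is None else str(r.peak_bp),
                "" if r.flank_start_bp is None else str(r.flank_start_bp),
                "" if r.flank_end_bp is None else str(r.flank_end_bp),
            ]
            fh.write("\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# probe -> gene map
# ---------------------------------------------------------------------------


def read_probe_gene_map(path) -> dict[str, str]:
    """Read the 2-column TSV ``probe_id  gene_id`` (many probes -> one gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'probe_id' and 'gene_id'")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"probe {dup!r} mapped to more than one gene")
    return dict(zip(df["probe_id"], df["gene_id"]))


def write_probe_gene_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"probe_id": list(mapping), "gene_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------


def write_results(results: Sequence[IntersectionResult], path, comparisons=None) -> None:
    """Write results as versioned TSV, sorted by (max_sub_p, set_name)."""
    if comparisons is None:
        comparisons = list(results[0].sub_p) if results else []
    columns = list(RESULTS_BASE_COLUMNS)
    for c in comparisons:
        columns += [f"sub_p__{c}", f"whole_p__{c}"]
    rows = []
    for r in sorted(results, key=lambda r: (r.max_sub_p, r.set_name)):
        row = {
            "set_name": r.set_name,
            "category": r.category,
            "n_genes": r.n_genes,
            "n_in_qtl": r.n_in_qtl,
            "direction": r.direction,
            "max_sub_p": r.max_sub_p,
            "max_whole_p": r.max_whole_p,
            "rank": r.rank,
            "critical_value": r.critical_value,
            "significant": r.significant,
        }
        for c in comparisons:
            row[f"sub_p__{c}"] = r.sub_p[c]
            row[f"whole_p__{c}"] = r.whole_p[c]
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        if df[col].dtype.kind == "f":
            # shortest round-tripping decimal representation
            df[col] = df[col].map(lambda v: repr(float(v)))
    with open(path, "w") as fh:
        fh.write(RESULTS_HEADER_TAG + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV into a DataFrame (for diffing and plotting)."""
    with open(path) as fh:
        tag = fh.readline().strip()
        if tag != RESULTS_HEADER_TAG:
            raise FormatError(f"{path}: not a qtlgsa results file (header {tag!r})")
        return pd.read_csv(fh, sep="\t", float_precision="round_trip")


def results_to_objects(df: pd.DataFrame) -> list[IntersectionResult]:
    """Rehydrate IntersectionResult objects from a read-back results table."""
    comparisons = [c[len("sub_p__"):] for c in df.columns if c.startswith("sub_p__")]
    out = []
    for _, row in df.iterrows():
        out.append(
            IntersectionResult(
                set_name=row["set_name"],
                category=row["category"],
                n_genes=int(row["n_genes"]),
                n_in_qtl=int(row["n_in_qtl"]),
                direction=row["direction"],
                max_sub_p=float(row["max_sub_p"]),
                max_whole_p=float(row["max_whole_p"]),
                rank=int(row["rank"]),
                critical_value=float(row["critical_value"]),
                significant=bool(row["significant"]),
                sub_p={c: float(row[f"sub_p__{c}"]) for c in comparisons},
                whole_p={c: float(row[f"whole_p__{c}"]) for c in comparisons},
            )
        )
    return out
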