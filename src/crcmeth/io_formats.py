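"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the in-memory types built here.
Coordinate convention: everything internal is 0-based half-open
(BED-style); only :class:`CytosineRecord.pos` is 1-based, as in Bismark
cytosine reports, and is converted at the boundary (``pos - 1`` as start).
Missing matrix cells are serialized as empty strings, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CytosineRecord",
    "GenomicInterval",
    "GeneSetCollection",
    "ClinicalRecord",
    "ParseError",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "read_clinical",
    "write_clinical",
    "write_graph",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine from a Bismark cytosine report (1-based position)."""

    chrom: str
    pos: int  # 1-based
    strand: str
    count_methylated: int
    count_unmethylated: int
    context: str = "CpG"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError("counts must be non-negative")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def is_cpg(self) -> bool:
        return self.context.upper() in {"CPG", "CG"}

    @property
    def start(self) -> int:
        """0-based start (internal convention)."""
        return self.pos - 1

    @property
    def end(self) -> int:
        return self.pos


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (internal = BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between half-open intervals; 0 when overlapping.

        Returns None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        return max(0, other.start - self.end, self.start - other.end)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT container); symbols unique within a set."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate symbols in gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class ClinicalRecord:
    """Survival time (days), event flag, group label, optional mutation count."""

    sample_id: str
    time: float
    event: int
    group: str = ""
    mutation_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if self.mutation_count is not None and self.mutation_count < 0:
            raise ValueError("mutation_count must be non-negative")


# ---------------------------------------------------------------------------
# Bismark cytosine report
# ---------------------------------------------------------------------------

def read_cytosine_report(path) -> list:
    """Read a Bismark-style cytosine report (TSV).

    Columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context[, trinucleotide]. Non-CpG contexts are
    retained (flag with :attr:`CytosineRecord.is_cpg` downstream).
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, pos, strand, meth, unmeth, context = fields[:6]
            try:
                record = CytosineRecord(
                    chrom=chrom,
                    pos=int(pos),
                    strand=strand,
                    count_methylated=int(meth),
                    count_unmethylated=int(unmeth),
                    context=context,
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(record)
    return records


def write_cytosine_report(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_methylated}"
                f"\t{r.count_unmethylated}\t{r.context}\t{r.context}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list:
    """Read a 3-6 column BED file into GenomicInterval objects (no shift)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: BED needs >=3 columns"
                )
            try:
                interval = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else "",
                    score=float(fields[4]) if len(fields) > 4 and fields[4] not in ("", ".") else 0.0,
                    strand=fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            intervals.append(interval)
    return intervals


def write_bed(intervals, path, extra_columns=None) -> None:
    """Write BED6(+). extra_columns: list of per-interval value tuples."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name or ".",
                repr(iv.score) if iv.score else "0",
                iv.strand or ".",
            ]
            if extra_columns is not None:
                row.extend(str(v) for v in extra_columns[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix; blank cells become NaN (missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate feature ids: {dupes}")
    return df.apply(pd.to_numeric, errors="raise")


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix as TSV; NaN serialized as empty string, never 0."""
    df.to_csv(path, sep="\t", na_rep="", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT / regulons / clinical
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description "
                    "and >=1 member"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


_MODE_ALIASES = {
    "1": 1, "+1": 1, "activation": 1,
    "-1": -1, "repression": -1,
}


def read_regulons(path) -> pd.DataFrame:
    """Read a 3-column TSV of (tf, target, mode) into a DataFrame.

    mode accepts 1/+1/activation and -1/repression; stored as +-1 int.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["tf", "target"]:
                continue  # optional header
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: regulon rows need tf, target, mode"
                )
            tf, target, mode = fields[0], fields[1], fields[2].strip().lower()
            if mode not in _MODE_ALIASES:
                raise ParseError(
                    f"{path}: line {lineno}: mode must be one of "
                    f"{sorted(_MODE_ALIASES)}, got {mode!r}"
                )
            rows.append((tf, target, _MODE_ALIASES[mode]))
    df = pd.DataFrame(rows, columns=["tf", "target", "mode"])
    if df.duplicated(["tf", "target"]).any():
        dupes = df[df.duplicated(["tf", "target"])][["tf", "target"]]
        raise ParseError(f"{path}: duplicate (tf, target) pairs:\n{dupes}")
    return df


def write_regulons(df: pd.DataFrame, path) -> None:
    df[["tf", "target", "mode"]].to_csv(path, sep="\t", index=False)


def read_clinical(path) -> list:
    """Read a clinical TSV with columns sample_id, time, event, group
    [, mutation_count]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        mut = row.get("mutation_count")
        try:
            records.append(
                ClinicalRecord(
                    sample_id=row["sample_id"],
                    time=float(row["time"]),
                    event=int(row["event"]),
                    group=str(row.get("group", "") or ""),
                    mutation_count=None if mut is None or pd.isna(mut) else int(mut),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return records


def write_clinical(records, path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "time": r.time,
            "event": r.event,
            "group": r.group,
            "mutation_count": "" if r.mutation_count is None else r.mutation_count,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def write_graph(graph: nx.Graph, path, fmt: str = "sif") -> None:
    """Export a network as SIF or GraphML.

    SIF lines read ``source activates|represses target`` based on edge
    ``sign``; GraphML carries edge weights and any node attributes.
    """
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                interaction = "represses" if data.get("sign", 1) < 0 else "activates"
                fh.write(f"{u}\t{interaction}\t{v}\n")
    elif fmt == "graphml":
        export = graph.copy()
        for _, data in export.nodes(data=True):
            for key, value in list(data.items()):
                if isinstance(value, (np.floating, np.integer)):
                    data[key] = value.item()
                elif isinstance(value, (bool, np.bool_)):
                    data[key] = bool(value)
        for _, _, data in export.edges(data=True):
            for key, value in list(data.items()):
                if isinstance(value, (np.floating, np.integer)):
                    data[key] = value.item()
        nx.write_graphml(export, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; use 'sif' or 'graphml'")
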