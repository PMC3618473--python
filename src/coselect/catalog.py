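"""Curated genomic-event catalog for cell-line panels.

A *genomic event* is a mutation (coding-sequence variant) and/or a
copy-number aberration — homozygous deletion (total copy number 0) or
amplification (total copy number >= 8) — at a locus in a cell line.
This module reads the three headered TSV inputs (mutations, gene-level
total copy number, lineage annotations) and assembles the binary
cell-line x locus event matrix consumed by every downstream stage.

Sub-loci such as ``CDKN2A(p14)`` are independent loci and are never
merged into their parent gene symbol.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import RowParseError, TableFormatError

logger = logging.getLogger(__name__)

UNKNOWN_LINEAGE = "unknown"

_TRUE_STRINGS = {"1", "true"}
_FALSE_STRINGS = {"0", "false"}


@dataclass(frozen=True)
class MutationRecord:
    cell_line: str
    locus: str
    mutated: bool


@dataclass(frozen=True)
class CopyNumberRecord:
    cell_line: str
    locus: str
    total_copy_number: int


class LineageMap(dict):
    """cell_line -> lineage mapping, total over all identifiers.

    Lookup of a cell line absent from the table yields the ``"unknown"``
    sentinel rather than raising.
    """

    def __missing__(self, key):  # noqa: D105
        return UNKNOWN_LINEAGE


@dataclass
class EventMatrix:
    """Binary cell-line x locus matrix of genomic events.

    ``cell_lines`` and ``loci`` are lexicographically sorted; ``values``
    is an N x G boolean array; ``lineage`` maps cell lines to lineage
    labels (``"unknown"`` where unannotated).
    """

    cell_lines: list[str]
    loci: list[str]
    values: np.ndarray
    lineage: LineageMap = field(default_factory=LineageMap)

    def __post_init__(self) -> None:
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("duplicate cell lines in event matrix")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci in event matrix")
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.cell_lines), len(self.loci)):
            raise ValueError("event matrix shape does not match labels")
        self._line_index = {c: i for i, c in enumerate(self.cell_lines)}
        self._locus_index = {g: j for j, g in enumerate(self.loci)}

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_column(self, locus: str) -> np.ndarray:
        return self.values[:, self._locus_index[locus]]

    def has_event(self, cell_line: str, locus: str) -> bool:
        return bool(self.values[self._line_index[cell_line], self._locus_index[locus]])

    def restrict_cell_lines(self, cell_lines) -> "EventMatrix":
        """Sub-matrix over the given cell lines (canonical ordering kept)."""
        keep = sorted(set(cell_lines) & set(self.cell_lines))
        rows = [self._line_index[c] for c in keep]
        lin = LineageMap({c: self.lineage[c] for c in keep if c in self.lineage})
        return EventMatrix(keep, list(self.loci), self.values[rows, :], lin)

    def drop_empty_loci(self) -> "EventMatrix":
        """Drop loci with zero events (they cannot join any co-event)."""
        keep = self.values.any(axis=0)
        return EventMatrix(
            list(self.cell_lines),
            [g for g, k in zip(self.loci, keep) if k],
            self.values[:, keep],
            LineageMap(self.lineage),
        )

    def to_events_frame(self) -> pd.DataFrame:
        """Long-format table with one row per true event."""
        rows = [
            (c, g)
            for i, c in enumerate(self.cell_lines)
            for j, g in enumerate(self.loci)
            if self.values[i, j]
        ]
        return pd.DataFrame(rows, columns=["cell_line", "locus"])

    @classmethod
    def from_events_frame(cls, frame: pd.DataFrame, lineage: LineageMap | None = None) -> "EventMatrix":
        for col in ("cell_line", "locus"):
            if col not in frame.columns:
                raise TableFormatError(f"events table is missing column '{col}'")
        cell_lines = sorted(frame["cell_line"].unique())
        loci = sorted(frame["locus"].unique())
        li = {c: i for i, c in enumerate(cell_lines)}
        gi = {g: j for j, g in enumerate(loci)}
        values = np.zeros((len(cell_lines), len(loci)), dtype=bool)
        for c, g in frame[["cell_line", "locus"]].itertuples(index=False):
            values[li[c], gi[g]] = True
        return cls(cell_lines, loci, values, lineage or LineageMap())


def _read_tsv_rows(path, required: tuple[str, ...]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise TableFormatError(f"{path}: missing required column '{col}'")
        yield from ((lineno, row) for lineno, row in enumerate(reader, start=2))


def load_mutation_table(path) -> list[MutationRecord]:
    """Read a mutations TSV (columns cell_line, locus, mutated).

    Boolean parsing accepts {0,1,true,false} case-insensitively.
    Duplicate (cell_line, locus) rows with equal values are de-duplicated;
    conflicting duplicates raise.
    """
    seen: dict[tuple[str, str], MutationRecord] = {}
    for lineno, row in _read_tsv_rows(path, ("cell_line", "locus", "mutated")):
        raw = (row["mutated"] or "").strip().lower()
        if raw in _TRUE_STRINGS:
            mutated = True
        elif raw in _FALSE_STRINGS:
            mutated = False
        else:
            raise RowParseError(f"unparseable boolean {row['mutated']!r}", lineno)
        locus = (row["locus"] or "").strip()
        if not locus:
            raise RowParseError("empty locus", lineno)
        rec = MutationRecord(row["cell_line"].strip(), locus, mutated)
        key = (rec.cell_line, rec.locus)
        if key in seen:
            if seen[key].mutated != rec.mutated:
                raise RowParseError(
                    f"conflicting mutation calls for {key[0]}/{key[1]}", lineno
                )
            continue
        seen[key] = rec
    return list(seen.values())


def load_copy_number_table(path) -> list[CopyNumberRecord]:
    """Read a copy-number TSV (columns cell_line, locus, total_copy_number).

    Records are returned in file order; copy numbers must parse as
    non-negative integers.
    """
    records = []
    for lineno, row in _read_tsv_rows(path, ("cell_line", "locus", "total_copy_number")):
        raw = (row["total_copy_number"] or "").strip()
        try:
            cn = int(raw)
        except ValueError:
            raise RowParseError(f"non-integer copy number {raw!r}", lineno) from None
        if cn < 0:
            raise RowParseError(f"negative copy number {cn}", lineno)
        records.append(CopyNumberRecord(row["cell_line"].strip(), row["locus"].strip(), cn))
    return records


def write_copy_number_table(records, path) -> None:
    """Paired writer for :func:`load_copy_number_table` (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell_line", "locus", "total_copy_number"])
        for rec in records:
            writer.writerow([rec.cell_line, rec.locus, rec.total_copy_number])


def load_lineage_table(path) -> LineageMap:
    """Read a lineage TSV (columns cell_line, lineage).

    Conflicting lineage assignments for the same cell line raise.
    """
    mapping = LineageMap()
    for lineno, row in _read_tsv_rows(path, ("cell_line", "lineage")):
        cell, lin = row["cell_line"].strip(), row["lineage"].strip()
        if cell in mapping and mapping[cell] != lin:
            raise RowParseError(f"conflicting lineage for cell line {cell!r}", lineno)
        mapping[cell] = lin
    return mapping


def build_event_matrix(
    mutations,
    copy_numbers,
    amplification_threshold: int = 8,
    deletion_value: int = 0,
    lineage: LineageMap | None = None,
) -> EventMatrix:
    """Assemble the binary event matrix from mutation and copy-number calls.

    ``events[i, g]`` is true iff the locus is mutated, homozygously
    deleted (total copy number equal to ``deletion_value``), or amplified
    (total copy number >= ``amplification_threshold``). Cell lines and
    loci are the union of those appearing in either input, sorted
    lexicographically. Empty inputs give an empty matrix.
    """
    if not deletion_value < amplification_threshold:
        raise ValueError("deletion_value must be below amplification_threshold")
    cell_lines = sorted(
        {m.cell_line for m in mutations} | {c.cell_line for c in copy_numbers}
    )
    loci = sorted({m.locus for m in mutations} | {c.locus for c in copy_numbers})
    li = {c: i for i, c in enumerate(cell_lines)}
    gi = {g: j for j, g in enumerate(loci)}
    values = np.zeros((len(cell_lines), len(loci)), dtype=bool)
    for m in mutations:
        if m.mutated:
            values[li[m.cell_line], gi[m.locus]] = True
    for c in copy_numbers:
        if c.total_copy_number == deletion_value or c.total_copy_number >= amplification_threshold:
            values[li[c.cell_line], gi[c.locus]] = True
    return EventMatrix(cell_lines, loci, values, lineage or LineageMap())


def locus_frequencies(matrix: EventMatrix, subset=None) -> dict[str, float]:
    """Per-locus event frequency over the panel or a cell-line subset.

    The output is ordered by locus (the matrix's canonical ordering).
    """
    if subset is None:
        sub = matrix
        n = matrix.n_cell_lines
    else:
        subset = set(subset)
        if not subset:
            raise ValueError("empty cell-line subset")
        if not subset <= set(matrix.cell_lines):
            missing = sorted(subset - set(matrix.cell_lines))
            raise ValueError(f"subset contains unknown cell lines: {missing[:5]}")
        sub = matrix.restrict_cell_lines(subset)
        n = sub.n_cell_lines
    counts = sub.values.sum(axis=0)
    return {g: counts[j] / n for j, g in enumerate(sub.loci)}
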