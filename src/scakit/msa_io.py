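"""Alignment, annotation, and position-map input/output.

Alignments are read with Biopython (FASTA or Stockholm), normalized to the
21-symbol alphabet of :mod:`scakit.alphabet`: rows are upper-cased, '.' and
lowercase insert states become gaps, and ambiguity codes (B, Z, X, U, O, J,
'*') are mapped to gap with a logged count.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import AlignIO

from .alphabet import AMINO_ACIDS, GAP, encode_rows

logger = logging.getLogger(__name__)

_CANONICAL = set(AMINO_ACIDS) | {GAP}


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged rows, bad ids)."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment over {20 amino acids, '-'}.

    ``rows[s][i]`` is the symbol of sequence ``s`` at alignment column ``i``.
    """

    ids: tuple
    rows: tuple
    descriptions: tuple = None

    def __post_init__(self):
        if self.descriptions is None:
            object.__setattr__(self, "descriptions", tuple("" for _ in self.ids))
        if not (len(self.ids) == len(self.rows) == len(self.descriptions)):
            raise AlignmentError("ids, rows and descriptions must align")
        if len(self.rows) == 0:
            raise AlignmentError("alignment has no sequences")
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentError("alignment length must be >= 1")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise AlignmentError(
                    f"ragged alignment: sequence {rid!r} has length "
                    f"{len(row)} != {L}"
                )
            bad = set(row) - _CANONICAL
            if bad:
                raise AlignmentError(
                    f"sequence {rid!r} contains non-canonical symbols {sorted(bad)}"
                )
        if len(set(self.ids)) != len(self.ids):
            seen, dups = set(), set()
            for rid in self.ids:
                if rid in seen:
                    dups.add(rid)
                seen.add(rid)
            raise AlignmentError(f"duplicate sequence ids: {sorted(dups)}")

    @property
    def M(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """M x L integer code matrix (0 = gap)."""
        return encode_rows(self.rows)

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def subset_sequences(self, indices: Sequence[int]) -> "MSA":
        idx = list(indices)
        return MSA(
            ids=tuple(self.ids[i] for i in idx),
            rows=tuple(self.rows[i] for i in idx),
            descriptions=tuple(self.descriptions[i] for i in idx),
        )

    def subset_columns(self, columns: Sequence[int]) -> "MSA":
        cols = list(columns)
        return MSA(
            ids=self.ids,
            rows=tuple("".join(row[i] for i in cols) for row in self.rows),
            descriptions=self.descriptions,
        )


def normalize_symbols(raw: str) -> tuple:
    """Normalize one raw row; returns (row, number of non-canonical symbols)."""
    row = []
    n_bad = 0
    for ch in raw:
        up = ch.upper()
        if ch == "." or ch.islower():
            row.append(GAP)
        elif up in _CANONICAL:
            row.append(up)
        else:
            row.append(GAP)
            n_bad += 1
    return "".join(row), n_bad


def read_alignment(path, format: str = "fasta") -> MSA:
    """Read an aligned FASTA or Stockholm file.

    Symbols outside the canonical alphabet are replaced by gaps and counted
    in a single warning; ids and record order are preserved losslessly.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        aln = AlignIO.read(str(path), format)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    ids, rows, descs = [], [], []
    n_bad_total = 0
    for rec in aln:
        row, n_bad = normalize_symbols(str(rec.seq))
        n_bad_total += n_bad
        ids.append(rec.id)
        rows.append(row)
        descs.append(rec.description if rec.description != rec.id else "")
    if n_bad_total:
        logger.warning(
            "%s: %d non-canonical symbols replaced by gaps", path.name, n_bad_total
        )
    return MSA(ids=tuple(ids), rows=tuple(rows), descriptions=tuple(descs))


def write_fasta(msa: MSA, path) -> None:
    """Write the alignment as canonical FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rid, desc, row in zip(msa.ids, msa.descriptions, msa.rows):
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for start in range(0, len(row), 60):
                fh.write(row[start : start + 60] + "\n")


@dataclass
class AnnotationTable:
    """Per-sequence labels: id -> {key: value}."""

    labels: dict = field(default_factory=dict)

    def get(self, seq_id: str, key: str, default: str = "") -> str:
        return self.labels.get(seq_id, {}).get(key, default)

    def column(self, msa: MSA, key: str, default: str = "") -> list:
        """Label vector aligned with the MSA's sequence order."""
        unmatched = [i for i in self.labels if i not in set(msa.ids)]
        if unmatched:
            logger.info(
                "%d annotated ids absent from the alignment (e.g. %s)",
                len(unmatched),
                unmatched[0],
            )
        return [self.get(rid, key, default) for rid in msa.ids]

    def keys(self):
        out = set()
        for labels in self.labels.values():
            out.update(labels)
        return sorted(out)


def parse_annotations(path, id_column: str) -> AnnotationTable:
    """Parse a delimited annotation table (TSV for .tsv/.tab, else CSV)."""
    import pandas as pd

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not in table header")
    dup = df[id_column][df[id_column].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate ids in annotation table: {sorted(set(dup))}")
    labels = {}
    for _, row in df.iterrows():
        labels[row[id_column]] = {
            k: row[k] for k in df.columns if k != id_column
        }
    return AnnotationTable(labels=labels)


def read_stockholm_annotations(path) -> AnnotationTable:
    """Harvest '#=GS <id> <feature> <text>' lines from a Stockholm file."""
    labels: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#=GS"):
                parts = line.split(None, 3)
                if len(parts) == 4:
                    _, rid, feature, text = parts
                    labels.setdefault(rid, {})[feature] = text.strip()
    return AnnotationTable(labels=labels)


@dataclass(frozen=True)
class PositionMap:
    """Alignment column (0-based) -> reference residue label.

    Columns where the reference sequence is gapped carry no label and are
    listed in ``unmapped``.
    """

    labels: Mapping[int, str]
    unmapped: frozenset

    def __post_init__(self):
        vals = list(self.labels.values())
        if len(set(vals)) != len(vals):
            raise ValueError("position map labels must be injective")
        if set(self.labels) & self.unmapped:
            raise ValueError("a column cannot be both mapped and unmapped")

    def label(self, column: int) -> Optional[str]:
        return self.labels.get(column)

    def restrict(self, kept_columns: Sequence[int]) -> "PositionMap":
        """Re-index the map onto a retained subset of columns."""
        labels, unmapped = {}, set()
        for new, old in enumerate(kept_columns):
            if old in self.labels:
                labels[new] = self.labels[old]
            else:
                unmapped.add(new)
        return PositionMap(labels=labels, unmapped=frozenset(unmapped))


def build_position_map(
    msa: MSA, reference_id: str, labels: Optional[Sequence[str]] = None
) -> PositionMap:
    """Map alignment columns to reference numbering (1-based by default)."""
    ref_row = msa.rows[msa.index_of(reference_id)]
    ungapped = sum(1 for c in ref_row if c != GAP)
    if ungapped == 0:
        raise ValueError(f"reference {reference_id!r} is entirely gapped")
    if labels is not None and len(labels) != ungapped:
        raise ValueError(
            f"got {len(labels)} labels for {ungapped} ungapped reference residues"
        )
    mapping, unmapped = {}, set()
    k = 0
    for col, ch in enumerate(ref_row):
        if ch == GAP:
            unmapped.add(col)
        else:
            mapping[col] = str(labels[k]) if labels is not None else str(k + 1)
            k += 1
    return PositionMap(labels=mapping, unmapped=frozenset(unmapped))


def write_position_map(pmap: PositionMap, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["column_index", "reference_label"])
        for col in sorted(set(pmap.labels) | set(pmap.unmapped)):
            writer.writerow([col, pmap.labels.get(col, "")])


def read_position_map(path) -> PositionMap:
    labels, unmapped = {}, set()
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            col = int(rec["column_index"])
            if rec["reference_label"]:
                labels[col] = rec["reference_label"]
            else:
                unmapped.add(col)
    return PositionMap(labels=labels, unmapped=frozenset(unmapped))
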