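"""Sequence and annotation I/O, and the paired-numerical DNA encoding.

DNA letters are mapped onto a signed track in which the base pairs A/T and
C/G share a value (A,T -> +1; C,G -> -1).  Because paired bases collapse to
the same number, the encoding is strand-symmetric and is well suited to
extracting the three-base periodicity of coding regions.

Coordinates are 0-based, half-open everywhere inside the package; BED is
taken as-is and GFF3 (1-based, inclusive) is converted on ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DnaRecord",
    "NumericSequence",
    "ExonInterval",
    "read_fasta",
    "write_fasta",
    "map_paired_numeric",
    "read_annotations",
    "write_bed",
    "write_bedgraph",
    "write_track_tsv",
    "read_track_bedgraph",
    "read_track_tsv",
]


@dataclass(frozen=True)
class DnaRecord:
    """A named DNA sequence; uppercased on construction."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NumericSequence:
    """Per-position numeric track derived from a :class:`DnaRecord`."""

    record_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a nonempty 1-D array")

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True, order=True)
class ExonInterval:
    """0-based half-open exon interval on a named record."""

    record_id: str
    start: int
    end: int
    label: str = field(default="exon", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.record_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# Paired-numerical lookup: A/T -> +1, C/G -> -1, every other IUPAC code -> 0.
_PAIRED_LUT = np.zeros(128, dtype=float)
for _c in "AT":
    _PAIRED_LUT[ord(_c)] = 1.0
for _c in "CG":
    _PAIRED_LUT[ord(_c)] = -1.0


def map_paired_numeric(record: DnaRecord) -> NumericSequence:
    """Encode a DNA record as the +/-1 paired-numerical signal.

    A and T map to +1, C and G to -1; ambiguity codes (N, R, Y, ...) map to
    0 so they contribute nothing to either filter branch.  Zero-mapped
    symbols are counted and reported through the module logger.
    """
    raw = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
    values = _PAIRED_LUT[raw]
    n_ambiguous = int(np.count_nonzero(~np.isin(raw, [65, 67, 71, 84])))
    if n_ambiguous:
        logger.warning(
            "record %s: %d non-ACGT symbols zero-mapped", record.id, n_ambiguous
        )
    return NumericSequence(record_id=record.id, values=values)


def read_fasta(path: str | Path) -> list[DnaRecord]:
    """Read a (multi-)FASTA file into a list of :class:`DnaRecord`."""
    path = Path(path)
    records = [
        DnaRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[DnaRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def _validate_intervals(
    intervals: list[ExonInterval],
    lengths: dict[str, int] | None,
) -> list[ExonInterval]:
    """Check for overlaps within a record and (optionally) bounds."""
    intervals = sorted(intervals)
    problems: list[str] = []
    prev: ExonInterval | None = None
    for iv in intervals:
        if lengths is not None and iv.record_id in lengths:
            if iv.end > lengths[iv.record_id]:
                problems.append(
                    f"{iv.record_id}:{iv.start}-{iv.end} beyond record end "
                    f"{lengths[iv.record_id]}"
                )
        if prev is not None and prev.record_id == iv.record_id and iv.start < prev.end:
            problems.append(
                f"{iv.record_id}:{iv.start}-{iv.end} overlaps "
                f"{prev.start}-{prev.end}"
            )
        prev = iv
    if problems:
        raise ValueError("invalid annotation intervals: " + "; ".join(problems))
    return intervals


def read_annotations(
    path: str | Path,
    format: str = "BED",
    lengths: dict[str, int] | None = None,
) -> list[ExonInterval]:
    """Read exon annotations from BED3+ or GFF3.

    BED coordinates pass through unchanged; GFF3 1-based inclusive starts
    are shifted to the internal 0-based half-open convention.  Overlapping
    intervals (and, if record ``lengths`` are supplied, out-of-bounds ones)
    raise a ``ValueError`` listing every offender.
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unsupported annotation format {format!r}")
    path = Path(path)
    intervals: list[ExonInterval] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "BED":
                record_id, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else "exon"
            else:  # GFF3: seqid source type start end ...
                record_id = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])
                label = fields[2]
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {line!r}") from exc
        intervals.append(ExonInterval(record_id, start, end, label))
    return _validate_intervals(intervals, lengths)


def write_bed(intervals: Iterable[ExonInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.record_id}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def write_bedgraph(
    tracks: Sequence[tuple[str, np.ndarray]], path: str | Path
) -> None:
    """Write per-nucleotide scores as 4-column bedGraph (one row per base)."""
    with open(path, "w") as fh:
        for record_id, scores in tracks:
            for b, s in enumerate(np.asarray(scores, dtype=float)):
                fh.write(f"{record_id}\t{b}\t{b + 1}\t{s:.8g}\n")


def write_track_tsv(
    tracks: Sequence[tuple[str, np.ndarray]], path: str | Path
) -> None:
    """Write scores as a 3-column TSV: record, position, score."""
    with open(path, "w") as fh:
        fh.write("record\tposition\tscore\n")
        for record_id, scores in tracks:
            for b, s in enumerate(np.asarray(scores, dtype=float)):
                fh.write(f"{record_id}\t{b}\t{s:.8g}\n")


def _tracks_from_rows(
    rows: Iterable[tuple[str, int, float]]
) -> list[tuple[str, np.ndarray]]:
    by_record: dict[str, list[tuple[int, float]]] = {}
    for record_id, pos, score in rows:
        by_record.setdefault(record_id, []).append((pos, score))
    out = []
    for record_id, pairs in by_record.items():
        pairs.sort()
        out.append((record_id, np.array([s for _, s in pairs], dtype=float)))
    return out


def read_track_bedgraph(path: str | Path) -> list[tuple[str, np.ndarray]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        rows.append((f[0], int(f[1]), float(f[3])))
    return _tracks_from_rows(rows)


def read_track_tsv(path: str | Path) -> list[tuple[str, np.ndarray]]:
    rows = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        rows.append((f[0], int(f[1]), float(f[2])))
    return _tracks_from_rows(rows)
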