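"""Shared I/O, coordinate conventions and sequence plumbing.

Coordinates are 0-based half-open throughout the library and in BED files on
disk; human-readable reports print 1-based inclusive positions.  Sequences are
normalized to the alphabet {A, C, G, T, N}: lowercase (soft-masked) input is
upper-cased and scanned like any other sequence, and IUPAC ambiguity codes
other than N are coerced to N with a logged warning, because triplet and loop
logic is only defined on concrete bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger("lg4kit")

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """One normalized FASTA record (chromosome / contig)."""

    chrom: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """A BED-like half-open genomic interval.

    ``score`` follows BED conventions: either a number or the placeholder
    ``"."``.  Point features (variants, breakpoints) use ``end == start + 1``.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Upper-case ``seq`` and coerce any non-ACGTN character to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        log.warning(
            "coerced %d non-ACGTN character(s) %s to N%s",
            sum(seq.count(c) for c in bad),
            sorted(bad),
            f" in {context}" if context else "",
        )
        seq = seq.translate(str.maketrans({c: "N" for c in bad}))
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _prescan_fasta(path: Path) -> None:
    """Structural validation with line numbers (SeqIO is too forgiving)."""
    seen: dict[str, int] = {}
    in_records = False
    nonblank = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            nonblank += 1
            if stripped.startswith(">"):
                in_records = True
                ident = stripped[1:].split()[0] if stripped[1:].split() else ""
                if ident in seen:
                    raise FormatError(
                        f"{path}: duplicate record id {ident!r} at line {lineno} "
                        f"(first seen at line {seen[ident]})"
                    )
                seen[ident] = lineno
            elif not in_records:
                raise FormatError(
                    f"{path}: sequence data before first FASTA header at line {lineno}"
                )
    if nonblank == 0:
        raise FormatError(f"{path}: empty FASTA file")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Returns one :class:`GenomeRecord` per header, in file order, with
    normalization applied.  Rejects empty files, leading sequence data and
    duplicate identifiers, naming the offending line.
    """
    path = Path(path)
    _prescan_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            GenomeRecord(chrom=rec.id, seq=normalize_sequence(str(rec.seq), context=rec.id))
        )
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def records_by_chrom(records: Iterable[GenomeRecord]) -> dict[str, GenomeRecord]:
    return {rec.chrom: rec for rec in records}


def _format_score(score: float | str) -> str:
    if isinstance(score, str):
        return score
    if isinstance(score, float) and score == int(score):
        return str(int(score))
    return f"{score:g}"


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write 6-column BED, sorted by (chrom, start, end)."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name,
                        _format_score(iv.score),
                        iv.strand,
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED (3 to 6 columns) into Interval objects."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: fewer than 3 BED columns at line {lineno}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinate at line {lineno}") from exc
            name = cols[3] if len(cols) > 3 else "."
            score: float | str = "."
            if len(cols) > 4 and cols[4] != ".":
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 else "."
            try:
                out.append(Interval(cols[0], start, end, name, score, strand))
            except ValueError as exc:
                raise FormatError(f"{path}: {exc} at line {lineno}") from exc
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column chrom.sizes TSV into {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}: expected 2 columns at line {lineno}")
            if cols[0] in sizes:
                raise FormatError(f"{path}: duplicate chromosome {cols[0]!r} at line {lineno}")
            try:
                sizes[cols[0]] = int(cols[1])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer length at line {lineno}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def validate_intervals(intervals: Iterable[Interval], chrom_sizes: Mapping[str, int]) -> None:
    """Check every interval fits inside its chromosome."""
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"{iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length "
                f"{chrom_sizes[iv.chrom]}"
            )
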