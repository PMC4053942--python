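"""Readers and writers for the standard formats the toolkit touches.

All internal coordinates are 0-based half-open. The only 1-based inclusive
coordinates in the package live in :class:`MatchRecord`, which mirrors the
``show-coords -T -H`` convention of MUMmer so externally computed repeat
tables can be used verbatim.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]

# IUPAC nucleotide codes; anything beyond these is a format error.
_IUPAC = set("ACGTURYSWKMBDHVN")
_CIRCULAR_TOKEN = re.compile(r"circular\s*=\s*(true|false)", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Replicon:
    """A single chromosome or plasmid.

    Bacterial replicons are circular by default throughout the toolkit;
    ``circular`` can be overridden per record (``circular=false`` in the
    FASTA header) or per run.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.name!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSet:
    """An ordered collection of replicons making up one genome."""

    replicons: List[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicons]
        if len(names) != len(set(names)):
            raise ValueError("replicon names must be unique within a genome")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)

    def __iter__(self):
        return iter(self.replicons)

    def __len__(self) -> int:
        return len(self.replicons)

    def __getitem__(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass
class ShortAlignment:
    """A short-read-to-long-read alignment (PAF semantics).

    ``target_*`` coordinates are 0-based half-open positions on the long
    read; ``strand`` is the orientation of the short read relative to it.
    """

    query_name: str
    target_name: str
    strand: str
    target_start: int
    target_end: int
    query_start: int = 0
    query_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(
                f"alignment {self.query_name!r}->{self.target_name!r}: "
                f"need 0 <= start < end, got [{self.target_start}, {self.target_end})"
            )


@dataclass
class MatchRecord:
    """One repeat match between two genomic loci.

    Coordinates are 1-based inclusive, as printed by ``show-coords``.  An
    inverted match is flagged by ``orientation`` and carries a decreasing
    second coordinate pair (``ref_b_start > ref_b_end``).
    """

    ref_a_start: int
    ref_a_end: int
    ref_b_start: int
    ref_b_end: int
    identity: float
    replicon_a: str
    replicon_b: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity must be in [0, 100], got {self.identity}")
        if self.orientation not in ("forward", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def len_a(self) -> int:
        return self.ref_a_end - self.ref_a_start + 1

    @property
    def len_b(self) -> int:
        return abs(self.ref_b_end - self.ref_b_start) + 1

    @property
    def span(self) -> int:
        return max(self.len_a, self.len_b)


def _open_text(path: PathLike) -> io.TextIOBase:
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path: PathLike, circular_default: bool = True) -> GenomeSet:
    """Read a (possibly gzipped) multi-FASTA file into a :class:`GenomeSet`.

    Lower-case bases are upper-cased.  A ``circular=true`` / ``circular=false``
    token in the record description overrides ``circular_default``.
    """
    replicons = []
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"record {record.id!r} is empty")
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"record {record.id!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            circ = circular_default
            m = _CIRCULAR_TOKEN.search(record.description)
            if m:
                circ = m.group(1).lower() == "true"
            replicons.append(Replicon(record.id, seq, circular=circ))
    if not replicons:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSet(replicons)


def write_fasta(genome: GenomeSet, path: PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.name,
            description=f"circular={'true' if r.circular else 'false'}",
        )
        for r in genome
    ]
    with open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_length_file(path: PathLike) -> List[int]:
    """Read a plain list of read lengths, one positive integer per line.

    Blank lines are skipped; anything else that is not a positive integer is
    a parse error reported with its line number.
    """
    lengths = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                value = int(line)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: not an integer: {line!r}")
            if value <= 0:
                raise FormatError(f"{path}:{lineno}: length must be positive, got {value}")
            lengths.append(value)
    if not lengths:
        raise FormatError(f"{path}: no read lengths found")
    return lengths


def read_paf(path: PathLike) -> List[ShortAlignment]:
    """Parse minimal PAF (columns 1-12) into :class:`ShortAlignment` records.

    Column 6 is taken as the *target* (long read) name and columns 8/9 as the
    coordinates on it, kept 0-based half-open as in PAF.
    """
    alignments = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >=12 columns, got {len(cols)}")
            try:
                aln = ShortAlignment(
                    query_name=cols[0],
                    target_name=cols[5],
                    strand=cols[4],
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
            alignments.append(aln)
    return alignments


def read_coords_table(path: PathLike) -> List[MatchRecord]:
    """Parse a ``show-coords -T -H`` style table into match records.

    Expected columns: S1 E1 S2 E2 LEN1 LEN2 %IDY TAG1 TAG2 (whitespace or
    tab separated).  Orientation is inverted when S2 > E2.
    """
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("=", "/", "NUCMER")):
                continue
            cols = line.split()
            if len(cols) < 9:
                raise FormatError(
                    f"{path}:{lineno}: expected >=9 columns "
                    f"(S1 E1 S2 E2 LEN1 LEN2 %IDY TAG1 TAG2), got {len(cols)}"
                )
            try:
                s1, e1, s2, e2 = (int(c) for c in cols[:4])
                identity = float(cols[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
            orientation = "inverted" if s2 > e2 else "forward"
            records.append(
                MatchRecord(
                    ref_a_start=s1,
                    ref_a_end=e1,
                    ref_b_start=s2,
                    ref_b_end=e2,
                    identity=identity,
                    replicon_a=cols[7],
                    replicon_b=cols[8],
                    orientation=orientation,
                )
            )
    return records


_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
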