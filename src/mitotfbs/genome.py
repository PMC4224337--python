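"""Circular-coordinate genome model shared by every analysis stage.

Human mtDNA is a ~16.5-kb circle; every coordinate in this package is a
1-based inclusive position on that circle, matching the rCRS convention
used throughout the mitochondrial literature.  Features that cross the
origin (position L -> 1) are represented natively with a ``wraps`` flag
and only split into two records on BED export.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeError(ValueError):
    """Malformed sequence, annotation, or coordinate input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a circle; ``wraps`` marks origin crossing."""

    start: int
    end: int
    wraps: bool = False

    @classmethod
    def from_endpoints(cls, start: int, end: int, L: int) -> "GenomicInterval":
        if not (1 <= start <= L and 1 <= end <= L):
            raise GenomeError(f"interval endpoints ({start}, {end}) outside 1..{L}")
        return cls(start, end, wraps=end < start)

    def length(self, L: int) -> int:
        if self.wraps:
            return L - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, pos: int, L: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def positions(self, L: int) -> Iterator[int]:
        p = self.start
        for _ in range(self.length(L)):
            yield p
            p = p % L + 1

    def overlaps(self, other: "GenomicInterval", L: int) -> bool:
        # small intervals relative to L: positions() is cheap and exact
        mine = set(self.positions(L))
        return any(p in mine for p in other.positions(L))

    def to_bed_rows(self, L: int, name: str = ".", score: int = 0,
                    strand: str = ".") -> list[tuple]:
        """BED6 rows (0-based half-open); wrapping intervals split in two."""
        chrom = "chrM"
        if not self.wraps:
            return [(chrom, self.start - 1, self.end, name, score, strand)]
        return [
            (chrom, self.start - 1, L, name, score, strand),
            (chrom, 0, self.end, name, score, strand),
        ]


@dataclass(frozen=True)
class CircularGenome:
    """Uppercase DNA sequence over {A,C,G,T,N} with modulo-L position arithmetic."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise GenomeError(f"non-DNA characters in {self.name!r}: {sorted(bad)}")
        if not seq:
            raise GenomeError("empty genome sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        return self.sequence[(pos - 1) % self.length]

    def fetch(self, start: int, length: int) -> str:
        """Slice of exactly ``length`` bases starting at 1-based ``start``, wrapping."""
        if length < 0 or length > self.length:
            raise GenomeError(f"slice length {length} outside 0..{self.length}")
        i = (start - 1) % self.length
        doubled = self.sequence + self.sequence
        return doubled[i:i + length]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.start, iv.length(self.length))

    def rotate(self, k: int) -> "CircularGenome":
        """Cut the first ``k`` bases and paste them at the end.

        This reproduces the two-reference trick used to call features that
        straddle the origin of a circular genome on linear tooling.  Use
        :func:`rotated_to_original` / :func:`original_to_rotated` to map
        coordinates between the two numberings.
        """
        L = self.length
        if not 0 <= k < L:
            raise GenomeError(f"rotation offset {k} outside 0..{L - 1}")
        return CircularGenome(self.name, self.sequence[k:] + self.sequence[:k])


def rotate_genome(g: CircularGenome, k: int) -> CircularGenome:
    return g.rotate(k)


def original_to_rotated(pos: int, k: int, L: int) -> int:
    """Map a 1-based position on the original circle onto rotate(k) numbering."""
    return (pos - k - 1) % L + 1


def rotated_to_original(pos: int, k: int, L: int) -> int:
    return (pos + k - 1) % L + 1


@dataclass(frozen=True)
class GeneAnnotation:
    """Protein-coding gene span with reading-frame phase.

    ``end < start`` encodes an origin-spanning gene.  ``phase`` is the offset
    (0/1/2) of the first complete codon from the gene's 5' end on its strand.
    """

    gene: str
    start: int
    end: int
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError(f"{self.gene}: strand must be '+' or '-', got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise GenomeError(f"{self.gene}: phase must be 0, 1 or 2, got {self.phase!r}")
        if self.start < 1 or self.end < 1:
            raise GenomeError(f"{self.gene}: coordinates must be >= 1")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.start, self.end, wraps=self.end < self.start)

    def length(self, L: int) -> int:
        return self.interval().length(L)


def codon_position(pos: int, ann: GeneAnnotation, L: int) -> int | None:
    """Within-codon index (1, 2 or 3) of ``pos`` in the reading frame of ``ann``.

    Returns ``None`` when ``pos`` is outside the gene, inside the partial
    codon trimmed by ``phase``, or inside an incomplete trailing codon.  On
    the minus strand counting proceeds from ``ann.end`` toward ``ann.start``
    (i.e. along the reverse complement).
    """
    if not 1 <= pos <= L:
        raise GenomeError(f"position {pos} outside 1..{L}")
    iv = ann.interval()
    if not iv.contains(pos, L):
        return None
    glen = iv.length(L)
    if ann.strand == "+":
        offset = (pos - ann.start) % L
    else:
        offset = (ann.end - pos) % L
    offset -= ann.phase
    if offset < 0:
        return None
    n_complete = (glen - ann.phase) // 3
    if offset >= 3 * n_complete:
        return None
    return offset % 3 + 1


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[CircularGenome]:
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise GenomeError(f"empty FASTA record {rec.id!r} in {path}")
        genomes.append(CircularGenome(rec.id, str(rec.seq)))
    if not genomes:
        raise GenomeError(f"no FASTA records in {path}")
    return genomes


def read_genome(path: str | Path) -> CircularGenome:
    return read_fasta(path)[0]


def write_fasta(genomes: Iterable[CircularGenome] | CircularGenome,
                path: str | Path) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """TSV with columns gene, start, end, strand, phase (header optional)."""
    anns: list[GeneAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if ln == 1 and row[0].lower() == "gene":
                continue
            if len(row) < 5:
                raise GenomeError(f"{path}:{ln}: expected 5 columns, got {len(row)}")
            try:
                anns.append(GeneAnnotation(row[0], int(row[1]), int(row[2]),
                                           row[3], int(row[4])))
            except (ValueError, GenomeError) as exc:
                raise GenomeError(f"{path}:{ln}: {exc}") from exc
    return anns


def write_annotations(anns: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "start", "end", "strand", "phase"])
        for a in anns:
            w.writerow([a.gene, a.start, a.end, a.strand, a.phase])


def write_bed(intervals: Iterable[tuple[GenomicInterval, str, int, str]],
              L: int, path: str | Path) -> None:
    """Write (interval, name, score, strand) tuples as BED6."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for iv, name, score, strand in intervals:
            for row in iv.to_bed_rows(L, name, score, strand):
                w.writerow(row)
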