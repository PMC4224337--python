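"""Discriminating cytoplasmic-mtDNA reads from NUMT reads.

Nuclear mitochondrial pseudogenes (NUMTs) are mtDNA-derived segments in
the nuclear genome; reads deriving from them can masquerade as mtDNA
signal.  Given a pre-aligned NUMT candidate sequence for a binding-site
region, every position where it differs from the mtDNA defines a
diagnostic allele pair, and each read is classified by the alleles it
carries at the diagnostics it covers: consistent mtDNA alleles at every
covered diagnostic -> mt-like, consistent NUMT alleles -> numt-like, and
everything else (mixed alleles, third alleles, or no covered diagnostic)
-> ambiguous.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomicInterval

log = logging.getLogger(__name__)

DEFAULT_FLANK = 50  # bp added on each side of a TFBS when building regions


class NumtError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticSet:
    """Positions distinguishing the mtDNA region from its best NUMT hit."""

    region: GenomicInterval
    positions: tuple[tuple[int, str, str], ...]  # (pos, mt_allele, numt_allele)

    def __post_init__(self) -> None:
        for pos, mt, nu in self.positions:
            if mt == nu or len(mt) != 1 or len(nu) != 1:
                raise NumtError(f"bad diagnostic at {pos}: {mt!r} vs {nu!r}")


@dataclass(frozen=True)
class AlignedRead:
    """Gapless read placed on genome coordinates (1-based start)."""

    start: int
    sequence: str

    def covers(self, pos: int, L: int) -> bool:
        offset = (pos - self.start) % L
        return offset < len(self.sequence)

    def base_at(self, pos: int, L: int) -> str | None:
        offset = (pos - self.start) % L
        if offset >= len(self.sequence):
            return None
        return self.sequence[offset]


@dataclass
class ReadClassSummary:
    """Per-position tallies over the diagnostic region plus read totals."""

    per_position: dict[int, tuple[int, int, int]]  # pos -> (mt, numt, ambiguous)
    n_mt: int
    n_numt: int
    n_ambiguous: int
    numt_mean: float
    numt_sd: float
    coverage_mean: float
    coverage_sd: float

    @property
    def n_reads(self) -> int:
        return self.n_mt + self.n_numt + self.n_ambiguous

    def contamination_estimate(self) -> float:
        """numt-like fraction among classified (non-ambiguous) reads."""
        classified = self.n_mt + self.n_numt
        return self.n_numt / classified if classified else float("nan")


def find_diagnostic_positions(mt_region_seq: str, numt_seq: str,
                              region: GenomicInterval) -> DiagnosticSet:
    """Character-wise comparison of two pre-aligned, gapless sequences."""
    if len(mt_region_seq) != len(numt_seq):
        raise NumtError(f"aligned sequences differ in length "
                        f"({len(mt_region_seq)} vs {len(numt_seq)})")
    mt = mt_region_seq.upper()
    nu = numt_seq.upper()
    # enumerate genomic positions along the (possibly wrapping) region
    diags = []
    pos = region.start
    for i in range(len(mt)):
        if mt[i] != nu[i]:
            diags.append((pos, mt[i], nu[i]))
        pos = pos + 1
    return DiagnosticSet(region, tuple(diags))


def classify_read(read: AlignedRead, diag: DiagnosticSet, L: int) -> str:
    """'mt', 'numt' or 'ambiguous' from alleles at covered diagnostics only."""
    mt_votes = numt_votes = other = covered = 0
    for pos, mt_allele, numt_allele in diag.positions:
        base = read.base_at(pos, L)
        if base is None:
            continue
        covered += 1
        if base == mt_allele:
            mt_votes += 1
        elif base == numt_allele:
            numt_votes += 1
        else:
            other += 1
    if covered == 0 or other > 0 or (mt_votes and numt_votes):
        return "ambiguous"
    return "mt" if mt_votes else "numt"


def classify_reads(reads: list[AlignedRead], diag: DiagnosticSet,
                   L: int) -> ReadClassSummary:
    """Classify every read and tally per-position counts over the region.

    Per position, only reads covering that position are counted, so the
    three classes always sum to the covering-read depth there.
    """
    labels = [classify_read(r, diag, L) for r in reads]
    per_position: dict[int, tuple[int, int, int]] = {}
    numt_counts: list[int] = []
    cov_counts: list[int] = []
    for pos in diag.region.positions(L):
        mt = numt = amb = 0
        for read, label in zip(reads, labels):
            if read.covers(pos, L):
                if label == "mt":
                    mt += 1
                elif label == "numt":
                    numt += 1
                else:
                    amb += 1
        per_position[pos] = (mt, numt, amb)
        numt_counts.append(numt)
        cov_counts.append(mt + numt + amb)
    numt_arr = np.array(numt_counts, dtype=float)
    cov_arr = np.array(cov_counts, dtype=float)
    return ReadClassSummary(
        per_position,
        n_mt=labels.count("mt"),
        n_numt=labels.count("numt"),
        n_ambiguous=labels.count("ambiguous"),
        numt_mean=float(numt_arr.mean()) if numt_arr.size else 0.0,
        numt_sd=float(numt_arr.std()) if numt_arr.size else 0.0,
        coverage_mean=float(cov_arr.mean()) if cov_arr.size else 0.0,
        coverage_sd=float(cov_arr.std()) if cov_arr.size else 0.0,
    )


def consensus_from_reads(reads: list[AlignedRead], L: int,
                         min_coverage: int = 1) -> tuple[str, float]:
    """Majority-base consensus over the circle; low-coverage/tied positions masked.

    Masked positions are written as lowercase 'n'.  Returns the consensus
    string and the fraction of positions with coverage >= min_coverage and
    an unambiguous majority.
    """
    if min_coverage < 1:
        raise NumtError("min_coverage must be >= 1")
    counts = np.zeros((L, 4), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for read in reads:
        start0 = (read.start - 1) % L
        for i, base in enumerate(read.sequence.upper()):
            j = base_idx.get(base)
            if j is not None:
                counts[(start0 + i) % L, j] += 1
    depth = counts.sum(axis=1)
    best = counts.max(axis=1)
    ties = (counts == best[:, None]).sum(axis=1) > 1
    callable_pos = (depth >= min_coverage) & ~ties & (best > 0)
    n_ties = int((ties & (depth >= min_coverage)).sum())
    if n_ties:
        log.info("consensus: %d position(s) masked due to base ties", n_ties)
    bases = np.array(list("ACGT"))
    consensus = np.full(L, "n", dtype="<U1")
    consensus[callable_pos] = bases[counts.argmax(axis=1)[callable_pos]]
    return "".join(consensus), float(callable_pos.sum()) / L


def linked_variant_support(reads: list[AlignedRead], pos_a: int, pos_b: int,
                           allele_a: str, allele_b: str, L: int) -> int:
    """Number of reads covering both positions and carrying both alleles."""
    n = 0
    for read in reads:
        ba = read.base_at(pos_a, L)
        bb = read.base_at(pos_b, L)
        if ba == allele_a.upper() and bb == allele_b.upper():
            n += 1
    return n


# ---------------------------------------------------------------------------
# I/O: reads as TSV (start, sequence); summary as TSV


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("start"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise NumtError(f"{path}:{ln}: expected 'start sequence'")
            reads.append(AlignedRead(int(parts[0]), parts[1].upper()))
    return reads


def write_reads_tsv(reads: list[AlignedRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["start", "sequence"])
        for r in reads:
            w.writerow([r.start, r.sequence])


def summary_to_tsv(summary: ReadClassSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["pos", "mt_like", "numt_like", "ambiguous"])
        for pos, (mt, numt, amb) in sorted(summary.per_position.items()):
            w.writerow([pos, mt, numt, amb])
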