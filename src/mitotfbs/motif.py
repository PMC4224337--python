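"""JASPAR-style motif models and circular-genome scanning.

A position frequency matrix (PFM) holds per-column base counts; it is
converted to a log-odds position weight matrix (PWM) with a pseudocount
spread over a background distribution.  Scores are reported both in bits
and as the JASPAR-style *relative score*

    rel = (score - smin) / (smax - smin)   in [0, 1],

where smax/smin are the best and worst achievable scores, so a threshold
(default 0.80) is comparable across motifs of different widths.  Scanning
is strand-aware and treats the genome as a circle: windows spanning the
origin are scored like any other.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import CircularGenome, GenomicInterval, GenomeError, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_THRESHOLD = 0.80
DEFAULT_PSEUDOCOUNT = 0.8
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class MotifError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    motif_id: str
    counts: np.ndarray  # shape (4, W), rows A,C,G,T

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise MotifError(f"{self.motif_id}: counts must be 4xW")
        if (counts < 0).any():
            raise MotifError(f"{self.motif_id}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise MotifError(f"{self.motif_id}: zero-sum column")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def to_pwm(self, pseudocount: float = DEFAULT_PSEUDOCOUNT,
               background: Sequence[float] = UNIFORM_BACKGROUND) -> "PositionWeightMatrix":
        return pfm_to_pwm(self, pseudocount, background)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Base-2 log-odds weights with cached per-column extrema."""

    motif_id: str
    weights: np.ndarray  # shape (4, W)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4:
            raise MotifError(f"{self.motif_id}: weights must be 4xW")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def smax(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def smin(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))

    def reverse_complement(self) -> "PositionWeightMatrix":
        # complement = reverse row order (A<->T, C<->G), then reverse columns
        return PositionWeightMatrix(self.motif_id, self.weights[::-1, ::-1].copy())

    def relative(self, score: float) -> float:
        span = self.smax - self.smin
        if span <= 0:
            return 1.0
        return (score - self.smin) / span


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float
    relative_score: float
    site_sequence: str


def pfm_to_pwm(pfm: PositionFrequencyMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT,
               background: Sequence[float] = UNIFORM_BACKGROUND) -> PositionWeightMatrix:
    """weight(b, i) = log2(((n_bi + c*q_b) / (N_i + c)) / q_b)."""
    if pseudocount <= 0:
        raise MotifError("pseudocount must be > 0")
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or (q <= 0).any() or not math.isclose(q.sum(), 1.0, abs_tol=1e-9):
        raise MotifError("background must be 4 positive probabilities summing to 1")
    col_sums = pfm.counts.sum(axis=0)
    prob = (pfm.counts + pseudocount * q[:, None]) / (col_sums + pseudocount)
    weights = np.log2(prob / q[:, None])
    return PositionWeightMatrix(pfm.motif_id, weights)


def score_window(pwm: PositionWeightMatrix, seq: str) -> tuple[float, float]:
    """Sum of per-column weights for a W-mer; raises on N or wrong width."""
    if len(seq) != pwm.width:
        raise MotifError(f"window length {len(seq)} != motif width {pwm.width}")
    idx = encode(seq.upper())
    if (idx < 0).any():
        raise MotifError("ambiguous base (N) in window")
    score = float(pwm.weights[idx, np.arange(pwm.width)].sum())
    return score, pwm.relative(score)


def _scan_one_strand(codes: np.ndarray, pwm_weights: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every start 1..L on the doubled encoding; returns (scores, valid)."""
    W = pwm_weights.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)[:L]
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = pwm_weights[safe, np.arange(W)].sum(axis=1)
    return scores, valid


def scan_circular(g: CircularGenome, pwm: PositionWeightMatrix,
                  threshold: float = DEFAULT_THRESHOLD,
                  strands: str = "both") -> list[MotifHit]:
    """All windows on the circle (both strands) with relative score >= threshold.

    Minus-strand hits score the reverse complement of the genomic window and
    are reported on original (plus-strand) coordinates.  Windows containing N
    are skipped.  The threshold bound is closed (ties are hits).
    """
    if not 0.0 <= threshold <= 1.0:
        raise MotifError(f"threshold {threshold} outside [0, 1]")
    L, W = g.length, pwm.width
    if W > L:
        raise MotifError(f"motif width {W} exceeds genome length {L}")
    if strands not in ("both", "+", "-"):
        raise MotifError(f"strands must be 'both', '+' or '-'")

    codes = encode(g.sequence + g.sequence[:W - 1] if W > 1 else g.sequence)
    span = pwm.smax - pwm.smin
    hits: list[MotifHit] = []
    todo = [("+", pwm.weights)] if strands == "+" else \
           [("-", pwm.reverse_complement().weights)] if strands == "-" else \
           [("+", pwm.weights), ("-", pwm.reverse_complement().weights)]
    for strand, weights in todo:
        scores, valid = _scan_one_strand(codes, weights, L)
        rel = (scores - pwm.smin) / span if span > 0 else np.ones_like(scores)
        for i in np.nonzero(valid & (rel >= threshold))[0]:
            start = int(i) + 1
            end = (start + W - 2) % L + 1
            iv = GenomicInterval(start, end, wraps=end < start)
            window = g.fetch(start, W)
            site = window if strand == "+" else reverse_complement(window)
            hits.append(MotifHit(pwm.motif_id, iv, strand,
                                 float(scores[i]), float(rel[i]), site))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def apply_variant_and_rescore(hit: MotifHit, pwm: PositionWeightMatrix,
                              variant: tuple[int, str, str], g: CircularGenome,
                              threshold: float = DEFAULT_THRESHOLD) -> tuple[float, bool]:
    """Relative score of the hit window with a single substitution applied.

    The variant is given on plus-strand genomic coordinates; for minus-strand
    hits the substituted window is reverse-complemented before scoring.
    Returns ``(new_relative_score, retained)`` with ``retained`` meaning the
    rescored site still clears the scan threshold.
    """
    pos, ref, alt = variant
    L = g.length
    if not hit.interval.contains(pos, L):
        raise MotifError(f"variant position {pos} outside hit {hit.interval}")
    if g.base(pos) != ref.upper():
        raise MotifError(f"reference mismatch at {pos}: genome has {g.base(pos)}, "
                         f"variant says {ref}")
    offset = (pos - hit.interval.start) % L
    window = list(g.fetch(hit.interval.start, pwm.width))
    window[offset] = alt.upper()
    mutated = "".join(window)
    if hit.strand == "-":
        mutated = reverse_complement(mutated)
    _, rel = score_window(pwm, mutated)
    return rel, rel >= threshold


# ---------------------------------------------------------------------------
# JASPAR flat-format I/O

_ROW_RE = re.compile(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$")


def read_jaspar(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Read JASPAR PFM flat files, bracketed or plain 4-row dialect."""
    pfms: list[PositionFrequencyMatrix] = []
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise MotifError(f"{path}: expected '>' header at line {i + 1}")
        motif_id = lines[i][1:].strip().split()[0] or f"motif{len(pfms) + 1}"
        rows: dict[str, list[float]] = {}
        i += 1
        for _ in range(4):
            if i >= len(lines):
                raise MotifError(f"{path}: truncated matrix for {motif_id}")
            m = _ROW_RE.match(lines[i])
            if m:
                base, values = m.group(1), m.group(2)
            else:
                # plain dialect: 4 bare rows in A,C,G,T order
                base = BASES[len(rows)]
                values = lines[i].strip(" []")
            rows[base] = [float(v) for v in values.split()]
            i += 1
        counts = np.array([rows[b] for b in BASES])
        pfms.append(PositionFrequencyMatrix(motif_id, counts))
    return pfms


def write_jaspar(pfms: Iterable[PositionFrequencyMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id}\n")
            for b in BASES:
                row = " ".join(f"{v:g}" for v in pfm.counts[_BASE_INDEX[b]])
                fh.write(f"{b} [ {row} ]\n")


def hits_to_bed(hits: Sequence[MotifHit], L: int, path: str | Path) -> None:
    from .genome import write_bed
    write_bed(((h.interval, h.motif_id, round(1000 * h.relative_score), h.strand)
               for h in hits), L, path)
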