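"""DNase footprint F-scores and extreme-site calling on circular tracks.

For each position p on the circle a 3w-bp window (default 60 bp) is split
into proximal, central and distal fragments of w bp each, and

    F = (C + 1) / L + (C + 1) / R

is computed from the three fragment means (C central, L proximal flank,
R distal flank).  Protein-protected stretches depress the central counts
and yield low F; nucleosome-free/hypersensitive stretches raise them and
yield high F.  Positions where either flank mean is zero are undefined
(NaN) because the published form adds the +1 guard only to C; a
``flank_pseudocount`` option is provided for users who prefer a guarded
denominator, documented as a deviation from the printed formula.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import GenomicInterval, GenomeError

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 20
DEFAULT_PERCENTILE = 0.01
DEFAULT_MERGE_GAP = 5


class FootprintError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageTrack:
    name: str
    counts: np.ndarray  # per-position read counts, length L, circular

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size == 0:
            raise FootprintError("counts must be a nonempty 1-D array")
        if (counts < 0).any():
            raise FootprintError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.size

    def rotate(self, k: int) -> "CoverageTrack":
        return CoverageTrack(self.name, np.roll(self.counts, -k))


def fscore_profile(track: CoverageTrack, w: int = DEFAULT_WINDOW,
                   flank_pseudocount: float = 0.0) -> np.ndarray:
    """Per-position F values (index i = position i+1); NaN where undefined.

    Position p is taken as the ((w+1)//2)-th base of the central fragment
    (base 10 for the default w=20); the proximal and distal fragments are
    the w bp immediately before and after the central one, wrapping at the
    origin.
    """
    if w <= 0:
        raise FootprintError(f"fragment width must be positive, got {w}")
    L = track.length
    if 3 * w > L:
        raise FootprintError(f"3w = {3 * w} exceeds track length {L}")
    c = track.counts
    # circular w-bp window sums for every start
    ext = np.concatenate([c, c[:w - 1]]) if w > 1 else c
    sums = np.convolve(ext, np.ones(w), mode="valid")[:L]
    off = (w + 1) // 2 - 1  # central fragment starts at p - off
    starts = (np.arange(L) - off) % L
    C = sums[starts] / w
    Lf = sums[(starts - w) % L] / w
    Rf = sums[(starts + w) % L] / w
    if flank_pseudocount > 0:
        Lf = Lf + flank_pseudocount
        Rf = Rf + flank_pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (C + 1.0) / Lf + (C + 1.0) / Rf
    F[(Lf <= 0) | (Rf <= 0)] = np.nan
    return F


def call_extreme_sites(profile: np.ndarray, percentile: float = DEFAULT_PERCENTILE,
                       mode: str = "lowest",
                       merge_gap: int = DEFAULT_MERGE_GAP) -> list[GenomicInterval]:
    """Positions with F in the extreme ``percentile``, merged into intervals.

    ``k = ceil(percentile * n_defined)`` positions are selected from the
    sorted defined F values (ties at the cut value are all included), then
    runs separated by gaps <= ``merge_gap`` are merged, wrapping across the
    origin.  Undefined (NaN) positions are never called.
    """
    if not 0.0 < percentile < 1.0:
        raise FootprintError(f"percentile {percentile} outside (0, 1)")
    if mode not in ("lowest", "highest"):
        raise FootprintError(f"mode must be 'lowest' or 'highest', got {mode!r}")
    profile = np.asarray(profile, dtype=float)
    L = profile.size
    defined = ~np.isnan(profile)
    n_def = int(defined.sum())
    if n_def == 0:
        log.warning("all F values undefined; no sites called")
        return []
    k = max(1, math.ceil(percentile * n_def))
    values = np.sort(profile[defined])
    if mode == "lowest":
        cut = values[k - 1]
        selected = defined & (profile <= cut)
    else:
        cut = values[n_def - k]
        selected = defined & (profile >= cut)
    return merge_positions(np.nonzero(selected)[0] + 1, L, merge_gap)


def merge_positions(positions: np.ndarray, L: int, merge_gap: int) -> list[GenomicInterval]:
    """Merge sorted 1-based positions into circular intervals (gap <= merge_gap)."""
    positions = np.asarray(positions, dtype=int)
    if positions.size == 0:
        return []
    if positions.size == L:
        return [GenomicInterval(1, L)]
    runs: list[list[int]] = [[int(positions[0]), int(positions[0])]]
    for p in positions[1:]:
        if p - runs[-1][1] - 1 <= merge_gap:
            runs[-1][1] = int(p)
        else:
            runs.append([int(p), int(p)])
    # wrap join: gap from last run's end, across the origin, to first run's start
    if len(runs) > 1:
        wrap_gap = (runs[0][0] - 1) + (L - runs[-1][1])
        if wrap_gap <= merge_gap:
            first = runs.pop(0)
            runs[-1][1] = first[1]
            return [GenomicInterval(s, e, wraps=e < s) for s, e in runs]
    return [GenomicInterval(s, e, wraps=e < s) for s, e in runs]


# ---------------------------------------------------------------------------
# I/O: coverage as bedGraph or 2-column TSV (pos, count)


def read_coverage(path: str | Path, L: int | None = None,
                  name: str = "chrM") -> CoverageTrack:
    path = Path(path)
    rows: list[tuple[int, int, float]] = []  # 0-based half-open
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) >= 4:  # bedGraph: chrom start end value
                rows.append((int(parts[1]), int(parts[2]), float(parts[3])))
            elif len(parts) == 2:  # TSV: pos (1-based), count
                pos = int(parts[0])
                rows.append((pos - 1, pos, float(parts[1])))
            else:
                raise FootprintError(f"{path}:{ln}: unrecognized coverage row")
    if not rows:
        raise FootprintError(f"{path}: no coverage rows")
    size = L if L is not None else max(e for _, e, _ in rows)
    counts = np.zeros(size)
    for s, e, v in rows:
        counts[s:e] = v
    return CoverageTrack(name, counts)


def write_bedgraph(values: np.ndarray, path: str | Path, chrom: str = "chrM") -> None:
    """Write per-position values as bedGraph, collapsing equal-value runs."""
    values = np.asarray(values, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        start = 0
        for i in range(1, values.size + 1):
            if i == values.size or values[i] != values[start] \
                    or (np.isnan(values[i]) != np.isnan(values[start])):
                v = values[start]
                w.writerow([chrom, start, i, "nan" if np.isnan(v) else f"{v:g}"])
                start = i
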