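"""Strand-aware kernel-density ChIP peak calling on the mtDNA circle.

This is a deliberately simplified caller in the spirit of kernel-density
ChIP peak estimation: per-strand read-start counts are smoothed with a
Gaussian kernel (sd = ``bandwidth``), the plus-strand density is shifted
downstream and the minus-strand density upstream by half the library
fragment size, and candidate peaks are local maxima of the combined
density that clear a candidate threshold and a fold-enrichment ratio over
a matched background track.  The expected bimodal strand pattern (plus
sub-peak upstream of the minus sub-peak, separated by roughly one
fragment length) is reported per peak.

Density units: each read contributes a unit-area Gaussian, so the raw
density integrates to the read count.  The candidate threshold is
expressed in *equivalent overlapping fragments*: a density d corresponds
to ``d * bandwidth * sqrt(2*pi)`` co-occurring fragment starts, so the
default threshold of 30 demands roughly 30 overlapping fragments.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .genome import GenomicInterval

log = logging.getLogger(__name__)


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class StrandedStarts:
    """Per-position 5' read-start counts for each strand, circular."""

    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        plus = np.asarray(self.plus, dtype=float)
        minus = np.asarray(self.minus, dtype=float)
        if plus.shape != minus.shape or plus.ndim != 1 or plus.size == 0:
            raise PeakError("plus/minus must be equal-length nonempty 1-D arrays")
        if (plus < 0).any() or (minus < 0).any():
            raise PeakError("negative start counts")
        object.__setattr__(self, "plus", plus)
        object.__setattr__(self, "minus", minus)

    @property
    def length(self) -> int:
        return self.plus.size

    @property
    def total(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def rotate(self, k: int) -> "StrandedStarts":
        return StrandedStarts(np.roll(self.plus, -k), np.roll(self.minus, -k))


@dataclass(frozen=True)
class PeakCallerConfig:
    candidate_threshold: float = 30.0   # equivalent overlapping fragments
    enrichment_ratio: float = 3.0       # chip/background density fold
    fragment_size: int = 120            # library fragment length, bp
    bandwidth: float = 40.0             # Gaussian kernel sd, bp
    q_percentile: float = 0.01          # optional rank filter on q values

    def __post_init__(self) -> None:
        if min(self.candidate_threshold, self.enrichment_ratio,
               self.fragment_size, self.bandwidth) <= 0:
            raise PeakError("all peak-caller parameters must be positive")
        if not 0.0 < self.q_percentile < 1.0:
            raise PeakError("q_percentile must lie in (0, 1)")

    @property
    def density_to_fragments(self) -> float:
        return self.bandwidth * math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class PeakCall:
    summit: int
    interval: GenomicInterval
    chip_density: float          # combined density at summit (reads/bp)
    background_density: float    # scaled background density at summit
    enrichment: float
    strand_separation: int | None  # bp between +/- sub-peaks (circular)
    bimodal: bool
    p_raw: float
    q_proxy: float


def _gaussian_kernel(sd: float) -> np.ndarray:
    radius = int(math.ceil(4 * sd))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()  # unit mass discretely, so density area == read count


def _smooth_circular(counts: np.ndarray, sd: float) -> np.ndarray:
    return ndimage.convolve1d(counts, _gaussian_kernel(sd), mode="wrap")


def kde_profile(starts: StrandedStarts, cfg: PeakCallerConfig
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(plus_density, minus_density, combined) on the circle.

    The plus density is shifted downstream and the minus density upstream
    by fragment_size // 2, so both strands pile up over the binding point.
    """
    if cfg.fragment_size >= starts.length / 2:
        raise PeakError(f"fragment_size {cfg.fragment_size} too large for "
                        f"track of length {starts.length}")
    if starts.total == 0:
        log.warning("empty start counts; densities are all zero")
    shift = cfg.fragment_size // 2
    plus = np.roll(_smooth_circular(starts.plus, cfg.bandwidth), shift)
    minus = np.roll(_smooth_circular(starts.minus, cfg.bandwidth), -shift)
    return plus, minus, plus + minus


def _circular_delta(a: int, b: int, L: int) -> int:
    """Signed shortest offset from a to b on the circle, in (-L/2, L/2]."""
    d = (b - a) % L
    return d if d <= L // 2 else d - L


def _local_maxima(d: np.ndarray) -> np.ndarray:
    """Indices of circular local maxima; plateaus yield their first index."""
    return np.nonzero((d >= np.roll(d, 1)) & (d > np.roll(d, -1)))[0]


def call_peaks(chip: StrandedStarts, background: StrandedStarts,
               cfg: PeakCallerConfig = PeakCallerConfig(),
               apply_q_filter: bool = False) -> list[PeakCall]:
    """Candidate peaks with enrichment, bimodality and a Poisson tail test.

    Candidates are local maxima of the combined ChIP density whose height
    clears ``candidate_threshold`` (in equivalent-fragment units) and whose
    fold over the depth-scaled background density clears
    ``enrichment_ratio``.  Candidates closer than one fragment length are
    merged, keeping the highest.  ``p_raw`` is the Poisson upper-tail
    probability of the ChIP start count within the peak interval given the
    scaled background count; ``q_proxy`` is its Benjamini-Hochberg
    adjustment across peaks (a documented proxy, not a reproduction of any
    specific caller's q value).
    """
    if chip.length != background.length:
        raise PeakError("chip and background tracks differ in length")
    L = chip.length
    _, _, combined = kde_profile(chip, cfg)
    plus_raw = _smooth_circular(chip.plus, cfg.bandwidth)    # unshifted, for bimodality
    minus_raw = _smooth_circular(chip.minus, cfg.bandwidth)

    if background.total == 0:
        log.warning("background has no reads; using a uniform pseudo-background")
        bg_density = np.full(L, chip.total / L)
        scale = 1.0
    else:
        _, _, bg_density = kde_profile(background, cfg)
        scale = chip.total / background.total
        bg_density = bg_density * scale

    eff = combined * cfg.density_to_fragments
    floor = 1e-12
    enrichment = combined / np.maximum(bg_density, floor)

    cand = [i for i in _local_maxima(combined)
            if eff[i] >= cfg.candidate_threshold
            and enrichment[i] >= cfg.enrichment_ratio]
    # merge candidates within one fragment length, highest first
    cand.sort(key=lambda i: -combined[i])
    summits: list[int] = []
    for i in cand:
        if all(abs(_circular_delta(i, j, L)) >= cfg.fragment_size for j in summits):
            summits.append(i)

    half_span = int(cfg.fragment_size + 2 * cfg.bandwidth)
    chip_starts = chip.plus + chip.minus
    bg_starts = background.plus + background.minus
    calls: list[PeakCall] = []
    for s in summits:
        half_max = combined[s] / 2.0
        left = s
        for _ in range(half_span):
            nxt = (left - 1) % L
            if combined[nxt] < half_max:
                break
            left = nxt
        right = s
        for _ in range(half_span):
            nxt = (right + 1) % L
            if combined[nxt] < half_max:
                break
            right = nxt
        iv = GenomicInterval(left + 1, right + 1, wraps=right < left)

        # bimodality: nearest strand sub-peaks around the summit
        lo = np.arange(s - half_span, s + half_span + 1) % L
        p_sub = int(lo[np.argmax(plus_raw[lo])])
        m_sub = int(lo[np.argmax(minus_raw[lo])])
        sep = _circular_delta(p_sub, m_sub, L)
        bimodal = (sep > 0 and
                   cfg.fragment_size - cfg.bandwidth <= sep <= cfg.fragment_size + cfg.bandwidth)

        idx = np.fromiter(iv.positions(L), dtype=int) - 1
        k = float(chip_starts[idx].sum())
        lam = scale * max(float(bg_starts[idx].sum()), 1.0) if background.total > 0 \
            else chip.total * iv.length(L) / L
        p_raw = float(stats.poisson.sf(k - 1, lam))
        calls.append(PeakCall(s + 1, iv, float(combined[s]),
                              float(bg_density[s]), float(enrichment[s]),
                              int(sep) if sep is not None else None, bimodal,
                              p_raw, q_proxy=1.0))

    calls = _attach_q(calls)
    calls.sort(key=lambda c: -c.chip_density)
    if apply_q_filter and calls:
        qs = np.array([c.q_proxy for c in calls])
        cut = np.quantile(qs, cfg.q_percentile) if len(calls) > 1 else qs[0]
        calls = [c for c in calls if c.q_proxy <= cut]
    return calls


def _attach_q(calls: list[PeakCall]) -> list[PeakCall]:
    """Benjamini-Hochberg over p_raw."""
    if not calls:
        return calls
    n = len(calls)
    order = np.argsort([c.p_raw for c in calls])
    q = np.empty(n)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = n - rank_from_last
        prev = min(prev, calls[idx].p_raw * n / rank)
        q[idx] = prev
    return [PeakCall(c.summit, c.interval, c.chip_density, c.background_density,
                     c.enrichment, c.strand_separation, c.bimodal, c.p_raw,
                     float(q[i])) for i, c in enumerate(calls)]


def mito_nuclear_ratio(mt_peak_reads: float, nuclear_site_reads: list[float]) -> float:
    """mtDNA peak reads over the mean of nuclear-site read counts."""
    if not nuclear_site_reads:
        raise PeakError("nuclear site read list is empty")
    mean = float(np.mean(nuclear_site_reads))
    if mean <= 0:
        raise PeakError("mean nuclear read count is zero; ratio undefined")
    return float(mt_peak_reads) / mean


# ---------------------------------------------------------------------------
# I/O: stranded starts as 3-column TSV (pos, strand, count)


def read_starts(path: str | Path, L: int) -> StrandedStarts:
    plus = np.zeros(L)
    minus = np.zeros(L)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("pos"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3 or parts[1] not in ("+", "-"):
                raise PeakError(f"{path}:{ln}: expected 'pos strand count'")
            pos, strand, count = int(parts[0]), parts[1], float(parts[2])
            (plus if strand == "+" else minus)[(pos - 1) % L] += count
    return StrandedStarts(plus, minus)


def write_starts(starts: StrandedStarts, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["pos", "strand", "count"])
        for strand, arr in (("+", starts.plus), ("-", starts.minus)):
            for i in np.nonzero(arr)[0]:
                w.writerow([i + 1, strand, f"{arr[i]:g}"])


def peaks_to_table(calls: list[PeakCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["summit", "start", "end", "wraps", "chip_density",
                    "background_density", "enrichment", "strand_separation",
                    "bimodal", "p_raw", "q_proxy"])
        for c in calls:
            w.writerow([c.summit, c.interval.start, c.interval.end,
                        int(c.interval.wraps), f"{c.chip_density:.6g}",
                        f"{c.background_density:.6g}", f"{c.enrichment:.6g}",
                        c.strand_separation, int(c.bimodal),
                        f"{c.p_raw:.6g}", f"{c.q_proxy:.6g}"])
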