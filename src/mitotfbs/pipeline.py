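"""End-to-end selection screen: variants -> tip/nodal -> decision tree -> summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genome import CircularGenome, GeneAnnotation
from .motif import MotifHit, PositionWeightMatrix, DEFAULT_THRESHOLD
from .selection import (CprCnrSummary, SelectionCall, classify_site,
                        compare_cpr_cnr)
from .variants import (LineageTable, MIN_CARRIERS, MIN_FRACTION,
                       VariantObservation, classify_variants,
                       filter_third_codon)

log = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    cpr_calls: list[SelectionCall]
    cnr_calls: list[SelectionCall]
    summary: CprCnrSummary | None
    classified: list  # (VariantObservation, VariantClass) after third-codon filter


def label_cpr_cnr(hits: Sequence[MotifHit], peak_intervals: Sequence,
                  L: int) -> tuple[list[MotifHit], list[MotifHit]]:
    """A motif hit is CPR when it overlaps any called peak interval, else CNR."""
    cpr, cnr = [], []
    for h in hits:
        if any(h.interval.overlaps(iv, L) for iv in peak_intervals):
            cpr.append(h)
        else:
            cnr.append(h)
    return cpr, cnr


def run_selection_screen(genome: CircularGenome,
                         annotations: Sequence[GeneAnnotation],
                         pwm: PositionWeightMatrix,
                         cpr_hits: Sequence[MotifHit],
                         cnr_hits: Sequence[MotifHit],
                         variants: Sequence[VariantObservation],
                         lineages: LineageTable,
                         threshold: float = DEFAULT_THRESHOLD,
                         min_carriers: int = MIN_CARRIERS,
                         min_fraction: float = MIN_FRACTION) -> ScreenResult:
    """Third-codon filter -> tip/nodal classification -> per-site decision tree.

    Variants are first restricted to third codon positions (so selection on
    the motif is separated from selection on the encoded protein), then
    classified against the lineage table, assigned to containing sites, and
    run through the negative-selection decision tree.  The CPR/CNR summary
    is computed when at least one CNR site exists.
    """
    L = genome.length
    third = filter_third_codon(variants, annotations, L)
    classified = classify_variants(third, lineages, min_carriers, min_fraction)

    def calls_for(hits: Sequence[MotifHit]) -> list[SelectionCall]:
        calls = []
        for hit in hits:
            in_site = [(v, vc) for v, vc in classified
                       if hit.interval.contains(v.pos, L)]
            calls.append(classify_site(hit, in_site, pwm, genome, threshold))
        return calls

    cpr_calls = calls_for(cpr_hits)
    cnr_calls = calls_for(cnr_hits)
    summary = compare_cpr_cnr(cpr_calls, cnr_calls) if cnr_calls else None
    return ScreenResult(cpr_calls, cnr_calls, summary, classified)
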