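"""Negative-selection decision tree per motif site and CPR/CNR comparison.

A motif site is consistent with negative selection when it (1) harbors no
population variants at all, (2) harbors only tip variants (too young for
selection to have acted), or (3) harbors nodal variants whose substituted
alleles all retain the motif prediction score above the scan threshold.
A site with any score-disrupting nodal variant is not consistent: an old
motif-breaking allele survived, which purifying selection on the site
would have removed.

ChIP-positive regions (CPRs, predicted motifs overlapped by an observed
binding peak) are the test set; ChIP-negative regions (CNRs, predicted
motifs with no peak) provide the null distribution of nodal counts and
retention fractions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import CircularGenome, GenomicInterval
from .motif import MotifHit, PositionWeightMatrix, apply_variant_and_rescore, DEFAULT_THRESHOLD
from .variants import VariantClass, VariantObservation

log = logging.getLogger(__name__)

CONSISTENT_CATEGORIES = frozenset({"NO_VARIANTS", "TIPS_ONLY", "NODAL_RETAINED"})


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRescore:
    variant: VariantObservation
    variant_class: str
    new_relative_score: float
    retained: bool


@dataclass(frozen=True)
class SelectionCall:
    site_id: str
    site: MotifHit
    category: str  # NO_VARIANTS | TIPS_ONLY | NODAL_RETAINED | NODAL_DISRUPTED
    consistent_with_negative_selection: bool
    rescored: tuple[VariantRescore, ...]

    @property
    def n_tip(self) -> int:
        return sum(1 for r in self.rescored if r.variant_class == "tip")

    @property
    def n_nodal(self) -> int:
        return sum(1 for r in self.rescored if r.variant_class == "nodal")

    @property
    def n_unclassified(self) -> int:
        return sum(1 for r in self.rescored if r.variant_class == "unclassified")

    @property
    def fraction_retaining(self) -> float:
        """Share of this site's variants whose rescored motif stays above threshold."""
        if not self.rescored:
            return float("nan")
        return sum(r.retained for r in self.rescored) / len(self.rescored)


@dataclass(frozen=True)
class CprCnrSummary:
    cnr_nodal_counts: tuple[int, ...]
    cnr_five_number: tuple[float, float, float, float, float]  # min Q1 med Q3 max
    cnr_mean: float
    cpr_nodal_counts: tuple[int, ...]
    cpr_percentiles: tuple[float, ...]  # per CPR site, within the CNR distribution
    cpr_fraction_retaining: tuple[float, ...]
    cnr_fraction_retaining: tuple[float, ...]


def classify_site(site: MotifHit, site_variants: Sequence[tuple[VariantObservation, VariantClass]],
                  pwm: PositionWeightMatrix, g: CircularGenome,
                  threshold: float = DEFAULT_THRESHOLD,
                  site_id: str | None = None) -> SelectionCall:
    """Decision tree for one motif site.

    ``site_variants`` pairs each (third-codon, in-site) variant with its
    tip/nodal class.  The category is decided by the classified variants:
    nodal variants, if any, decide between NODAL_RETAINED and
    NODAL_DISRUPTED via rescoring; otherwise tips give TIPS_ONLY; a site
    with no tip or nodal variants is NO_VARIANTS.  Unclassified variants
    are rescored and reported but by default decide nothing (they are
    neither demonstrably old nor single-carrier young).
    """
    L = g.length
    rescored: list[VariantRescore] = []
    for v, vc in site_variants:
        if not site.interval.contains(v.pos, L):
            raise SelectionError(f"variant at {v.pos} outside site "
                                 f"{site.interval.start}-{site.interval.end}")
        rel, retained = apply_variant_and_rescore(
            site, pwm, (v.pos, v.ref, v.alt), g, threshold)
        rescored.append(VariantRescore(v, vc.label, rel, retained))

    nodal = [r for r in rescored if r.variant_class == "nodal"]
    tips = [r for r in rescored if r.variant_class == "tip"]
    if nodal:
        category = "NODAL_RETAINED" if all(r.retained for r in nodal) \
            else "NODAL_DISRUPTED"
    elif tips:
        category = "TIPS_ONLY"
    else:
        category = "NO_VARIANTS"
    return SelectionCall(
        site_id or f"{site.motif_id}:{site.interval.start}-{site.interval.end}",
        site, category, category in CONSISTENT_CATEGORIES, tuple(rescored))


def compare_cpr_cnr(cpr_calls: Sequence[SelectionCall],
                    cnr_calls: Sequence[SelectionCall]) -> CprCnrSummary:
    """Descriptive CPR-vs-CNR comparison (no significance test is asserted).

    The CNR nodal-count distribution is summarized by its five-number
    summary and mean; each CPR site's empirical percentile is the fraction
    of CNR sites with nodal count <= the CPR's.
    """
    if not cnr_calls:
        raise SelectionError("empty CNR set: null distribution undefined")
    cnr_counts = np.array([c.n_nodal for c in cnr_calls])
    cpr_counts = np.array([c.n_nodal for c in cpr_calls]) if cpr_calls else np.array([], int)
    five = (float(cnr_counts.min()),
            float(np.percentile(cnr_counts, 25)),
            float(np.median(cnr_counts)),
            float(np.percentile(cnr_counts, 75)),
            float(cnr_counts.max()))
    percentiles = tuple(float((cnr_counts <= c).mean()) for c in cpr_counts)
    return CprCnrSummary(
        cnr_nodal_counts=tuple(int(c) for c in cnr_counts),
        cnr_five_number=five,
        cnr_mean=float(cnr_counts.mean()),
        cpr_nodal_counts=tuple(int(c) for c in cpr_counts),
        cpr_percentiles=percentiles,
        cpr_fraction_retaining=tuple(c.fraction_retaining for c in cpr_calls),
        cnr_fraction_retaining=tuple(c.fraction_retaining for c in cnr_calls),
    )


def crossref_dnase(cnr_calls: Sequence[SelectionCall],
                   dnase_sites: Sequence[GenomicInterval],
                   L: int) -> pd.DataFrame:
    """Mark CNRs that colocalize with DNase-called intervals.

    CNRs overlapping a footprint/hypersensitivity interval may be true
    binding sites of other factors; those that additionally carry no
    variants or only tips are flagged as selection-consistent candidates.
    """
    rows = []
    for call in cnr_calls:
        overlapping = any(call.site.interval.overlaps(iv, L) for iv in dnase_sites)
        rows.append({
            "site_id": call.site_id,
            "start": call.site.interval.start,
            "end": call.site.interval.end,
            "dnase_overlap": overlapping,
            "category": call.category,
            "consistent": call.consistent_with_negative_selection,
            "candidate_functional": overlapping and
                call.category in ("NO_VARIANTS", "TIPS_ONLY"),
        })
    return pd.DataFrame(rows, columns=["site_id", "start", "end", "dnase_overlap",
                                       "category", "consistent",
                                       "candidate_functional"])


# ---------------------------------------------------------------------------
# Reports


def calls_to_tsv(calls: Sequence[SelectionCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["site_id", "start", "end", "strand", "category", "consistent",
                    "n_tip", "n_nodal", "n_unclassified", "min_rescored_rel",
                    "fraction_retaining"])
        for c in calls:
            min_rel = min((r.new_relative_score for r in c.rescored), default=float("nan"))
            w.writerow([c.site_id, c.site.interval.start, c.site.interval.end,
                        c.site.strand, c.category,
                        int(c.consistent_with_negative_selection),
                        c.n_tip, c.n_nodal, c.n_unclassified,
                        f"{min_rel:.4f}", f"{c.fraction_retaining:.4f}"])


def summary_to_tsv(summary: CprCnrSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metric", "value"])
        mn, q1, med, q3, mx = summary.cnr_five_number
        w.writerow(["cnr_nodal_min", mn])
        w.writerow(["cnr_nodal_q1", q1])
        w.writerow(["cnr_nodal_median", med])
        w.writerow(["cnr_nodal_q3", q3])
        w.writerow(["cnr_nodal_max", mx])
        w.writerow(["cnr_nodal_mean", f"{summary.cnr_mean:.4f}"])
        w.writerow(["cpr_nodal_counts", ",".join(map(str, summary.cpr_nodal_counts))])
        w.writerow(["cpr_percentiles", ",".join(f"{p:.4f}" for p in summary.cpr_percentiles)])
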