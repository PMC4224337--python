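"""Tip/nodal classification of population variants against a lineage table.

Variants observed in a single individual sit at the tips of the
phylogeny: they are young and have had little exposure to selection.
Variants shared by a clade (here: at least ``min_carriers`` individuals
who make up at least ``min_fraction`` of some named sublineage) are nodal:
they are old enough for purifying selection to have had the opportunity
to remove them.  Everything in between (2-4 carriers, or >=5 carriers
with no sublineage concentrated enough) is left unclassified and excluded
from both tallies.

Lineages are haplogroup-style label paths (coarse to fine, e.g.
``L3/N/R/H1``); a sublineage is the set of sampled individuals sharing
any path prefix.  An adapter converts a Newick tree with labeled internal
nodes into this representation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import GeneAnnotation, GenomicInterval, GenomeError, codon_position
from .motif import MotifHit

log = logging.getLogger(__name__)

MIN_CARRIERS = 5
MIN_FRACTION = 0.85


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantObservation:
    pos: int
    ref: str
    alt: str
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if not self.carriers:
            raise VariantError(f"variant {self.pos}{self.ref}>{self.alt}: no carriers")
        if self.ref == self.alt:
            raise VariantError(f"variant at {self.pos}: ref equals alt")


@dataclass(frozen=True)
class VariantClass:
    label: str                        # 'tip', 'nodal' or 'unclassified'
    sublineage: tuple[str, ...] | None = None
    carrier_fraction: float | None = None


class LineageTable:
    """individual id -> lineage path (tuple of labels, coarse to fine)."""

    def __init__(self, paths: Mapping[str, Sequence[str]]):
        if not paths:
            raise VariantError("empty lineage table")
        self.paths: dict[str, tuple[str, ...]] = {}
        for ind, path in paths.items():
            path = tuple(path)
            if not path:
                raise VariantError(f"individual {ind!r} has an empty lineage path")
            self.paths[ind] = path
        # members of every prefix-defined sublineage
        self._groups: dict[tuple[str, ...], set[str]] = {}
        for ind, path in self.paths.items():
            for depth in range(1, len(path) + 1):
                self._groups.setdefault(path[:depth], set()).add(ind)

    def __len__(self) -> int:
        return len(self.paths)

    def __contains__(self, ind: str) -> bool:
        return ind in self.paths

    @property
    def individuals(self) -> set[str]:
        return set(self.paths)

    def sublineages(self) -> dict[tuple[str, ...], set[str]]:
        return self._groups

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "/") -> "LineageTable":
        paths: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("id\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise VariantError(f"{path}:{ln}: expected 'id<TAB>path'")
                paths[parts[0]] = tuple(parts[1].split(sep))
        return cls(paths)

    def to_tsv(self, path: str | Path, sep: str = "/") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "lineage"])
            for ind in sorted(self.paths):
                w.writerow([ind, sep.join(self.paths[ind])])

    @classmethod
    def from_newick(cls, path_or_string: str | Path) -> "LineageTable":
        """Leaf paths = labels of internal ancestors, root to parent.

        Unlabeled internal nodes receive synthetic ``nodeN`` labels so that
        every clade of the tree remains addressable as a sublineage.
        """
        import dendropy

        text = str(path_or_string)
        if Path(text).exists():
            tree = dendropy.Tree.get(path=text, schema="newick")
        else:
            tree = dendropy.Tree.get(data=text, schema="newick")
        counter = 0
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and not node.label:
                counter += 1
                node.label = f"node{counter}"
        paths: dict[str, tuple[str, ...]] = {}
        for leaf in tree.leaf_node_iter():
            labels = [a.label for a in leaf.ancestor_iter()][::-1]
            paths[leaf.taxon.label] = tuple(labels) if labels else ("root",)
        return cls(paths)


def classify_variant(v: VariantObservation, lt: LineageTable,
                     min_carriers: int = MIN_CARRIERS,
                     min_fraction: float = MIN_FRACTION) -> VariantClass:
    """Apply the tip/nodal definition to one variant.

    tip: a single carrier.  nodal: some sublineage S has at least
    ``min_carriers`` carriers comprising at least ``min_fraction`` of S;
    the smallest such S is reported (ties: deepest path, then
    lexicographic).  Otherwise unclassified.
    """
    unknown = v.carriers - lt.individuals
    if unknown:
        raise VariantError(f"variant at {v.pos}: unknown carrier ids {sorted(unknown)}")
    if len(v.carriers) == 1:
        return VariantClass("tip")
    if len(v.carriers) < min_carriers:
        return VariantClass("unclassified")
    best: tuple[int, int, tuple[str, ...]] | None = None
    best_frac = 0.0
    for prefix, members in lt.sublineages().items():
        inside = len(v.carriers & members)
        if inside >= min_carriers and inside / len(members) >= min_fraction:
            key = (len(members), -len(prefix), prefix)
            if best is None or key < best:
                best = key
                best_frac = inside / len(members)
    if best is None:
        return VariantClass("unclassified")
    return VariantClass("nodal", sublineage=best[2], carrier_fraction=best_frac)


def classify_variants(variants: Iterable[VariantObservation], lt: LineageTable,
                      min_carriers: int = MIN_CARRIERS,
                      min_fraction: float = MIN_FRACTION
                      ) -> list[tuple[VariantObservation, VariantClass]]:
    return [(v, classify_variant(v, lt, min_carriers, min_fraction))
            for v in variants]


def filter_third_codon(variants: Iterable[VariantObservation],
                       annotations: Sequence[GeneAnnotation],
                       L: int) -> list[VariantObservation]:
    """Variants sitting at codon position 3 of the gene containing them.

    When a position falls inside several annotated genes, the first
    annotation in file order is treated as the primary gene and the
    overlap is logged.
    """
    kept: list[VariantObservation] = []
    for v in variants:
        containing = [a for a in annotations if a.interval().contains(v.pos, L)]
        if not containing:
            continue
        if len(containing) > 1:
            log.info("position %d inside %d overlapping genes; using %s",
                     v.pos, len(containing), containing[0].gene)
        if codon_position(v.pos, containing[0], L) == 3:
            kept.append(v)
    return kept


def tabulate_tip_nodal(classified: Sequence[tuple[VariantObservation, VariantClass]],
                       site_sets: Mapping[str, Sequence[MotifHit]],
                       L: int) -> pd.DataFrame:
    """Per-site tip/nodal/unclassified counts for labeled site sets (CPR/CNR)."""
    rows = []
    for set_label, hits in site_sets.items():
        for hit in hits:
            tip = nodal = uncl = 0
            for v, vc in classified:
                if hit.interval.contains(v.pos, L):
                    if vc.label == "tip":
                        tip += 1
                    elif vc.label == "nodal":
                        nodal += 1
                    else:
                        uncl += 1
            rows.append({"set": set_label, "motif_id": hit.motif_id,
                         "start": hit.interval.start, "end": hit.interval.end,
                         "strand": hit.strand, "n_tip": tip, "n_nodal": nodal,
                         "n_unclassified": uncl})
    return pd.DataFrame(rows, columns=["set", "motif_id", "start", "end",
                                       "strand", "n_tip", "n_nodal",
                                       "n_unclassified"])


# ---------------------------------------------------------------------------
# I/O: variants as TSV (pos, ref, alt, carriers) or a minimal haploid VCF


def read_variants_tsv(path: str | Path) -> list[VariantObservation]:
    out: list[VariantObservation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("pos"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise VariantError(f"{path}:{ln}: expected 'pos ref alt carriers'")
            carriers = frozenset(c for c in parts[3].split(",") if c)
            out.append(VariantObservation(int(parts[0]), parts[1].upper(),
                                          parts[2].upper(), carriers))
    return out


def write_variants_tsv(variants: Iterable[VariantObservation],
                       path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["pos", "ref", "alt", "carriers"])
        for v in sorted(variants, key=lambda v: (v.pos, v.alt)):
            w.writerow([v.pos, v.ref, v.alt, ",".join(sorted(v.carriers))])


def read_variants_vcf(path: str | Path) -> list[VariantObservation]:
    """Minimal haploid VCF subset: CHROM POS ID REF ALT ... FORMAT samples.

    A sample carries the variant when its genotype field starts with '1'.
    Multi-allelic rows are split per alternate allele.
    """
    out: list[VariantObservation] = []
    samples: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VariantError(f"{path}: VCF has no sample columns")
                samples = cols[9:]
                continue
            if not samples:
                raise VariantError(f"{path}:{ln}: data row before #CHROM header")
            cols = line.split("\t")
            pos, ref, alts = int(cols[1]), cols[3].upper(), cols[4].upper().split(",")
            gts = [c.split(":")[0] for c in cols[9:]]
            for ai, alt in enumerate(alts, start=1):
                carriers = frozenset(s for s, g in zip(samples, gts)
                                     if g.split("/")[0].split("|")[0] == str(ai))
                if carriers:
                    out.append(VariantObservation(pos, ref, alt, carriers))
    return out


def classified_to_tsv(classified: Sequence[tuple[VariantObservation, VariantClass]],
                      path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["pos", "ref", "alt", "n_carriers", "class", "sublineage",
                    "carrier_fraction"])
        for v, vc in classified:
            w.writerow([v.pos, v.ref, v.alt, len(v.carriers), vc.label,
                        "/".join(vc.sublineage) if vc.sublineage else "",
                        f"{vc.carrier_fraction:.4f}" if vc.carrier_fraction else ""])
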