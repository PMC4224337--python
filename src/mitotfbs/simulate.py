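"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the study conditions this package
analyzes: a panel of full-length circular mtDNA-like sequences carrying
clade-shared (nodal) and singleton (tip) variants with optional purifying
selection at designated motifs; stranded ChIP-seq read starts with the
bimodal strand offset around planted sites over a uniform background,
optionally with NUMT-derived contaminant reads; and DNase cut-count
tracks with protected and hypersensitive intervals.

Population model
----------------
A two-level clade structure stands in for the mtDNA phylogeny: the panel
is divided into clades (lineages), each hanging from one internal stem
branch.  Mutations drawn on a stem propagate to the whole clade (true
class: nodal); mutations drawn on a leaf affect one individual (true
class: tip).  Mutation positions are drawn from a weighted distribution
that up-weights third codon positions and planted motif footprints, so
that a panel of a few hundred sequences yields per-site variant counts
comparable to what a population panel of thousands produces.  When a
motif is flagged ``selected``, any stem mutation whose substituted allele
would drop the motif's relative score below the scan threshold is
rejected and redrawn — purifying selection acting on old alleles only.
Leaf mutations are never rejected: young alleles have not yet been
exposed to selection.

All randomness flows through one ``numpy.random.Generator``; the same
seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .footprint import CoverageTrack
from .genome import (CircularGenome, GeneAnnotation, GenomicInterval,
                     codon_position, reverse_complement)
from .motif import (BASES, DEFAULT_THRESHOLD, MotifHit, PositionFrequencyMatrix,
                    PositionWeightMatrix, score_window)
from .numt import AlignedRead, DiagnosticSet
from .peaks import StrandedStarts
from .variants import LineageTable, VariantObservation

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Reference genome, genes, planted motifs


def random_genome(L: int, rng: np.random.Generator,
                  name: str = "synthetic_mtdna") -> CircularGenome:
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=L)])
    return CircularGenome(name, seq)


def tile_genes(L: int, n_genes: int = 2) -> list[GeneAnnotation]:
    """Plus-strand genes tiling the whole circle, each a multiple of 3 bp.

    Gene starts are congruent modulo 3, so the reading frame is global and
    a motif planted at start ≡ 1 (mod 3) has its columns 3, 6, 9, ... on
    third codon positions.  Requires L divisible by 3.
    """
    if L % 3:
        raise SimulationError(f"L = {L} not divisible by 3")
    n_codons = L // 3
    per = n_codons // n_genes
    anns = []
    start = 1
    for i in range(n_genes):
        codons = per if i < n_genes - 1 else n_codons - per * (n_genes - 1)
        end = start + 3 * codons - 1
        anns.append(GeneAnnotation(f"gene{i + 1}", start, end, "+", 0))
        start = end + 1
    return anns


def selection_test_pfm(motif_id: str = "synthTF", width: int = 9,
                       seed: int = 7) -> PositionFrequencyMatrix:
    """A mixed-information PFM whose critical columns sit at codon position 3.

    Columns 3, 6, 9, ... (the third codon positions when the motif is
    planted in frame) are high-information (97/1/1/1): any substitution
    there drops the relative score below the 0.80 scan threshold.  The
    remaining columns are low-information (35/25/25/15): substitutions
    there are tolerated.  This mirrors the biological scenario under
    study: binding-energy-critical bases at synonymous sites, where the
    protein sequence leaves selection on the motif free to act.
    """
    rng = np.random.default_rng(seed)
    counts = np.empty((4, width))
    for col in range(width):
        if (col + 1) % 3 == 0:
            profile = np.array([97.0, 1.0, 1.0, 1.0])
        else:
            profile = np.array([35.0, 25.0, 25.0, 15.0])
        counts[:, col] = rng.permutation(profile)
    return PositionFrequencyMatrix(motif_id, counts)


@dataclass(frozen=True)
class PlantedMotif:
    motif_id: str
    pwm: PositionWeightMatrix
    start: int           # 1-based; consensus occupies [start, start + W - 1]
    strand: str
    selected: bool

    def interval(self, L: int) -> GenomicInterval:
        end = (self.start + self.pwm.width - 2) % L + 1
        return GenomicInterval(self.start, end, wraps=end < self.start)

    def hit(self, g: CircularGenome) -> MotifHit:
        iv = self.interval(g.length)
        window = g.fetch(self.start, self.pwm.width)
        site = window if self.strand == "+" else reverse_complement(window)
        score, rel = score_window(self.pwm, site)
        return MotifHit(self.motif_id, iv, self.strand, score, rel, site)


def plant_motifs(g: CircularGenome, motifs: Sequence[PlantedMotif]) -> CircularGenome:
    """Overwrite each planted footprint with the motif's consensus sequence."""
    seq = list(g.sequence)
    L = g.length
    for m in motifs:
        site = m.pwm.consensus
        if m.strand == "-":
            site = reverse_complement(site)
        for i, base in enumerate(site):
            seq[(m.start - 1 + i) % L] = base
    return CircularGenome(g.name, "".join(seq))


# ---------------------------------------------------------------------------
# Population simulation


@dataclass(frozen=True)
class PopulationConfig:
    n_clades: int = 20
    clade_size: int = 10
    n_groups: int = 4              # coarse lineages grouping the clades
    mu_internal: float = 3.0       # expected mutations per clade stem
    mu_leaf: float = 0.5           # expected mutations per leaf
    third_codon_weight: float = 5.0
    motif_weight: float = 400.0
    threshold: float = DEFAULT_THRESHOLD
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.n_clades < 1 or self.clade_size < 1:
            raise SimulationError("clade counts must be positive")
        if self.mu_internal < 0 or self.mu_leaf < 0:
            raise SimulationError("mutation rates must be non-negative")


@dataclass(frozen=True)
class MutationEvent:
    pos: int
    ref: str
    alt: str
    branch: str          # 'internal' or 'leaf'
    carrier_group: str   # clade label or individual id
    true_class: str      # 'nodal' or 'tip'


@dataclass
class PopulationTruth:
    events: list[MutationEvent]
    clade_members: dict[str, list[str]]
    selected_motif_ids: list[str]

    def observations(self) -> list[tuple[VariantObservation, str]]:
        """Pool events into per-(pos, alt) observations with expected classes.

        The expected class follows the printed definitions applied to the
        true carrier history: any stem event makes the pooled observation
        nodal; a lone leaf event is a tip; independently recurring leaf
        events at the same position and allele produce a multi-carrier
        observation that is, by definition, neither.
        """
        pooled: dict[tuple[int, str, str], list[MutationEvent]] = {}
        for ev in self.events:
            pooled.setdefault((ev.pos, ev.ref, ev.alt), []).append(ev)
        out = []
        for (pos, ref, alt), evs in sorted(pooled.items()):
            carriers: set[str] = set()
            for ev in evs:
                if ev.branch == "internal":
                    carriers.update(self.clade_members[ev.carrier_group])
                else:
                    carriers.add(ev.carrier_group)
            if any(ev.branch == "internal" for ev in evs):
                expected = "nodal"
            elif len(carriers) == 1:
                expected = "tip"
            else:
                expected = "unclassified"
            out.append((VariantObservation(pos, ref, alt, frozenset(carriers)),
                        expected))
        return out


def _position_weights(g: CircularGenome, annotations: Sequence[GeneAnnotation],
                      motifs: Sequence[PlantedMotif],
                      cfg: PopulationConfig) -> np.ndarray:
    L = g.length
    w = np.ones(L)
    for ann in annotations:
        for pos in ann.interval().positions(L):
            if codon_position(pos, ann, L) == 3:
                w[pos - 1] *= cfg.third_codon_weight
    for m in motifs:
        for pos in m.interval(L).positions(L):
            w[pos - 1] *= cfg.motif_weight
    return w / w.sum()


def _disrupts_selected(pos: int, alt: str, g: CircularGenome,
                       motifs: Sequence[PlantedMotif], threshold: float) -> bool:
    from .motif import apply_variant_and_rescore
    for m in motifs:
        if m.selected and m.interval(g.length).contains(pos, g.length):
            hit = m.hit(g)
            _, retained = apply_variant_and_rescore(
                hit, m.pwm, (pos, g.base(pos), alt), g, threshold)
            if not retained:
                return True
    return False


def simulate_population(g: CircularGenome, annotations: Sequence[GeneAnnotation],
                        motifs: Sequence[PlantedMotif], cfg: PopulationConfig,
                        rng: np.random.Generator
                        ) -> tuple[dict[str, str], LineageTable, PopulationTruth]:
    """Sequences, lineage table and ground truth for a clade-structured panel."""
    L = g.length
    weights = _position_weights(g, annotations, motifs, cfg)
    positions = np.arange(1, L + 1)
    other = {b: [x for x in BASES if x != b] for b in BASES}

    clade_members: dict[str, list[str]] = {}
    paths: dict[str, tuple[str, ...]] = {}
    for c in range(cfg.n_clades):
        clade = f"C{c:02d}"
        group = f"G{c % cfg.n_groups}"
        members = [f"{clade}_i{j:02d}" for j in range(cfg.clade_size)]
        clade_members[clade] = members
        for ind in members:
            paths[ind] = (group, clade)
    lineages = LineageTable(paths)

    events: list[MutationEvent] = []

    def draw_mutation(used: set[int], reject_disrupting: bool) -> tuple[int, str, str]:
        for _ in range(cfg.max_redraws):
            pos = int(rng.choice(positions, p=weights))
            if pos in used:
                continue
            ref = g.base(pos)
            alt = other[ref][rng.integers(0, 3)]
            if reject_disrupting and _disrupts_selected(pos, alt, g, motifs,
                                                        cfg.threshold):
                continue
            return pos, ref, alt
        raise SimulationError("no legal mutation site found after "
                              f"{cfg.max_redraws} redraws")

    clade_positions: dict[str, set[int]] = {c: set() for c in clade_members}
    for clade in clade_members:
        for _ in range(rng.poisson(cfg.mu_internal)):
            pos, ref, alt = draw_mutation(clade_positions[clade],
                                          reject_disrupting=True)
            clade_positions[clade].add(pos)
            events.append(MutationEvent(pos, ref, alt, "internal", clade, "nodal"))

    for clade, members in clade_members.items():
        for ind in members:
            used = set(clade_positions[clade])
            for _ in range(rng.poisson(cfg.mu_leaf)):
                pos, ref, alt = draw_mutation(used, reject_disrupting=False)
                used.add(pos)
                events.append(MutationEvent(pos, ref, alt, "leaf", ind, "tip"))

    sequences = build_sequences(g, events, clade_members)
    truth = PopulationTruth(events, clade_members,
                            [m.motif_id for m in motifs if m.selected])
    return sequences, lineages, truth


def build_sequences(g: CircularGenome, events: Sequence[MutationEvent],
                    clade_members: dict[str, list[str]]) -> dict[str, str]:
    """Apply recorded mutation events to the reference, per individual."""
    per_individual: dict[str, list[MutationEvent]] = {
        ind: [] for members in clade_members.values() for ind in members}
    for ev in events:
        if ev.branch == "internal":
            for ind in clade_members[ev.carrier_group]:
                per_individual[ind].append(ev)
        else:
            per_individual[ev.carrier_group].append(ev)
    sequences = {}
    for ind, evs in per_individual.items():
        seq = list(g.sequence)
        for ev in evs:
            seq[ev.pos - 1] = ev.alt
        sequences[ind] = "".join(seq)
    return sequences


def variants_from_alignment(reference: CircularGenome,
                            sequences: dict[str, str]) -> list[VariantObservation]:
    """Call substitution variants from a gapless population alignment."""
    ref = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
    carriers: dict[tuple[int, str, str], set[str]] = {}
    for ind, seq in sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if arr.size != ref.size:
            raise SimulationError(f"{ind}: sequence length differs from reference")
        for i in np.nonzero(arr != ref)[0]:
            key = (int(i) + 1, chr(ref[i]), chr(arr[i]))
            carriers.setdefault(key, set()).add(ind)
    return [VariantObservation(pos, ref_b, alt_b, frozenset(inds))
            for (pos, ref_b, alt_b), inds in sorted(carriers.items())]


# ---------------------------------------------------------------------------
# ChIP-seq read-start simulation


@dataclass(frozen=True)
class ChipSimConfig:
    fragment_size: int = 120
    bandwidth: float = 40.0          # positional jitter sd = bandwidth / 2
    background_rate: float = 0.02    # read starts per bp per strand
    read_length: int = 36
    contamination: float = 0.0       # fraction of site reads rebased onto a NUMT

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination <= 1.0:
            raise SimulationError("contamination must lie in [0, 1]")
        if self.background_rate < 0:
            raise SimulationError("background_rate must be >= 0")


@dataclass
class ChipSimResult:
    starts: StrandedStarts
    site_centers: list[int]
    reads: list[AlignedRead] | None = None
    read_origins: list[str] | None = None  # 'mt' or 'numt', parallel to reads


def simulate_chip_reads(g: CircularGenome, sites: Sequence[tuple[int, int]],
                        cfg: ChipSimConfig, rng: np.random.Generator,
                        diagnostics: DiagnosticSet | None = None,
                        emit_reads: bool = False) -> ChipSimResult:
    """Stranded start counts for planted sites over a uniform background.

    ``sites`` is a list of (center, n_fragment_pairs).  Each pair yields a
    plus-strand start near ``center - fragment_size/2`` and a minus-strand
    start near ``center + fragment_size/2``, each with Gaussian jitter of
    sd ``bandwidth/2`` — the bimodal strand pattern of true binding.  When
    ``emit_reads`` is set, site reads are materialized as gapless aligned
    reads; a ``contamination`` fraction is rebased onto the NUMT haplotype
    (allele swap at the covered diagnostic positions).
    """
    L = g.length
    plus = rng.poisson(cfg.background_rate, size=L).astype(float)
    minus = rng.poisson(cfg.background_rate, size=L).astype(float)
    reads: list[AlignedRead] = []
    origins: list[str] = []
    sd = cfg.bandwidth / 2.0
    for center, n_pairs in sites:
        for _ in range(int(n_pairs)):
            p_start = int(round(center - cfg.fragment_size / 2
                                + rng.normal(0.0, sd))) % L or L
            m_start = int(round(center + cfg.fragment_size / 2
                                + rng.normal(0.0, sd))) % L or L
            plus[p_start - 1] += 1
            minus[m_start - 1] += 1
            if emit_reads:
                for start in (p_start, (m_start - cfg.read_length) % L + 1):
                    seq = g.fetch(start, cfg.read_length)
                    origin = "mt"
                    if diagnostics is not None and rng.random() < cfg.contamination:
                        origin = "numt"
                        seq = _rebase_on_numt(seq, start, diagnostics, L)
                    reads.append(AlignedRead(start, seq))
                    origins.append(origin)
    result = ChipSimResult(StrandedStarts(plus, minus),
                           [c for c, _ in sites])
    if emit_reads:
        result.reads, result.read_origins = reads, origins
    return result


def _rebase_on_numt(seq: str, start: int, diag: DiagnosticSet, L: int) -> str:
    out = list(seq)
    for pos, _mt, numt_allele in diag.positions:
        offset = (pos - start) % L
        if offset < len(out):
            out[offset] = numt_allele
    return "".join(out)


def simulate_region_reads(g: CircularGenome, region: GenomicInterval,
                          n_reads: int, read_length: int, contamination: float,
                          diagnostics: DiagnosticSet,
                          rng: np.random.Generator
                          ) -> tuple[list[AlignedRead], list[str]]:
    """Uniform-coverage reads fully inside ``region``, a fraction NUMT-derived."""
    L = g.length
    span = region.length(L)
    if read_length > span:
        raise SimulationError("read_length exceeds region span")
    reads, origins = [], []
    for _ in range(n_reads):
        offset = int(rng.integers(0, span - read_length + 1))
        start = (region.start - 1 + offset) % L + 1
        seq = g.fetch(start, read_length)
        origin = "numt" if rng.random() < contamination else "mt"
        if origin == "numt":
            seq = _rebase_on_numt(seq, start, diagnostics, L)
        reads.append(AlignedRead(start, seq))
        origins.append(origin)
    return reads, origins


# ---------------------------------------------------------------------------
# DNase cut-count simulation


@dataclass(frozen=True)
class DnaseSimConfig:
    depth: float = 100.0
    protected_factor: float = 0.1
    hypersensitive_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.protected_factor < 0 or self.hypersensitive_factor < 0:
            raise SimulationError("DNase factors must be >= 0")


def simulate_dnase(L: int, protected: Sequence[GenomicInterval],
                   hypersensitive: Sequence[GenomicInterval],
                   cfg: DnaseSimConfig, rng: np.random.Generator) -> CoverageTrack:
    """Poisson cut counts: baseline ``depth``, scaled inside planted intervals."""
    lam = np.full(L, cfg.depth)
    for iv in protected:
        for pos in iv.positions(L):
            lam[pos - 1] = cfg.depth * cfg.protected_factor
    for iv in hypersensitive:
        for pos in iv.positions(L):
            lam[pos - 1] = cfg.depth * cfg.hypersensitive_factor
    return CoverageTrack("synthetic_dnase", rng.poisson(lam).astype(float))


# ---------------------------------------------------------------------------
# Whole-scenario builder (drives the end-to-end selection screen)


@dataclass(frozen=True)
class ScenarioConfig:
    L: int = 16569
    n_genes: int = 2
    n_selected: int = 4
    n_neutral: int = 4
    motif_width: int = 9
    population: PopulationConfig = field(default_factory=PopulationConfig)

    def __post_init__(self) -> None:
        if self.L % 3:
            # keep the reading frame global; shave down to a codon boundary
            raise SimulationError(f"L = {self.L} must be divisible by 3")


@dataclass
class Scenario:
    genome: CircularGenome
    annotations: list[GeneAnnotation]
    pwm: PositionWeightMatrix
    motifs: list[PlantedMotif]
    sequences: dict[str, str]
    lineages: LineageTable
    truth: PopulationTruth


def build_scenario(cfg: ScenarioConfig, rng: np.random.Generator) -> Scenario:
    """Reference with planted motifs + simulated population, ready to screen.

    Half of the planted motifs evolve under purifying selection (the
    CPR-like test set) and half neutrally (the CNR-like null set); motif
    starts are congruent to 1 mod 3 so that the PWM's critical columns sit
    on third codon positions.
    """
    pfm = selection_test_pfm(width=cfg.motif_width)
    pwm = pfm.to_pwm()
    g = random_genome(cfg.L, rng)
    annotations = tile_genes(cfg.L, cfg.n_genes)

    n_motifs = cfg.n_selected + cfg.n_neutral
    motifs = []
    for i in range(n_motifs):
        start = int(round(cfg.L * (i + 0.5) / n_motifs))
        start -= (start - 1) % 3  # align columns 3,6,9 with codon position 3
        selected = i < cfg.n_selected
        motifs.append(PlantedMotif(
            f"{'sel' if selected else 'neu'}{i:02d}", pwm, start, "+", selected))
    g = plant_motifs(g, motifs)
    sequences, lineages, truth = simulate_population(
        g, annotations, motifs, cfg.population, rng)
    return Scenario(g, annotations, pwm, list(motifs), sequences, lineages, truth)
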