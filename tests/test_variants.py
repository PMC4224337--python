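"""Tip/nodal classification, third-codon filtering, per-site tallies."""

import itertools

import numpy as np
import pytest

from mitotfbs.genome import CircularGenome, GeneAnnotation, GenomicInterval, codon_position
from mitotfbs.motif import MotifHit
from mitotfbs.variants import (LineageTable, VariantError, VariantObservation,
                               classify_variant, classify_variants,
                               filter_third_codon, read_variants_tsv,
                               read_variants_vcf, tabulate_tip_nodal,
                               write_variants_tsv)


@pytest.fixture
def three_clades():
    """12 individuals: clades of 5, 4 and 3 under two coarse groups."""
    paths = {}
    for i in range(5):
        paths[f"a{i}"] = ("G1", "A")
    for i in range(4):
        paths[f"b{i}"] = ("G1", "B")
    for i in range(3):
        paths[f"c{i}"] = ("G2", "C")
    return LineageTable(paths)


def oracle_classify(carriers, lt, min_carriers=5, min_fraction=0.85):
    """Direct implementation of the printed definition, for cross-checking."""
    if len(carriers) == 1:
        return "tip"
    qualifying = []
    for prefix, members in lt.sublineages().items():
        inside = carriers & members
        if len(inside) >= min_carriers and len(inside) / len(members) >= min_fraction:
            qualifying.append(members)
    return "nodal" if qualifying else "unclassified"


class TestClassifyVariant:
    def _v(self, carriers):
        return VariantObservation(100, "A", "G", frozenset(carriers))

    def test_singleton_is_tip(self, three_clades):
        assert classify_variant(self._v({"a0"}), three_clades).label == "tip"

    def test_full_five_member_clade_is_nodal(self, three_clades):
        vc = classify_variant(self._v({f"a{i}" for i in range(5)}), three_clades)
        assert vc.label == "nodal"
        assert vc.sublineage == ("G1", "A")
        assert vc.carrier_fraction == pytest.approx(1.0)

    def test_five_of_ten_member_group_unclassified(self):
        # 5 carriers spread over a 10-member sublineage: 0.5 < 0.85
        lt = LineageTable({f"x{i}": ("G", "X") for i in range(10)})
        vc = classify_variant(self._v({f"x{i}" for i in range(5)}), lt)
        assert vc.label == "unclassified"

    def test_four_of_four_below_min_carriers(self, three_clades):
        vc = classify_variant(self._v({f"b{i}" for i in range(4)}), three_clades)
        assert vc.label == "unclassified"

    def test_smallest_qualifying_sublineage_reported(self):
        lt = LineageTable({f"y{i}": ("Top", "Mid", "Leafy") for i in range(5)}
                          | {f"z{i}": ("Top", "Mid") for i in range(1)})
        vc = classify_variant(self._v({f"y{i}" for i in range(5)}), lt)
        assert vc.label == "nodal"
        assert vc.sublineage == ("Top", "Mid", "Leafy")  # 5/5, not 5/6

    def test_unknown_carrier_rejected(self, three_clades):
        with pytest.raises(VariantError):
            classify_variant(self._v({"ghost"}), three_clades)

    def test_exhaustive_enumeration_matches_definition(self, three_clades):
        individuals = sorted(three_clades.individuals)
        for r in range(1, len(individuals) + 1):
            for combo in itertools.combinations(individuals, r):
                carriers = frozenset(combo)
                got = classify_variant(self._v(carriers), three_clades).label
                assert got == oracle_classify(set(carriers), three_clades), carriers

    def test_order_independence(self, three_clades, rng):
        carriers = {"a0", "a1", "a2", "a3", "a4", "b0"}
        labels = set()
        for _ in range(5):
            shuffled = list(carriers)
            rng.shuffle(shuffled)
            labels.add(classify_variant(self._v(set(shuffled)), three_clades).label)
        assert labels == {"nodal"}

    def test_partition_property(self, three_clades, rng):
        individuals = sorted(three_clades.individuals)
        variants = []
        for pos in range(1, 40):
            n = int(rng.integers(1, 12))
            carriers = frozenset(rng.choice(individuals, size=n, replace=False))
            variants.append(VariantObservation(pos, "A", "G", carriers))
        classified = classify_variants(variants, three_clades)
        n_by_label = {"tip": 0, "nodal": 0, "unclassified": 0}
        for _, vc in classified:
            n_by_label[vc.label] += 1
        assert sum(n_by_label.values()) == len(variants)


class TestThirdCodonFilter:
    def test_only_third_positions_kept(self):
        anns = [GeneAnnotation("g1", 10, 39, "+", 0)]
        variants = [VariantObservation(p, "A", "G", frozenset({"i"}))
                    for p in (10, 11, 12, 25, 50)]
        kept = filter_third_codon(variants, anns, 100)
        assert [v.pos for v in kept] == [12]  # 12 is codon pos 3; 25 is pos 1

    def test_noncoding_positions_dropped(self):
        anns = [GeneAnnotation("g1", 10, 39, "+", 0)]
        v = VariantObservation(80, "A", "G", frozenset({"i"}))
        assert filter_third_codon([v], anns, 100) == []

    def test_matches_enumeration_oracle(self, rng):
        L = 300
        anns = [GeneAnnotation("f", 10, 99, "+", 0),
                GeneAnnotation("r", 120, 239, "-", 1),
                GeneAnnotation("w", 290, 19, "+", 0)]
        variants = [VariantObservation(int(p), "A", "G", frozenset({"i"}))
                    for p in rng.choice(np.arange(1, L + 1), 120, replace=False)]
        kept = {v.pos for v in filter_third_codon(variants, anns, L)}
        oracle = set()
        for v in variants:
            for a in anns:
                if a.interval().contains(v.pos, L):
                    if codon_position(v.pos, a, L) == 3:
                        oracle.add(v.pos)
                    break
        assert kept == oracle


class TestTabulate:
    def _hit(self, motif_id, start, end, wraps=False):
        return MotifHit(motif_id, GenomicInterval(start, end, wraps), "+",
                        1.0, 0.95, "ACGT")

    def test_counts_per_site(self, three_clades):
        sites = {"CPR": [self._hit("m1", 100, 110)],
                 "CNR": [self._hit("m2", 200, 210), self._hit("m3", 390, 5, True)]}
        variants = [
            VariantObservation(100, "A", "G", frozenset({"a0"})),          # tip, on edge
            VariantObservation(105, "A", "G", frozenset(f"a{i}" for i in range(5))),
            VariantObservation(205, "A", "G", frozenset({"b0", "b1"})),    # unclassified
            VariantObservation(2, "A", "G", frozenset({"c0"})),            # tip, wraps
            VariantObservation(300, "A", "G", frozenset({"c1"})),          # no site
        ]
        classified = classify_variants(variants, three_clades)
        table = tabulate_tip_nodal(classified, sites, 400)
        m1 = table[table.motif_id == "m1"].iloc[0]
        assert (m1.n_tip, m1.n_nodal, m1.n_unclassified) == (1, 1, 0)
        m2 = table[table.motif_id == "m2"].iloc[0]
        assert (m2.n_tip, m2.n_nodal, m2.n_unclassified) == (0, 0, 1)
        m3 = table[table.motif_id == "m3"].iloc[0]
        assert (m3.n_tip, m3.n_nodal, m3.n_unclassified) == (1, 0, 0)

    def test_empty_site(self, three_clades):
        table = tabulate_tip_nodal([], {"CNR": [self._hit("m", 50, 60)]}, 400)
        row = table.iloc[0]
        assert (row.n_tip, row.n_nodal, row.n_unclassified) == (0, 0, 0)


class TestLineageIO:
    def test_tsv_round_trip(self, tmp_path, three_clades):
        path = tmp_path / "lin.tsv"
        three_clades.to_tsv(path)
        back = LineageTable.from_tsv(path)
        assert back.paths == three_clades.paths

    def test_newick_adapter_builds_prefix_groups(self):
        nwk = "((a0,a1,a2,a3,a4)A,((b0,b1)B1,(b2,b3)B2)B)root;"
        lt = LineageTable.from_newick(nwk)
        assert lt.paths["a0"][-1] == "A"
        assert lt.paths["b2"][-1] == "B2"
        groups = lt.sublineages()
        b_prefix = next(p for p in groups if p[-1] == "B")
        assert groups[b_prefix] == {"b0", "b1", "b2", "b3"}


class TestVariantIO:
    def test_tsv_round_trip(self, tmp_path):
        variants = [VariantObservation(10, "A", "G", frozenset({"x", "y"})),
                    VariantObservation(42, "C", "T", frozenset({"z"}))]
        path = tmp_path / "v.tsv"
        write_variants_tsv(variants, path)
        assert read_variants_tsv(path) == variants

    def test_minimal_vcf(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "chrM\t73\t.\tA\tG\t.\t.\t.\tGT\t1\t0\t1\n"
            "chrM\t150\t.\tC\tT,A\t.\t.\t.\tGT\t0\t2\t1\n")
        out = read_variants_vcf(path)
        assert out[0] == VariantObservation(73, "A", "G", frozenset({"s1", "s3"}))
        assert VariantObservation(150, "C", "T", frozenset({"s3"})) in out
        assert VariantObservation(150, "C", "A", frozenset({"s2"})) in out
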