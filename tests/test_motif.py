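"""PWM construction, window scoring, circular scanning and variant rescoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitotfbs.genome import CircularGenome, GenomicInterval, reverse_complement
from mitotfbs.motif import (BASES, MotifError, PositionFrequencyMatrix,
                            apply_variant_and_rescore, encode, pfm_to_pwm,
                            read_jaspar, scan_circular, score_window,
                            write_jaspar)


def brute_force_hits(g: CircularGenome, pwm, threshold):
    """Independent oracle: score every window of the doubled sequence."""
    L, W = g.length, pwm.width
    doubled = g.sequence + g.sequence
    span = pwm.smax - pwm.smin
    hits = set()
    for start0 in range(L):
        window = doubled[start0:start0 + W]
        if "N" in window:
            continue
        for strand, site in (("+", window), ("-", reverse_complement(window))):
            score = sum(pwm.weights["ACGT".index(b), i] for i, b in enumerate(site))
            rel = (score - pwm.smin) / span
            if rel >= threshold:
                hits.add((start0 + 1, strand, round(rel, 9)))
    return hits


def hit_set(hits):
    return {(h.interval.start, h.strand, round(h.relative_score, 9)) for h in hits}


class TestPwmConstruction:
    def test_certainty_column_approaches_two_bits(self):
        pfm = PositionFrequencyMatrix("c", np.array([[100.0], [0], [0], [0]]))
        pwm = pfm.to_pwm(pseudocount=1e-9)
        assert pwm.weights[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_uniform_column_scores_zero(self):
        pfm = PositionFrequencyMatrix("u", np.array([[25.0], [25], [25], [25]]))
        pwm = pfm.to_pwm()
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_computed_two_column_matrix(self):
        # counts col1 (A=8,C=2), col2 (G=5,T=5), pseudocount 1, uniform background
        pfm = PositionFrequencyMatrix("h", np.array(
            [[8.0, 0], [2, 0], [0, 5], [0, 5]]))
        pwm = pfm.to_pwm(pseudocount=1.0)
        expect = lambda n, N: math.log2(((n + 0.25) / (N + 1)) / 0.25)
        assert pwm.weights[0, 0] == pytest.approx(expect(8, 10))
        assert pwm.weights[1, 0] == pytest.approx(expect(2, 10))
        assert pwm.weights[2, 0] == pytest.approx(expect(0, 10))
        assert pwm.weights[2, 1] == pytest.approx(expect(5, 10))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(MotifError):
            PositionFrequencyMatrix("z", np.array([[0.0], [0], [0], [0]]))
        pfm = PositionFrequencyMatrix("p", np.ones((4, 2)))
        with pytest.raises(MotifError):
            pfm_to_pwm(pfm, pseudocount=0.0)
        with pytest.raises(MotifError):
            pfm_to_pwm(pfm, background=(0.5, 0.5, 0.0, 0.0))


class TestScoreWindow:
    def test_consensus_and_anticonsensus_bounds(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        anti = "".join(BASES[i] for i in pwm.weights.argmin(axis=0))
        assert score_window(pwm, pwm.consensus)[1] == pytest.approx(1.0)
        assert score_window(pwm, anti)[1] == pytest.approx(0.0)

    def test_exhaustive_enumeration_attains_smax(self, rng):
        counts = rng.integers(0, 50, size=(4, 5)).astype(float) + 1
        pwm = PositionFrequencyMatrix("e", counts).to_pwm()
        best = max(score_window(pwm, "".join(w))[0]
                   for w in itertools.product(BASES, repeat=5))
        assert best == pytest.approx(pwm.smax)

    def test_n_in_window_rejected(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        with pytest.raises(MotifError):
            score_window(pwm, "TGACTCN")


class TestScanCircular:
    def test_planted_consensus_at_origin_junction_wraps(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        cons = pwm.consensus  # 7-mer; plant last 4 bases at end + first 3 at start
        seq = cons[4:] + "C" * 93 + cons[:4]
        g = CircularGenome("j", seq)
        hits = [h for h in scan_circular(g, pwm, 0.99) if h.strand == "+"]
        assert any(h.interval.start == 97 and h.interval.wraps for h in hits)

    def test_equals_doubled_sequence_oracle(self, rng):
        for _ in range(5):
            L = int(rng.integers(50, 300))
            g = CircularGenome("r", "".join(
                np.array(list(BASES))[rng.integers(0, 4, size=L)]))
            counts = rng.integers(0, 30, size=(4, 8)).astype(float) + 0.5
            pwm = PositionFrequencyMatrix("o", counts).to_pwm()
            assert hit_set(scan_circular(g, pwm, 0.75)) == \
                brute_force_hits(g, pwm, 0.75)

    def test_rotation_invariance(self, small_genome, sharp_pfm):
        from mitotfbs.genome import rotated_to_original
        pwm = sharp_pfm.to_pwm()
        L = small_genome.length
        base = hit_set(scan_circular(small_genome, pwm, 0.7))
        for k in (1, 50, 137):
            rotated = scan_circular(small_genome.rotate(k), pwm, 0.7)
            mapped = {(rotated_to_original(s, k, L), st_, sc)
                      for s, st_, sc in hit_set(rotated)}
            assert mapped == base

    def test_strand_symmetry(self, small_genome, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        fwd = scan_circular(small_genome, pwm, 0.7)
        rc_genome = CircularGenome("rc", reverse_complement(small_genome.sequence))
        rc = scan_circular(rc_genome, pwm, 0.7)
        L, W = small_genome.length, pwm.width
        # a + hit at start s on g mirrors a - hit at L - (s + W - 1) + 1 on rc(g)
        mirrored = {((L - (s + W - 2) - 1) % L + 1, "+" if st_ == "-" else "-", sc)
                    for s, st_, sc in hit_set(rc)}
        assert mirrored == hit_set(fwd)

    def test_scores_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            g = CircularGenome("b", "".join(
                np.array(list(BASES))[rng.integers(0, 4, size=120)]))
            counts = rng.integers(0, 40, size=(4, 6)).astype(float) + 0.5
            pwm = PositionFrequencyMatrix("b", counts).to_pwm()
            for h in scan_circular(g, pwm, 0.0):
                assert 0.0 <= h.relative_score <= 1.0 + 1e-12

    def test_windows_with_n_are_skipped(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        g = CircularGenome("n", pwm.consensus + "N" + pwm.consensus + "A" * 20)
        hits = scan_circular(g, pwm, 0.99)
        assert all("N" not in h.site_sequence for h in hits)
        assert any(h.interval.start == 1 for h in hits)
        assert any(h.interval.start == 9 for h in hits)

    def test_width_exceeding_genome_rejected(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        with pytest.raises(MotifError):
            scan_circular(CircularGenome("s", "ACGT"), pwm, 0.8)


class TestVariantRescoring:
    def test_identity_variant_keeps_score(self, small_genome, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        hits = scan_circular(small_genome, pwm, 0.0)
        h = hits[0]
        pos = h.interval.start
        ref = small_genome.base(pos)
        with pytest.raises(MotifError):
            # alt == ref is a degenerate "variant": exercised via ref mismatch guard
            apply_variant_and_rescore(h, pwm, (pos, "A" if ref != "A" else "C", ref),
                                      small_genome)

    def test_consensus_restoring_variant_raises_score(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        g = CircularGenome("c", "A" + pwm.consensus[1:] + "ACGTACGTAC")
        h = scan_circular(g, pwm, 0.0)[0]
        assert h.interval.start == 1
        old = h.relative_score
        new, retained = apply_variant_and_rescore(
            h, pwm, (1, "A", pwm.consensus[0]), g)
        assert new >= old
        assert retained

    def test_rescore_matches_independent_window_score(self, rng, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        g = CircularGenome("r", pwm.consensus + "".join(
            np.array(list(BASES))[rng.integers(0, 4, size=50)]))
        for h in scan_circular(g, pwm, 0.9):
            pos = h.interval.start + 3
            ref = g.base(pos)
            alt = "A" if ref != "A" else "G"
            new, _ = apply_variant_and_rescore(h, pwm, (pos, ref, alt), g)
            mutated = list(g.fetch(h.interval.start, pwm.width))
            mutated[3] = alt
            site = "".join(mutated)
            if h.strand == "-":
                site = reverse_complement(site)
            assert new == pytest.approx(score_window(pwm, site)[1])

    def test_minus_strand_variant_is_complemented(self, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        g = CircularGenome("m", reverse_complement(pwm.consensus) + "A" * 30)
        h = [x for x in scan_circular(g, pwm, 0.99) if x.strand == "-"][0]
        pos = h.interval.start
        ref = g.base(pos)
        alt = "C" if ref != "C" else "G"
        new, _ = apply_variant_and_rescore(h, pwm, (pos, ref, alt), g)
        mutated = list(g.fetch(h.interval.start, pwm.width))
        mutated[0] = alt
        assert new == pytest.approx(
            score_window(pwm, reverse_complement("".join(mutated)))[1])

    def test_position_outside_hit_rejected(self, small_genome, sharp_pfm):
        pwm = sharp_pfm.to_pwm()
        h = scan_circular(small_genome, pwm, 0.0)[0]
        outside = (h.interval.end % small_genome.length) + 25
        with pytest.raises(MotifError):
            apply_variant_and_rescore(h, pwm, (outside, "A", "C"), small_genome)


class TestJasparIO:
    def test_round_trip_bracketed(self, tmp_path, sharp_pfm):
        path = tmp_path / "m.jaspar"
        write_jaspar([sharp_pfm], path)
        back = read_jaspar(path)
        assert len(back) == 1
        assert back[0].motif_id == sharp_pfm.motif_id
        assert np.allclose(back[0].counts, sharp_pfm.counts)

    def test_plain_dialect(self, tmp_path):
        path = tmp_path / "p.jaspar"
        path.write_text(">M1 TEST\n1 2\n3 4\n5 6\n7 8\n")
        pfm = read_jaspar(path)[0]
        assert pfm.motif_id == "M1"
        assert np.allclose(pfm.counts, [[1, 2], [3, 4], [5, 6], [7, 8]])
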