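"""MISA-style SSR detection, compound merging and primer feasibility."""

import numpy as np
import pytest

from foxcomp.seqcore import NucSequence
from foxcomp.simulate import plant_ssr
from foxcomp.ssr import (
    SSRLocus,
    SSRThresholds,
    canonical_motif,
    detect_ssrs,
    merge_compound,
    primer_feasible,
)

THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def oracle_scan(seq):
    """Independent brute-force maximal-tandem-repeat scan (unit 1-6)."""
    s = seq if isinstance(seq, str) else seq.seq
    n = len(s)
    found = []
    for u in range(1, 7):
        x = 0
        while x < n - u:
            if s[x] == s[x + u]:
                q = x
                while q < n - u and s[q] == s[q + u]:
                    q += 1
                span = q - x + u
                reps = span // u
                motif = s[x : x + u]
                primitive = all(
                    not (u % d == 0 and motif == motif[:d] * (u // d))
                    for d in range(1, u)
                )
                if reps >= THRESHOLDS[u] and primitive and "N" not in motif:
                    found.append((motif, reps, x + 1, x + u * reps))
                x = q + 1
            else:
                x += 1
    return sorted(found, key=lambda t: (t[2], len(t[0])))


def _clean_background(length, seed):
    """Random background verified repeat-free by the oracle."""
    rng = np.random.default_rng(seed)
    while True:
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        if not oracle_scan(s):
            return s


def _plant_guarded(seq, motif, reps, pos):
    """Plant a tract and pin the flanking bases so it cannot extend."""
    tract_len = len(motif) * reps
    s = seq.seq
    left = next(b for b in "ACGT" if b != motif[-1])
    right = next(b for b in "ACGT" if b != motif[0])
    s = s[: pos - 2] + left + s[pos - 1 :]
    s = s[: pos - 1 + tract_len] + right + s[pos + tract_len :]
    return plant_ssr(NucSequence(seq.id, s), motif, reps, pos)


class TestDetectSsrs:
    def test_planted_dinucleotide_exact_coordinates(self):
        seq = plant_ssr(NucSequence("s", _clean_background(400, 1)), "AC", 7, 101)
        loci = detect_ssrs(seq)
        expected = oracle_scan(seq)
        assert [(l.motif, l.repeats, l.start, l.end) for l in loci] == expected
        assert ("AC", 7, 101, 114) in expected

    def test_mononucleotide_run(self):
        seq = _plant_guarded(NucSequence("s", _clean_background(200, 2)), "A", 12, 50)
        loci = [l for l in detect_ssrs(seq) if l.unit_size == 1]
        assert [(l.motif, l.repeats, l.start, l.end) for l in loci] == [("A", 12, 50, 61)]

    def test_below_threshold_not_reported(self):
        seq = plant_ssr(NucSequence("s", _clean_background(200, 3)), "AC", 5, 50)
        assert all(l.motif != "AC" or l.repeats >= 6 for l in detect_ssrs(seq))
        assert detect_ssrs(seq) == []

    def test_periodic_unit_reported_at_smallest_period(self):
        seq = plant_ssr(NucSequence("s", _clean_background(200, 4)), "AG", 8, 60)
        loci = detect_ssrs(seq)
        assert len(loci) == 1 and loci[0].unit_size == 2

    def test_repeat_free_background_yields_nothing(self):
        for seed in range(5):
            seq = NucSequence("s", _clean_background(400, 100 + seed))
            assert detect_ssrs(seq) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        # biased alphabet raises accidental repeat frequency
        s = "".join(rng.choice(list("AACGT"), size=500))
        loci = detect_ssrs(NucSequence("s", s))
        assert [(l.motif, l.repeats, l.start, l.end) for l in loci] == oracle_scan(s)

    def test_maximality(self):
        seq = plant_ssr(NucSequence("s", _clean_background(300, 7)), "AAG", 6, 100)
        (locus,) = detect_ssrs(seq)
        s = seq.seq
        left = s[locus.start - 1 - 3 : locus.start - 1]
        right = s[locus.end : locus.end + 3]
        assert left != locus.motif and right != locus.motif

    def test_reverse_complement_involution(self):
        seq = _plant_guarded(NucSequence("s", _clean_background(300, 8)), "AC", 7, 120)
        fwd = detect_ssrs(seq)
        rev = detect_ssrs(seq.reverse_complement())
        n = len(seq)
        mapped = sorted((n - l.end + 1, n - l.start + 1) for l in rev)
        assert mapped == sorted((l.start, l.end) for l in fwd)

    def test_detection_idempotent(self):
        seq = plant_ssr(NucSequence("s", _clean_background(300, 9)), "ATCG", 6, 90)
        assert detect_ssrs(seq) == detect_ssrs(seq)


class TestCanonicalMotif:
    def test_rotation_minimum(self):
        assert canonical_motif("GA") == "AG"
        assert canonical_motif("CAG") == "AGC"

    def test_strand_joint(self):
        assert canonical_motif("GT", strand_joint=True) == "AC"


class TestMergeCompound:
    def _loci(self, spacer):
        start2 = 101 + 14 + spacer
        return [
            SSRLocus("s", "AC", 2, 7, 101, 114),
            SSRLocus("s", "AG", 2, 6, start2, start2 + 11),
        ]

    def test_nearby_loci_share_compound_id(self):
        merged = merge_compound(self._loci(10), 100)
        assert merged[0].compound_id == merged[1].compound_id is not None

    def test_distant_loci_not_merged(self):
        merged = merge_compound(self._loci(150), 100)
        assert all(l.compound_id is None for l in merged)

    def test_single_locus_no_compound(self):
        (out,) = merge_compound([SSRLocus("s", "AC", 2, 7, 101, 114)], 100)
        assert out.compound_id is None

    def test_unsorted_input_rejected(self):
        loci = list(reversed(self._loci(10)))
        with pytest.raises(ValueError, match="sorted"):
            merge_compound(loci, 100)

    def test_boundary_interruption_inclusive(self):
        merged = merge_compound(self._loci(100), 100)
        assert merged[0].compound_id is not None
        merged = merge_compound(self._loci(101), 100)
        assert merged[0].compound_id is None


class TestPrimerFeasible:
    def test_centered_locus_feasible_and_matches_enumeration(self):
        seq = plant_ssr(NucSequence("s", _clean_background(500, 20)), "AC", 7, 240)
        (locus,) = detect_ssrs(seq)
        windows = primer_feasible(seq, locus)
        assert 1 <= len(windows) <= 3
        for w in windows:
            assert w.left_end < locus.start and w.right_start > locus.end
            assert 100 <= w.product_len <= 400
            assert 18 <= w.left_end - w.left_start + 1 <= 22
            assert 18 <= w.right_end - w.right_start + 1 <= 22
        # oracle: best GC penalty over exhaustive enumeration
        best = min(
            abs(100 * sum(c in "GC" for c in seq.seq[ls - 1 : ls + ll - 1]) / ll - 50)
            + abs(100 * sum(c in "GC" for c in seq.seq[rs - 1 : rs + rl - 1]) / rl - 50)
            for ll in range(18, 23)
            for rl in range(18, 23)
            for ls in range(1, locus.start - ll + 1)
            for rs in range(locus.end + 1, len(seq) - rl + 2)
            if 100 <= (rs + rl - 1) - ls + 1 <= 400
        )
        assert windows[0].gc_penalty == pytest.approx(best)

    def test_locus_near_end_infeasible(self):
        bg = _clean_background(300, 21)
        seq = plant_ssr(NucSequence("s", bg), "AC", 7, 300 - 14 - 4)
        (locus,) = detect_ssrs(seq)
        assert primer_feasible(seq, locus) == []

    def test_sequence_shorter_than_min_product_infeasible(self):
        seq = plant_ssr(NucSequence("s", _clean_background(90, 22)), "AC", 7, 40)
        (locus,) = detect_ssrs(seq)
        assert primer_feasible(seq, locus) == []
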