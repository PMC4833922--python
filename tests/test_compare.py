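"""Linear comparison, gapped fallback, variant extraction, left-alignment."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampcall import (
    CompareMode,
    Variant,
    compare_insert,
    gapped_align,
    left_normalize,
    linear_compare,
    variants_from_alignment,
)
from ampcall.compare import FALLBACK, RESOLVED
from ampcall.panel import PrimerSeq, Tile, TileSpec

from conftest import make_insert
from oracle import (
    best_alignments_bruteforce,
    dp_align,
    leftmost_equivalent_indel,
)

THOROUGH = CompareMode("thorough")
FAST = CompareMode("fast", fast_gap=2)


def tile_for(ref_insert, start=101, chrom="chr1", fwd_tail="G"):
    return Tile(
        spec=TileSpec(chrom, start, start + len(ref_insert) - 1, "F", "R"),
        insert_ref=ref_insert,
        fwd_primer=PrimerSeq("F", "AAAA" + fwd_tail),
        rev_primer=PrimerSeq("R", "CCCCC"),
    )


class TestLinearCompare:
    def test_identity(self):
        tile = tile_for("ACGTACGT")
        res = linear_compare("ACGTACGT", tile.insert_ref, tile, THOROUGH)
        assert res.status == RESOLVED and res.variants == ()

    def test_single_substitution(self):
        tile = tile_for("ACGTACGT")
        res = linear_compare("ACGAACGT", tile.insert_ref, tile, THOROUGH)
        assert res.status == RESOLVED
        assert res.variants == (Variant("chr1", 104, "T", "A"),)

    def test_two_mismatches_fall_back(self):
        tile = tile_for("ACGTACGT")
        res = linear_compare("ACTTACTT", tile.insert_ref, tile, THOROUGH)
        assert res.status == FALLBACK

    def test_masked_base_never_mismatches(self):
        tile = tile_for("ACGTACGT")
        res = linear_compare("ACNTACNT", tile.insert_ref, tile, THOROUGH)
        assert res.status == RESOLVED and res.variants == ()

    def test_offset_read_positions_shifted(self):
        tile = tile_for("ACGTACGT")
        res = linear_compare("AGGT", tile.insert_ref, tile, THOROUGH, ref_offset=4)
        assert res.variants == (Variant("chr1", 106, "C", "G"),)

    def test_fast_accepts_separated_mismatches(self):
        tile = tile_for("ACGTACGTACGT")
        read = "TCGTACGTACGA"  # offsets 0 and 11: separation 10 > 2
        res = linear_compare(read, tile.insert_ref, tile, FAST)
        assert res.status == RESOLVED and len(res.variants) == 2

    def test_fast_rejects_clustered_mismatches(self):
        tile = tile_for("ACGTACGTACGT")
        read = "ATTTACGTACGT"  # offsets 1,2,3 adjacent
        res = linear_compare(read, tile.insert_ref, tile, FAST)
        assert res.status == FALLBACK

    @settings(deadline=None, max_examples=150)
    @given(st.data())
    def test_fast_with_huge_gap_matches_thorough(self, data):
        ref = data.draw(st.text(alphabet="ACGT", min_size=8, max_size=40))
        read = list(ref)
        k = data.draw(st.integers(0, 3))
        for _ in range(k):
            i = data.draw(st.integers(0, len(read) - 1))
            read[i] = data.draw(st.sampled_from("ACGT"))
        read = "".join(read)
        tile = tile_for(ref)
        loose_fast = CompareMode("fast", fast_gap=10_000)
        thorough = linear_compare(read, ref, tile, THOROUGH)
        fast = linear_compare(read, ref, tile, loose_fast)
        # with an effectively infinite gap, clustered-mismatch fallback
        # coincides with the >=2-mismatch fallback of thorough mode
        assert thorough == fast


class TestGappedAlign:
    def test_identical_sequences_score(self):
        aln = gapped_align("ACGTACGT", "ACGTACGT")
        assert aln.score == pytest.approx(2.0 * 8)
        assert "-" not in str(aln[0]) and "-" not in str(aln[1])

    def test_one_base_deletion_is_optimal(self):
        """Exhaustive enumeration confirms the returned alignment's score."""
        best, winners = best_alignments_bruteforce("ACGTT", "ACTT")
        aln = gapped_align("ACTT", "ACGTT", side="global")
        assert aln.score == pytest.approx(best)
        assert sum(c == "-" for c in str(aln[1])) == 1

    def test_two_base_insertion_is_optimal(self):
        best, _ = best_alignments_bruteforce("ACTA", "ACGTTA")
        aln = gapped_align("ACGTTA", "ACTA", side="global")
        assert aln.score == pytest.approx(best)
        assert sum(c == "-" for c in str(aln[0])) == 2

    def test_alignment_is_deterministic(self):
        a1 = gapped_align("ACGTTACA", "ACGTACGTACA")
        a2 = gapped_align("ACGTTACA", "ACGTACGTACA")
        assert str(a1[0]) == str(a2[0]) and str(a1[1]) == str(a2[1])

    def test_score_matches_independent_dp_on_random_pairs(self):
        rnd = random.Random(42)
        for _ in range(60):
            m = rnd.randint(8, 40)
            ref = "".join(rnd.choice("ACGT") for _ in range(m))
            read = list(ref)
            for _ in range(rnd.randint(0, 3)):
                read[rnd.randrange(len(read))] = rnd.choice("ACGT")
            if rnd.random() < 0.5 and len(read) > 10:
                i = rnd.randint(2, len(read) - 5)
                del read[i : i + rnd.randint(1, 3)]
            read = "".join(read)
            side = rnd.choice(["left", "right"])
            aln = gapped_align(read, ref, side=side)
            dp_score, _, _ = dp_align(
                ref, read,
                free_left=(side == "right"), free_right=(side == "left"),
            )
            assert aln.score == pytest.approx(dp_score)


class TestVariantsFromAlignment:
    def test_substitution_column(self):
        tile = tile_for("ACGTACGT")
        aln = gapped_align("ACGAACGT", tile.insert_ref)
        assert variants_from_alignment(aln, tile) == [
            Variant("chr1", 104, "T", "A")
        ]

    def test_identity_alignment_no_variants(self):
        tile = tile_for("ACGTACGT")
        aln = gapped_align(tile.insert_ref, tile.insert_ref)
        assert variants_from_alignment(aln, tile) == []

    def test_homopolymer_deletion_left_aligned(self):
        """A 2-base deletion inside a homopolymer lands at the run's start,
        matching a brute-force left-shift of the raw event."""
        ref = "ACGTAAAACGTTGCAT"
        tile = tile_for(ref)
        read = "ACGTAACGTTGCAT"
        variants = compare_insert(make_insert(read), tile, THOROUGH)
        # independent oracle: shift a deletion of AA to its leftmost placement
        ext = tile.fwd_primer.sequence[-1] + ref
        pos, vref, valt = leftmost_equivalent_indel(ext, 7, "del", "AA",
                                                    ref_start=tile.spec.start - 1)
        assert variants == [Variant("chr1", pos, vref, valt)]
        assert variants[0].pos == 104  # T anchor before the AAAA run

    def test_truncated_read_tail_produces_no_variants(self):
        ref = "ACGTACGTACGTACGT"
        tile = tile_for(ref)
        read = ref[:10]  # honest truncation, resolves linearly
        assert compare_insert(make_insert(read), tile, THOROUGH) == []
        # force the gapped path with two clustered mismatches up front
        read2 = "TTGTACGTAC"
        variants = compare_insert(make_insert(read2), tile, THOROUGH)
        assert all(v.pos <= tile.spec.start + 9 for v in variants)

    def test_reference_side_consistency_checked(self):
        tile = tile_for("ACGTACGT")
        other = tile_for("TTTTTTTT")
        aln = gapped_align("ACGTACGT", other.insert_ref)
        with pytest.raises(Exception, match="does not match"):
            variants_from_alignment(aln, tile)


class TestLeftNormalize:
    GET = staticmethod(lambda p: "ACGTAAAACGTTGCAT"[p - 101] if p >= 101 else "G")

    def test_idempotent(self):
        pos, ref, alt = left_normalize(104, "TAA", "T", self.GET, 100)
        assert (pos, ref, alt) == (104, "TAA", "T")

    def test_shifts_through_homopolymer(self):
        # raw deletion of the last two A's of the AAAA run (positions 107-108)
        pos, ref, alt = left_normalize(106, "AAA", "A", self.GET, 100)
        assert (pos, ref, alt) == (104, "TAA", "T")

    def test_trims_shared_suffix(self):
        pos, ref, alt = left_normalize(104, "TAAT", "TT", self.GET, 100)
        assert (pos, ref, alt) == (104, "TAA", "T")

    @settings(deadline=None, max_examples=150)
    @given(st.data())
    def test_normalization_idempotence_random(self, data):
        ref_seq = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=30))
        i = data.draw(st.integers(1, len(ref_seq) - 5))
        length = data.draw(st.integers(1, 3))

        def get(p):
            return ref_seq[p - 1] if 1 <= p <= len(ref_seq) else None

        pos, ref, alt = left_normalize(
            i, ref_seq[i - 1 : i + length], ref_seq[i - 1], get, 1
        )
        again = left_normalize(pos, ref, alt, get, 1)
        assert again == (pos, ref, alt)


class TestOracleEquivalence:
    def test_linear_equals_alignment_route_for_single_substitutions(self):
        """For reads with <=1 substitution the linear scan and the full
        alignment route must produce the identical variant set."""
        rnd = random.Random(7)
        for _ in range(200):
            n = rnd.randint(10, 60)
            ref = "".join(rnd.choice("ACGT") for _ in range(n))
            read = list(ref)
            if rnd.random() < 0.8:
                i = rnd.randrange(n)
                read[i] = rnd.choice([b for b in "ACGT" if b != ref[i]])
            read = "".join(read)
            tile = tile_for(ref)
            lin = linear_compare(read, ref, tile, THOROUGH)
            assert lin.status == RESOLVED
            aln = gapped_align(read, ref, side="global")
            assert variants_from_alignment(aln, tile) == list(lin.variants)


def test_compare_pipeline_is_pure():
    ref = "ACGTACGTAAAACGTTGCATACGT"
    tile = tile_for(ref)
    read = "ACGTACGTAACGTTGCATACGT"
    runs = [compare_insert(make_insert(read), tile, THOROUGH) for _ in range(3)]
    assert runs[0] == runs[1] == runs[2]
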