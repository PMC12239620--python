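import numpy as np
import pytest

from tetrack.io import TECopy, VariantRecord, revcomp
from tetrack.matching import (
    MULTIPLE,
    NONE,
    UNIQUE,
    annotate_te_snps,
    apply_variants,
    canonical,
    cross_reference,
    indel_overlapped_te_ids,
    uniquely_identifiable,
)


def _te(te_id, chrom, start, end, seq, family="Zator"):
    return TECopy(te_id, chrom, start, end, "+", family, "II", seq)


def _snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, 50.0, 30, 40, "hom")


class TestAnnotateTeSnps:
    def test_no_variants_gives_empty_list(self):
        tes = [_te("a", "I", 100, 104, "ACGT")]
        assert annotate_te_snps(tes, []) == []

    def test_offset_arithmetic(self):
        seq = "A" * 100
        tes = [_te("a", "I", 100, 200, seq)]
        (poly,) = annotate_te_snps(tes, [_snp("I", 150, "A", "T")])
        assert poly.fingerprint_snps == ((49, "A", "T"),)
        assert poly.projected_sequence[49] == "T"

    def test_ref_allele_mismatch_is_hard_error(self):
        tes = [_te("a", "I", 100, 104, "ACGT")]
        with pytest.raises(ValueError, match="disagrees"):
            annotate_te_snps(tes, [_snp("I", 101, "G", "T")])

    def test_te_without_snp_omitted(self):
        tes = [_te("a", "I", 0, 4, "ACGT"), _te("b", "I", 100, 104, "ACGT")]
        polys = annotate_te_snps(tes, [_snp("I", 2, "C", "G")])
        assert [p.ref_te.te_id for p in polys] == ["a"]

    def test_overlap_set_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(41)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        tes = []
        for i in range(500):
            start = int(rng.integers(0, 99_000))
            end = start + int(rng.integers(50, 900))
            tes.append(_te(f"te{i}", "I", start, end, genome[start:end]))
        variants = []
        for pos in sorted(rng.choice(100_000, size=2_000, replace=False)):
            pos = int(pos)
            ref = genome[pos]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            variants.append(_snp("I", pos + 1, ref, alt))
        polys = annotate_te_snps(tes, variants)
        got = {p.ref_te.te_id: {o for o, _, _ in p.fingerprint_snps} for p in polys}
        want = {}
        for te in tes:  # O(n*m) oracle
            offsets = {
                v.pos - 1 - te.start
                for v in variants
                if te.start <= v.pos - 1 < te.end
            }
            if offsets:
                want[te.te_id] = offsets
        assert got == want


class TestApplyVariants:
    def test_forced_substitution(self):
        assert apply_variants("ACGTACGT", [(2, "G", "T")]) == "ACTTACGT"

    def test_empty_snp_list_is_identity(self):
        assert apply_variants("ACGT", []) == "ACGT"

    def test_random_edits_match_char_array_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        offsets = rng.choice(1000, size=30, replace=False)
        snps = []
        arr = np.array(list(seq))
        for off in offsets:
            off = int(off)
            alt = "ACGT"[("ACGT".index(seq[off]) + 2) % 4]
            snps.append((off, seq[off], alt))
            arr[off] = alt
        out = apply_variants(seq, snps)
        assert out == "".join(arr)
        assert len(out) == len(seq)
        assert sum(a != b for a, b in zip(out, seq)) == 30

    def test_out_of_range_offset_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            apply_variants("ACGT", [(9, "A", "C")])


class TestUniquelyIdentifiable:
    def _poly(self, te_id, seq, snp_off=0):
        from tetrack.matching import PolymorphicTE

        alt = "ACGT"[("ACGT".index(seq[snp_off]) + 1) % 4]
        return PolymorphicTE(
            _te(te_id, "I", 0, len(seq), seq),
            ((snp_off, seq[snp_off], alt),),
            apply_variants(seq, [(snp_off, seq[snp_off], alt)]),
        )

    def test_identical_projected_sequences_both_dropped(self):
        a = self._poly("a", "ACGTACGTACG")
        b = self._poly("b", "ACGTACGTACG")
        assert uniquely_identifiable([a, b]) == []

    def test_single_te_retained(self):
        a = self._poly("a", "ACGTACGTACG")
        assert uniquely_identifiable([a]) == [a]

    def test_reverse_complement_counts_as_duplicate(self):
        seq = "ACGTACGTACG"
        a = self._poly("a", seq)
        b = self._poly("b", revcomp(seq), snp_off=len(seq) - 1)
        assert uniquely_identifiable([a, b]) == []
        assert len(uniquely_identifiable([a, b], consider_rc=False)) == 2

    def test_raw_duplicate_in_full_reference_set_disqualifies(self):
        a = self._poly("a", "ACGTACGTACG")
        twin = _te("twin", "II", 0, 11, "ACGTACGTACG")
        assert uniquely_identifiable([a], all_ref_tes=[a.ref_te, twin]) == []

    def test_census_matches_bruteforce_on_synthetic_genome(self, small_sim, small_tracking):
        _, _, _, polys, unique = small_tracking
        proj = [canonical(p.projected_sequence) for p in polys]
        raws = [canonical(t.sequence) for t in small_sim.ref_tes]
        want = {
            p.ref_te.te_id
            for p in polys
            if proj.count(canonical(p.projected_sequence)) == 1
            and raws.count(canonical(p.ref_te.sequence)) == 1
        }
        assert {p.ref_te.te_id for p in unique} == want


class TestCrossReference:
    def test_unique_match_and_orientation_flip(self):
        seq = "ACGTACGTACGTAC"
        p = TestUniquelyIdentifiable()._poly("a", seq)
        qsame = _te("q1", "I", 0, len(seq), p.projected_sequence)
        qflip = _te("q2", "I", 0, len(seq), revcomp(p.projected_sequence))
        (m,) = cross_reference([p], [qsame])
        assert m.match_class == UNIQUE and m.orientation_flip == (False,)
        (m2,) = cross_reference([p], [qflip])
        assert m2.match_class == UNIQUE and m2.orientation_flip == (True,)
        (m3,) = cross_reference([p], [qflip], consider_rc=False)
        assert m3.match_class == NONE

    def test_duplicated_query_sequence_is_multiple(self):
        p = TestUniquelyIdentifiable()._poly("a", "ACGTACGTACGTAC")
        q1 = _te("q1", "I", 0, 14, p.projected_sequence)
        q2 = _te("q2", "II", 50, 64, p.projected_sequence)
        (m,) = cross_reference([p], [q1, q2])
        assert m.match_class == MULTIPLE
        assert set(m.query_te_ids) == {"q1", "q2"}

    def test_matches_equal_bruteforce_all_pairs(self, small_sim, small_tracking):
        _, matches, _, _, unique = small_tracking
        by_id = {m.ref_te_id: m for m in matches}
        for p in unique:  # quadratic oracle
            hits = {
                q.te_id
                for q in small_sim.query_tes
                if q.sequence == p.projected_sequence
                or q.sequence == revcomp(p.projected_sequence)
            }
            assert set(by_id[p.ref_te.te_id].query_te_ids) == hits

    def test_planted_movers_all_match_their_true_counterpart(self, small_sim, small_tracking):
        _, matches, _, _, _ = small_tracking
        by_id = {m.ref_te_id: m for m in matches}
        for mv in small_sim.truth.movements:
            m = by_id[mv.te_id]
            if mv.kind == "duplication":
                assert m.match_class == MULTIPLE
                assert set(m.query_te_ids) == {mv.te_id, f"{mv.te_id}_dup"}
            else:
                assert m.match_class == UNIQUE
                assert m.query_te_ids == (mv.te_id,)


class TestIndelOverlap:
    def test_indel_touching_te_flagged(self):
        te = _te("a", "I", 100, 200, "A" * 100)
        indel = VariantRecord("I", 150, "AGG", "A", 50.0, 30, 40, "hom")
        snp = _snp("I", 150, "A", "G")
        assert indel_overlapped_te_ids([te], [indel]) == {"a"}
        assert indel_overlapped_te_ids([te], [snp]) == set()
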