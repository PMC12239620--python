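import numpy as np
import pytest

from tetrack.io import GenomeAssembly, PafRow, revcomp
from tetrack.synteny import (
    FORWARD,
    REVERSE,
    SyntenyBlock,
    SyntenyMap,
    blocks_from_paf,
    build_anchor_map,
)

from conftest import random_assembly


@pytest.fixture(scope="module")
def ref():
    return random_assembly(31, {"I": 20_000, "II": 15_000})


class TestAnchorMap:
    def test_identity_genomes_one_block_per_chromosome(self, ref):
        smap = build_anchor_map(ref, ref)
        spans = {b.ref_chrom: (b.ref_start, b.ref_end, b.orientation) for b in smap.blocks}
        assert spans == {
            "I": (0, 20_000, FORWARD),
            "II": (0, 15_000, FORWARD),
        }

    def test_identity_lift_is_identity(self, ref):
        smap = build_anchor_map(ref, ref)
        rng = np.random.default_rng(0)
        for _ in range(200):
            chrom = "I" if rng.random() < 0.5 else "II"
            pos = int(rng.integers(0, ref.lengths[chrom]))
            res = smap.lift(chrom, pos)
            assert (res.query_chrom, res.pos, res.interpolated) == (chrom, pos, False)

    def test_reverse_complement_chromosome(self, ref):
        sub = GenomeAssembly({"I": ref.chromosomes["I"]})
        query = GenomeAssembly({"I": revcomp(ref.chromosomes["I"])})
        smap = build_anchor_map(sub, query)
        (block,) = smap.blocks
        assert block.orientation == REVERSE
        assert (block.ref_start, block.ref_end) == (0, 20_000)
        res = smap.lift("I", 100)
        assert res.pos == 20_000 - 1 - 100

    def test_insertion_offsets_blocks(self, ref):
        ins = random_assembly(77, {"x": 500}).chromosomes["x"]
        qseq = ref.chromosomes["I"][:8000] + ins + ref.chromosomes["I"][8000:]
        smap = build_anchor_map(
            GenomeAssembly({"I": ref.chromosomes["I"]}), GenomeAssembly({"I": qseq})
        )
        assert len(smap.blocks) == 2
        first, second = smap.blocks
        assert first.query_start - first.ref_start == 0
        assert second.query_start - second.ref_start == 500

    def test_lift_monotonic_within_blocks(self, ref):
        query = GenomeAssembly({"I": revcomp(ref.chromosomes["I"])})
        sub = GenomeAssembly({"I": ref.chromosomes["I"]})
        for smap, sign in ((build_anchor_map(sub, sub), 1), (build_anchor_map(sub, query), -1)):
            b = smap.blocks[0]
            lifts = [smap.lift("I", p).pos for p in range(b.ref_start, b.ref_end, 997)]
            deltas = np.diff(lifts)
            assert np.all(sign * deltas > 0)

    def test_reciprocal_lift_round_trip(self, small_sim):
        fwd = build_anchor_map(small_sim.reference, small_sim.query, mask=small_sim.ref_tes)
        rev = build_anchor_map(small_sim.query, small_sim.reference, mask=small_sim.query_tes)
        rng = np.random.default_rng(4)
        checked = 0
        for b in fwd.blocks:
            for _ in range(5):
                pos = int(rng.integers(b.ref_start, b.ref_end))
                there = fwd.lift(b.ref_chrom, pos)
                back = rev.lift(there.query_chrom, there.pos)
                if not there.interpolated and not back.interpolated:
                    assert (back.query_chrom, back.pos) == (b.ref_chrom, pos)
                    checked += 1
        assert checked > 50

    def test_even_k_rejected(self, ref):
        with pytest.raises(ValueError):
            build_anchor_map(ref, ref, k=20)

    def test_degenerate_repeat_genome_gives_empty_map(self):
        mono = GenomeAssembly({"I": "AT" * 2000})
        assert len(build_anchor_map(mono, mono)) == 0

    def test_planted_indels_lift_matches_edit_map(self):
        # 50 indels applied to one chromosome with exact offset bookkeeping
        base = random_assembly(55, {"I": 120_000})
        seq = base.chromosomes["I"]
        rng = np.random.default_rng(6)
        positions = np.sort(rng.choice(np.arange(1000, 119_000), size=50, replace=False))
        positions = positions[np.diff(np.concatenate(([0], positions))) > 200]
        edits = []  # (ref_pos, delta)
        parts, cur = [], 0
        for p in positions:
            p = int(p)
            size = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion
                parts.append(seq[cur:p])
                cur = p + size
                edits.append((p, -size, p + size))
            else:
                parts.append(seq[cur:p])
                parts.append(
                    "".join(np.array(list("ACGT"))[rng.integers(0, 4, size)])
                )
                cur = p
                edits.append((p, size, p))
        parts.append(seq[cur:])
        query = GenomeAssembly({"I": "".join(parts)})

        def oracle(pos):  # cumulative-offset map of the planted edits
            delta = sum(d for (ep, d, end) in edits if end <= pos)
            return pos + delta

        smap = build_anchor_map(base, query)
        edit_sites = np.array([p for p, _, _ in edits])
        probes = rng.integers(0, 120_000, size=2_000)
        n_in_block = 0
        for pos in probes:
            pos = int(pos)
            if np.min(np.abs(edit_sites - pos)) <= 25:
                continue  # junction-adjacent bases are not block interior
            res = smap.lift("I", pos)
            if res is None or res.interpolated:
                continue
            assert res.pos == oracle(pos), pos
            n_in_block += 1
        assert n_in_block >= 1_000


class TestPafImport:
    def test_single_forward_row(self):
        row = PafRow("q1", 2000, 0, 1900, "+", "t1", 2200, 100, 2000, 1850, 1900, 60)
        smap = blocks_from_paf([row])
        (b,) = smap.blocks
        assert (b.ref_chrom, b.ref_start, b.ref_end) == ("t1", 100, 2000)
        assert (b.query_chrom, b.query_start, b.query_end) == ("q1", 0, 1900)
        assert b.orientation == FORWARD

    def test_short_rows_dropped(self):
        row = PafRow("q", 1000, 0, 500, "+", "t", 1000, 0, 500, 480, 500, 60)
        assert len(blocks_from_paf([row], min_len=1000)) == 0

    def test_reference_overlap_keeps_longer_row(self):
        long_row = PafRow("q", 9000, 0, 8000, "+", "t", 9000, 0, 8000, 7900, 8000, 60)
        short_row = PafRow("q2", 9000, 100, 3100, "+", "t", 9000, 4000, 7000, 2900, 3000, 60)
        smap = blocks_from_paf([long_row, short_row])
        assert [b.ref_span for b in smap.blocks] == [8000]

    def test_random_rows_match_bruteforce_overlap_resolution(self):
        rng = np.random.default_rng(13)
        rows = []
        for i in range(100):
            start = int(rng.integers(0, 90_000))
            end = start + int(rng.integers(1_000, 9_000))
            rows.append(
                PafRow(f"q{i}", 100_000, start, end, "+", "t", 100_000,
                       start, end, end - start, end - start, 60)
            )
        smap = blocks_from_paf(rows)
        # oracle: greedy keep-longest among rows overlapping on the reference
        kept = []
        for r in sorted(rows, key=lambda r: -(r.target_end - r.target_start)):
            if all(
                r.target_end <= k.target_start or k.target_end <= r.target_start
                for k in kept
            ):
                kept.append(r)
        spans = sorted((b.ref_start, b.ref_end) for b in smap.blocks)
        assert spans == sorted((r.target_start, r.target_end) for r in kept)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestMapInvariants:
    def test_blocks_sorted_and_searchable(self, small_sim):
        smap = build_anchor_map(small_sim.reference, small_sim.query, mask=small_sim.ref_tes)
        keys = [(b.ref_chrom, b.ref_start) for b in smap.blocks]
        assert keys == sorted(keys)
        for b1, b2 in zip(smap.blocks, smap.blocks[1:]):
            if b1.ref_chrom == b2.ref_chrom:
                assert b1.ref_end <= b2.ref_start

    def test_unplaced_for_unknown_chromosome(self, small_sim):
        smap = build_anchor_map(small_sim.reference, small_sim.query)
        assert smap.lift("chr99", 5) is None
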