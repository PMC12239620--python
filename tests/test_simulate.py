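import dataclasses
from collections import Counter

import numpy as np
import pytest

from tetrack.simulate import (
    DEFAULT_FAMILIES,
    DUPLICATION,
    SimulationParams,
    TEFamilySpec,
    make_te_library,
    simulate,
    simulate_reference,
)

from conftest import SMALL_FAMILIES, SMALL_PARAMS


class TestTeLibrary:
    def test_deterministic_under_seed(self):
        assert make_te_library(DEFAULT_FAMILIES, 4) == make_te_library(DEFAULT_FAMILIES, 4)
        assert make_te_library(DEFAULT_FAMILIES, 4) != make_te_library(DEFAULT_FAMILIES, 5)

    def test_consensus_lengths(self):
        lib = make_te_library(DEFAULT_FAMILIES, 1)
        for spec in DEFAULT_FAMILIES:
            assert len(lib[spec.name]) == spec.consensus_length

    def test_gc_fraction_of_long_consensus(self):
        spec = (TEFamilySpec("Gypsy", "I", 10_000, 1, 0.0),)
        seq = make_te_library(spec, 2)["Gypsy"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_family_spec_validation(self):
        with pytest.raises(ValueError):
            TEFamilySpec("x", "II", 100, 1, 0.01)  # too short
        with pytest.raises(ValueError):
            TEFamilySpec("x", "II", 500, 1, 0.5)  # divergence out of range


class TestSimulateReference:
    def test_zero_copies_gives_plain_genome(self):
        params = dataclasses.replace(SMALL_PARAMS, n_nested_distractors=0)
        specs = (TEFamilySpec("Zator", "II", 900, 0, 0.02),)
        asm, tes, truth = simulate_reference(params, family_specs=specs)
        assert tes == []
        assert asm.lengths == {
            n: params.chromosome_length for n in ("I", "II", "III")
        }

    def test_annotation_sequences_match_genome(self, small_sim):
        for te in small_sim.ref_tes:
            assert small_sim.reference.fetch(te.chrom, te.start, te.end) == te.sequence

    def test_infeasible_packing_rejected(self):
        specs = (TEFamilySpec("Zator", "II", 10_000, 200, 0.0),)
        params = dataclasses.replace(SMALL_PARAMS, n_nested_distractors=0)
        with pytest.raises(ValueError, match="packing"):
            simulate_reference(params, family_specs=specs)

    def test_arm_bias_matches_placement_probability(self):
        # 20 small replicates; compare pooled arm counts with a binomial CI
        params = SimulationParams(
            n_chromosomes=2,
            chromosome_length=50_000,
            n_intra_moves=0,
            n_inter_moves=0,
            n_nested_distractors=0,
            n_identical_flank_distractors=0,
            n_duplication_distractors=0,
        )
        specs = (TEFamilySpec("MITE", "II", 300, 40, 0.02),)
        w_arm, w_center = params.te_arm_weight, params.te_center_weight
        p_arm = (w_arm * 2 / 3) / (w_arm * 2 / 3 + w_center * 1 / 3)
        n_arm = n_tot = 0
        for seed in range(20):
            asm, tes, _ = simulate_reference(
                dataclasses.replace(params, rng_seed=seed), family_specs=specs
            )
            for te in tes:
                length = asm.lengths[te.chrom]
                mid = (te.start + te.end) // 2
                n_arm += mid < length / 3 or mid >= 2 * length / 3
                n_tot += 1
        sd = np.sqrt(p_arm * (1 - p_arm) * n_tot)
        assert abs(n_arm - p_arm * n_tot) < 2.58 * sd + 0.01 * n_tot


class TestDeriveQuery:
    def test_determinism_byte_identical(self, tmp_path):
        a = simulate(SMALL_PARAMS, family_specs=SMALL_FAMILIES)
        b = simulate(SMALL_PARAMS, family_specs=SMALL_FAMILIES)
        assert a.query.chromosomes == b.query.chromosomes
        assert a.variants == b.variants
        assert a.truth.movements == b.truth.movements
        pa = a.save(tmp_path / "a")
        pb = b.save(tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_all_zero_rates_identity(self):
        params = dataclasses.replace(
            SMALL_PARAMS,
            arm_snp_rate=0.0,
            center_snp_rate=0.0,
            indel_rate=0.0,
            n_intra_moves=0,
            n_inter_moves=0,
            n_nested_distractors=0,
            n_identical_flank_distractors=0,
            n_duplication_distractors=0,
        )
        sim = simulate(params, family_specs=SMALL_FAMILIES)
        assert sim.query.chromosomes == sim.reference.chromosomes
        assert sim.variants == []

    def test_inter_move_changes_chromosome(self, small_sim):
        inter = [m for m in small_sim.truth.movements if m.kind == "inter"]
        assert len(inter) == SMALL_PARAMS.n_inter_moves
        for m in inter:
            assert m.dest_chrom != m.src_chrom

    def test_truth_movement_counts(self, small_sim):
        counts = Counter(m.kind for m in small_sim.truth.movements)
        assert counts == {
            "intra": 2,
            "inter": 2,
            "flank_distractor": 2,
            "nested_distractor": 2,
            "duplication": 2,
        }
        # conservation: each TE moves at most once
        ids = [m.te_id for m in small_sim.truth.movements]
        assert len(ids) == len(set(ids))

    def test_every_movement_te_has_a_fingerprint_snp(self, small_sim):
        for m in small_sim.truth.movements:
            assert small_sim.truth.fingerprints.get(m.te_id)

    def test_moved_te_query_sequence_is_variant_applied_ref_sequence(self, small_sim):
        from tetrack.matching import apply_variants

        qte = {t.te_id: t for t in small_sim.query_tes}
        for m in small_sim.truth.movements:
            ref_te = {t.te_id: t for t in small_sim.ref_tes}[m.te_id]
            projected = apply_variants(
                ref_te.sequence, small_sim.truth.fingerprints[m.te_id]
            )
            dest_id = f"{m.te_id}_dup" if m.kind == DUPLICATION else m.te_id
            assert qte[dest_id].sequence == projected
            assert qte[dest_id].start == m.dest_query_start

    def test_vcf_positions_differ_between_assemblies(self, small_sim):
        moved_spans = {
            (m.src_chrom, m.src_start, m.src_end)
            for m in small_sim.truth.movements
            if m.kind != DUPLICATION
        }

        def in_moved(chrom, pos0):
            return any(
                c == chrom and s <= pos0 < e for c, s, e in moved_spans
            )

        for v in small_sim.variants:
            if not v.is_snp or in_moved(v.chrom, v.pos - 1):
                continue
            assert small_sim.reference.chromosomes[v.chrom][v.pos - 1] == v.ref_allele

    def test_vcf_application_reconstructs_query(self, small_sim):
        """Independent naive string editor: apply every VCF record plus the
        planted movement operations to the reference; the result must be
        byte-identical to the emitted query genome."""
        sim = small_sim
        edits = {chrom: [] for chrom in sim.reference.names}
        # (pos, del_len, insert) in reference coordinates
        for v in sim.variants:
            if v.is_snp:
                edits[v.chrom].append((v.pos - 1, 1, v.alt_allele))
            elif len(v.ref_allele) > len(v.alt_allele):  # deletion
                edits[v.chrom].append(
                    (v.pos, len(v.ref_allele) - 1, "")
                )
            else:  # insertion
                edits[v.chrom].append((v.pos, 0, v.alt_allele[1:]))
        from tetrack.matching import apply_variants

        ref_by_id = {t.te_id: t for t in sim.ref_tes}
        for m in sim.truth.movements:
            te = ref_by_id[m.te_id]
            projected = apply_variants(te.sequence, sim.truth.fingerprints[m.te_id])
            if m.kind != DUPLICATION:
                edits[m.src_chrom].append((m.src_start, te.length, ""))
            if m.kind == "flank_distractor":
                pad = sim.params.flank_pad

                def flank(start, end):
                    chars = list(sim.reference.fetch(m.src_chrom, start, end))
                    for v in sim.variants:
                        if v.is_snp and v.chrom == m.src_chrom and start <= v.pos - 1 < end:
                            chars[v.pos - 1 - start] = v.alt_allele
                    return "".join(chars)

                insert = (
                    flank(m.src_start - pad, m.src_start)
                    + projected
                    + flank(m.src_end, m.src_end + pad)
                )
            else:
                insert = projected
            edits[m.dest_chrom].append((m.dest_ref_pos, 0, insert))

        for chrom in sim.reference.names:
            seq = sim.reference.chromosomes[chrom]
            out, cur = [], 0
            for pos, dl, ins in sorted(edits[chrom]):
                if pos < cur:
                    continue  # SNP recorded inside an excised TE span
                out.append(seq[cur:pos])
                out.append(ins)
                cur = pos + dl
            out.append(seq[cur:])
            assert "".join(out) == sim.query.chromosomes[chrom], chrom

    def test_requesting_too_many_moves_fails(self):
        params = dataclasses.replace(SMALL_PARAMS, n_intra_moves=500)
        with pytest.raises(ValueError, match="eligible"):
            simulate(params, family_specs=SMALL_FAMILIES)
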