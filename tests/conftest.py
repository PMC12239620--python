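"""Shared fixtures: a miniature simulated genome pair and the tracking
chain run on it, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from tetrack.io import GenomeAssembly, filter_variants
from tetrack.matching import (
    annotate_te_snps,
    cross_reference,
    indel_overlapped_te_ids,
    uniquely_identifiable,
)
from tetrack.movement import call_movements
from tetrack.simulate import (
    SimulationParams,
    TEFamilySpec,
    simulate,
)
from tetrack.synteny import build_anchor_map

SMALL_FAMILIES = (
    TEFamilySpec("Tc1/Mariner", "II", 1600, 6, 0.02),
    TEFamilySpec("Zator", "II", 900, 8, 0.02),
    TEFamilySpec("MITE", "II", 300, 8, 0.02),
    TEFamilySpec("hAT", "II", 1200, 6, 0.02),
)

SMALL_PARAMS = SimulationParams(
    n_chromosomes=3,
    chromosome_length=60_000,
    n_intra_moves=2,
    n_inter_moves=2,
    n_nested_distractors=2,
    n_identical_flank_distractors=2,
    n_duplication_distractors=2,
    intra_distance_range=(1_000, 30_000),
    rng_seed=5,
)


def random_assembly(seed: int, lengths: dict[str, int]) -> GenomeAssembly:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return GenomeAssembly(
        {
            name: bytes(bases[rng.integers(0, 4, size=n)]).decode()
            for name, n in lengths.items()
        }
    )


def run_tracking(sim, **kwargs):
    """The full library-level tracking chain on a simulation result."""
    variants = filter_variants(sim.variants)
    snps = [v for v in variants if v.is_snp]
    hit = indel_overlapped_te_ids(sim.ref_tes, variants)
    trackable = [te for te in sim.ref_tes if te.te_id not in hit]
    poly = annotate_te_snps(trackable, snps)
    unique = uniquely_identifiable(poly, all_ref_tes=sim.ref_tes)
    matches = cross_reference(unique, sim.query_tes)
    smap = build_anchor_map(sim.reference, sim.query, mask=sim.ref_tes)
    calls = call_movements(
        matches, sim.ref_tes, sim.query_tes, smap, sim.reference, sim.query, **kwargs
    )
    return calls, matches, smap, poly, unique


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SMALL_PARAMS, family_specs=SMALL_FAMILIES)


@pytest.fixture(scope="session")
def small_tracking(small_sim):
    return run_tracking(small_sim)
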