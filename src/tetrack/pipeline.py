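"""Orchestration of the three pipeline stages: simulate, track, enrich.

Each run_* function takes explicit inputs, writes its output files into an
output directory together with a `run_config.log` capturing the resolved
configuration, and returns the in-memory results for programmatic use.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import __version__
from .align import AlignParams
from .enrichment import (
    define_workspaces,
    enrichment_test,
    variants_to_intervals,
    write_enrichment_tsv,
)
from .io import (
    Interval,
    filter_variants,
    read_bed,
    read_fasta,
    read_gff_te,
    read_paf,
    read_vcf,
)
from .matching import (
    annotate_te_snps,
    cross_reference,
    indel_overlapped_te_ids,
    uniquely_identifiable,
    write_fingerprints_tsv,
    write_matches_tsv,
)
from .movement import call_movements, summarize_by_family, write_movements_tsv
from .simulate import SimulationParams, SimulationResult, simulate
from .synteny import blocks_from_paf, build_anchor_map, write_blocks_tsv

logger = logging.getLogger(__name__)


def _log_config(outdir: Path, subcommand: str, config: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.log", "w") as fh:
        fh.write(f"tetrack {__version__}\nsubcommand: {subcommand}\n")
        for key in sorted(config):
            fh.write(f"{key}: {config[key]}\n")


def run_simulate(outdir, params: SimulationParams | None = None) -> SimulationResult:
    """Generate a synthetic genome pair and write all its files."""
    if params is None:
        params = SimulationParams()
    result = simulate(params)
    outdir = Path(outdir)
    result.save(outdir)
    _log_config(outdir, "simulate", dataclasses.asdict(params))
    return result


def run_track(
    ref_fa,
    query_fa,
    ref_te_gff,
    query_te_gff,
    vcf,
    outdir,
    paf=None,
    tolerance: int = 100,
    flank_identity_max: float = 0.90,
    k: int = 21,
    max_gap: int = 10_000,
    flank_rule: str = "either",
    flank_filter_inter: bool = True,
    align_params: AlignParams | None = None,
):
    """Fingerprint, cross-reference and classify TE movements.

    Returns (calls, matches, synteny_map, family_summary).  The synteny map
    comes from the supplied PAF when given, otherwise from the internal
    anchor aligner with the reference TE annotation masked out.
    """
    outdir = Path(outdir)
    ref = read_fasta(ref_fa)
    query = read_fasta(query_fa)
    ref_tes = read_gff_te(ref_te_gff, assembly=ref)
    query_tes = read_gff_te(query_te_gff, assembly=query)
    variants = filter_variants(read_vcf(vcf))

    snp_variants = [v for v in variants if v.is_snp]
    indel_hit = indel_overlapped_te_ids(ref_tes, variants)
    if indel_hit:
        logger.info("%d TEs overlapped by indels dropped from tracking", len(indel_hit))
    trackable = [te for te in ref_tes if te.te_id not in indel_hit]

    poly = annotate_te_snps(trackable, snp_variants)
    unique = uniquely_identifiable(poly, all_ref_tes=ref_tes)
    matches = cross_reference(unique, query_tes)

    if paf is not None:
        smap = blocks_from_paf(read_paf(paf))
    else:
        smap = build_anchor_map(ref, query, k=k, max_gap=max_gap, mask=ref_tes)

    calls = call_movements(
        matches,
        ref_tes,
        query_tes,
        smap,
        ref,
        query,
        tolerance=tolerance,
        flank_identity_max=flank_identity_max,
        align_params=align_params,
        flank_rule=flank_rule,
        flank_filter_inter=flank_filter_inter,
    )
    summary = summarize_by_family(calls)

    outdir.mkdir(parents=True, exist_ok=True)
    write_fingerprints_tsv(poly, outdir / "fingerprints.tsv")
    write_matches_tsv(matches, outdir / "matches.tsv")
    write_blocks_tsv(smap, outdir / "synteny_blocks.tsv")
    write_movements_tsv(calls, outdir / "movements.tsv")
    summary.to_csv(outdir / "family_summary.tsv", sep="\t", index=False)
    _log_config(
        outdir,
        "track",
        {
            "ref": str(ref_fa),
            "query": str(query_fa),
            "ref_te": str(ref_te_gff),
            "query_te": str(query_te_gff),
            "vcf": str(vcf),
            "paf": str(paf) if paf else "(internal anchor map)",
            "tolerance": tolerance,
            "flank_identity_max": flank_identity_max,
            "k": k,
            "max_gap": max_gap,
            "flank_rule": flank_rule,
            "flank_filter_inter": flank_filter_inter,
            "n_ref_tes": len(ref_tes),
            "n_polymorphic": len(poly),
            "n_unique": len(unique),
            "n_indel_dropped": len(indel_hit),
        },
    )
    return calls, matches, smap, summary


def run_enrich(
    variants_path,
    annotations_path,
    outdir,
    workspaces_path=None,
    ref_fa=None,
    arm_fraction: float = 1 / 3,
    n_iter: int = 20_000,
    seed: int = 0,
):
    """Workspace-restricted permutation enrichment of a variant set.

    Variants come from BED or VCF (SNP -> 1 bp interval, indel -> replaced
    span); workspaces from a labelled BED, or from arm/center terminal
    thirds of the chromosomes of `ref_fa`.
    """
    outdir = Path(outdir)
    variants_path = str(variants_path)
    if variants_path.endswith((".vcf", ".vcf.gz")):
        records = read_vcf(variants_path)
        variants = variants_to_intervals(filter_variants(records))
    else:
        variants = read_bed(variants_path)
    annotation = read_bed(annotations_path)

    if workspaces_path is not None:
        workspaces = define_workspaces({}, override_bed=read_bed(workspaces_path))
    elif ref_fa is not None:
        lengths = read_fasta(ref_fa).lengths
        workspaces = define_workspaces(lengths, arm_fraction=arm_fraction)
    else:
        raise ValueError("need either a workspace BED or a reference FASTA")

    rows = []
    results = {}
    for i, ws in enumerate(workspaces):
        res = enrichment_test(
            variants, annotation, ws, n_iter=n_iter, seed=seed * 10_000 + i
        )
        results[(ws.label, ws.chrom)] = res
        rows.append(
            {
                "variant_set": Path(variants_path).name,
                "annotation": Path(str(annotations_path)).name,
                "workspace": ws.label,
                "chrom": ws.chrom,
                "observed_bp": res.observed_overlap_bp,
                "null_mean_bp": f"{res.null_mean_bp:.3f}",
                "null_sd_bp": f"{res.null_sd_bp:.3f}",
                "log2_fold": f"{res.log2_fold:.4f}",
                "empirical_p": f"{res.empirical_p:.6g}",
                "hypergeometric_p": f"{res.hypergeometric_p:.6g}",
                "n_iterations": res.n_iterations,
            }
        )
    outdir.mkdir(parents=True, exist_ok=True)
    write_enrichment_tsv(rows, outdir / "enrichment.tsv")
    _log_config(
        outdir,
        "enrich",
        {
            "variants": str(variants_path),
            "annotations": str(annotations_path),
            "workspaces": str(workspaces_path) if workspaces_path else "(arm/center thirds)",
            "arm_fraction": arm_fraction,
            "n_iter": n_iter,
            "seed": seed,
        },
    )
    return results
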