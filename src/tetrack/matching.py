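"""Fingerprint reference TEs by their overlapping SNPs, project them into
query space by applying the variant bases, and cross-reference the projected
sequences against the query genome's TE set by exact string equality.

Only homozygous SNPs feed fingerprints: heterozygous, population-segregating
alleles would make a copy's projected sequence unstable.  TEs overlapped by
indel variants are dropped from tracking (with a logged count) because an
indel breaks exact full-length sequence comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import TECopy, VariantRecord, revcomp

logger = logging.getLogger(__name__)

UNIQUE = "unique"
MULTIPLE = "multiple"
NONE = "none"


@dataclass(frozen=True)
class PolymorphicTE:
    """A reference TE overlapped by at least one SNP.

    fingerprint_snps are (offset within the TE, ref base, alt base);
    projected_sequence is the TE sequence with the alt bases applied.
    """

    ref_te: TECopy
    fingerprint_snps: tuple[tuple[int, str, str], ...]
    projected_sequence: str

    def __post_init__(self):
        if not self.fingerprint_snps:
            raise ValueError("a PolymorphicTE needs at least one fingerprint SNP")


@dataclass(frozen=True)
class TEMatch:
    ref_te_id: str
    query_te_ids: tuple[str, ...]
    match_class: str  # unique | multiple | none
    orientation_flip: tuple[bool, ...] = ()

    def __post_init__(self):
        expected = {0: NONE, 1: UNIQUE}.get(len(self.query_te_ids), MULTIPLE)
        if self.match_class != expected:
            raise ValueError(
                f"match_class {self.match_class!r} inconsistent with "
                f"{len(self.query_te_ids)} query ids"
            )


def _snps_by_chrom(variants: list[VariantRecord]):
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.is_snp:
            by_chrom.setdefault(v.chrom, []).append(v)
    out = {}
    for chrom, snps in by_chrom.items():
        snps.sort(key=lambda v: v.pos)
        out[chrom] = (np.array([v.pos - 1 for v in snps], dtype=np.int64), snps)
    return out


def annotate_te_snps(
    ref_tes: list[TECopy], variants: list[VariantRecord]
) -> list[PolymorphicTE]:
    """One PolymorphicTE per reference TE overlapped by >= 1 SNP.

    SNP offsets are (0-based VCF position) - te.start.  A SNP whose REF
    allele disagrees with the TE sequence at that offset is a hard error
    (the assembly and the VCF are inconsistent).  Indel variants are
    ignored here; use `indel_overlapped_te_ids` to flag TEs they touch.
    """
    index = _snps_by_chrom(variants)
    out = []
    for te in ref_tes:
        if te.chrom not in index:
            continue
        positions, snps = index[te.chrom]
        lo = int(np.searchsorted(positions, te.start, side="left"))
        hi = int(np.searchsorted(positions, te.end, side="left"))
        if lo == hi:
            continue
        fps = []
        for v in snps[lo:hi]:
            off = (v.pos - 1) - te.start
            if te.sequence and te.sequence[off] != v.ref_allele:
                raise ValueError(
                    f"SNP {v.chrom}:{v.pos} REF {v.ref_allele!r} disagrees with "
                    f"TE {te.te_id} base {te.sequence[off]!r} at offset {off}"
                )
            fps.append((off, v.ref_allele, v.alt_allele))
        out.append(
            PolymorphicTE(
                ref_te=te,
                fingerprint_snps=tuple(fps),
                projected_sequence=apply_variants(te.sequence, fps),
            )
        )
    return out


def indel_overlapped_te_ids(
    tes: list[TECopy], variants: list[VariantRecord]
) -> set[str]:
    """IDs of TEs whose interval is touched by an indel's reference span."""
    indels = [v for v in variants if not v.is_snp]
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in indels:
        by_chrom.setdefault(v.chrom, []).append(v)
    hit = set()
    for te in tes:
        for v in by_chrom.get(te.chrom, ()):
            if v.start < te.end and te.start < v.end:
                hit.add(te.te_id)
                break
    return hit


def apply_variants(
    te_sequence: str, fingerprint_snps: list[tuple[int, str, str]]
) -> str:
    """Apply substitution-only variant bases to a TE sequence."""
    if not fingerprint_snps:
        return te_sequence
    chars = list(te_sequence)
    for off, ref_base, alt_base in fingerprint_snps:
        if not (0 <= off < len(chars)):
            raise ValueError(f"SNP offset {off} outside sequence of length {len(chars)}")
        if chars[off] != ref_base:
            raise ValueError(
                f"ref base mismatch at offset {off}: sequence has "
                f"{chars[off]!r}, variant says {ref_base!r}"
            )
        if len(alt_base) != 1:
            raise ValueError("fingerprints are substitution-only")
        chars[off] = alt_base
    return "".join(chars)


def canonical(seq: str) -> str:
    """Orientation-independent representative of a sequence."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def uniquely_identifiable(
    polymorphic_tes: list[PolymorphicTE],
    all_ref_tes: list[TECopy] | None = None,
    consider_rc: bool = True,
) -> list[PolymorphicTE]:
    """Retain copies whose projected sequence is unique among all projected
    sequences AND whose raw sequence is unique among all reference TE
    sequences (both orientations by default)."""
    key = canonical if consider_rc else (lambda s: s)
    raw_pool = (
        [te.sequence for te in all_ref_tes]
        if all_ref_tes is not None
        else [p.ref_te.sequence for p in polymorphic_tes]
    )
    raw_counts: dict[str, int] = {}
    for s in raw_pool:
        ks = key(s)
        raw_counts[ks] = raw_counts.get(ks, 0) + 1
    proj_counts: dict[str, int] = {}
    for p in polymorphic_tes:
        ks = key(p.projected_sequence)
        proj_counts[ks] = proj_counts.get(ks, 0) + 1
    return [
        p
        for p in polymorphic_tes
        if proj_counts[key(p.projected_sequence)] == 1
        and raw_counts[key(p.ref_te.sequence)] == 1
    ]


def cross_reference(
    unique_tes: list[PolymorphicTE],
    query_tes: list[TECopy],
    consider_rc: bool = True,
) -> list[TEMatch]:
    """Exact full-length matches of projected sequences against query TEs."""
    key = canonical if consider_rc else (lambda s: s)
    by_seq: dict[str, list[TECopy]] = {}
    for q in query_tes:
        by_seq.setdefault(key(q.sequence), []).append(q)
    out = []
    for p in unique_tes:
        hits = by_seq.get(key(p.projected_sequence), [])
        flips = tuple(q.sequence != p.projected_sequence for q in hits)
        out.append(
            TEMatch(
                ref_te_id=p.ref_te.te_id,
                query_te_ids=tuple(q.te_id for q in hits),
                match_class={0: NONE, 1: UNIQUE}.get(len(hits), MULTIPLE),
                orientation_flip=flips,
            )
        )
    return out


def write_fingerprints_tsv(poly_tes: list[PolymorphicTE], path) -> None:
    with open(path, "w") as fh:
        fh.write("te_id\tn_snps\toffsets\n")
        for p in poly_tes:
            offs = ",".join(str(o) for o, _, _ in p.fingerprint_snps)
            fh.write(f"{p.ref_te.te_id}\t{len(p.fingerprint_snps)}\t{offs}\n")


def write_matches_tsv(matches: list[TEMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_te_id\tquery_te_ids\tmatch_class\torientation_flip\n")
        for m in matches:
            qids = ";".join(m.query_te_ids) or "."
            flips = ";".join(str(int(f)) for f in m.orientation_flip) or "."
            fh.write(f"{m.ref_te_id}\t{qids}\t{m.match_class}\t{flips}\n")
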