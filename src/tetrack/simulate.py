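"""Synthetic reference/query genome pairs with planted TEs, variants and
transposition events, plus a machine-readable truth table.

The generator emulates the statistical structure of a pair of diverged
nematode strain assemblies: several class I/II TE families whose copies
concentrate in the terminal-third "arm" domains of each chromosome, per-copy
sequence divergence so individual copies are distinguishable, background
SNPs and small indels biased toward the arms, and a handful of planted
inter- and intrachromosomal TE movements with known distances.  Three
distractor classes stress the detector: same-family nested TEs whose inner
copy relocates, movements whose destination flanks replicate the source
flanks, and TEs duplicated at two query loci.

Movements are clean cut-and-paste: excision leaves no scar and insertion
adds no target-site duplication, since the detector operates on annotated
intervals and start coordinates rather than excision footprints.
Every moved or distractor TE is guaranteed at least one internal SNP, as
only SNP-bearing copies are trackable.  Background indels never fall inside
TE intervals by default so that exact-sequence cross-referencing stays
well-defined.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import (
    GenomeAssembly,
    TECopy,
    VariantRecord,
    write_fasta,
    write_gff_te,
    write_vcf,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHROM_NAMES = ["I", "II", "III", "IV", "V", "X"]

# movement / distractor kinds
INTRA_MOVE = "intra"
INTER_MOVE = "inter"
FLANK_DISTRACTOR = "flank_distractor"
NESTED_DISTRACTOR = "nested_distractor"
DUPLICATION = "duplication"

# TE roles in the reference
ROLE_NORMAL = "normal"
ROLE_NESTED_OUTER = "nested_outer"
ROLE_NESTED_INNER = "nested_inner"


@dataclass(frozen=True)
class TEFamilySpec:
    name: str
    te_class: str  # "I" | "II"
    consensus_length: int
    copy_number: int
    per_copy_divergence: float

    def __post_init__(self):
        if self.consensus_length < 150:
            raise ValueError("consensus must exceed 2x flank length + 50")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not 0 <= self.per_copy_divergence <= 0.1:
            raise ValueError("per-copy divergence outside [0, 0.1]")
        if self.te_class not in ("I", "II"):
            raise ValueError("te_class must be 'I' or 'II'")


#: Default family roster: class II DNA transposons dominate, Zator is the
#: most numerous family, and two retrotransposon (class I) families round
#: out the set.  Copy numbers are scaled to a miniature multi-chromosome
#: genome while keeping the relative abundances plausible.
DEFAULT_FAMILIES: tuple[TEFamilySpec, ...] = (
    TEFamilySpec("Tc1/Mariner", "II", 1600, 35, 0.02),
    TEFamilySpec("hAT", "II", 1200, 30, 0.02),
    TEFamilySpec("CMC", "II", 1500, 20, 0.02),
    TEFamilySpec("Zator", "II", 900, 30, 0.02),
    TEFamilySpec("Sola", "II", 1100, 15, 0.02),
    TEFamilySpec("MITE", "II", 300, 40, 0.02),
    TEFamilySpec("Novosib", "II", 1000, 10, 0.02),
    TEFamilySpec("Helitron", "II", 1500, 15, 0.02),
    TEFamilySpec("Gypsy", "I", 2000, 15, 0.02),
    TEFamilySpec("Copia", "I", 1800, 15, 0.02),
)


@dataclass(frozen=True)
class SimulationParams:
    n_chromosomes: int = 3
    chromosome_length: int = 500_000
    arm_fraction: float = 1 / 3
    arm_snp_rate: float = 0.0035  # per bp; genome-wide mean ~2.6e-3
    center_snp_rate: float = 0.00075
    indel_rate: float = 6e-5  # per bp in arms; center scaled as the SNP rates
    indel_max_len: int = 10
    n_intra_moves: int = 5
    n_inter_moves: int = 5
    intra_distance_range: tuple[int, int] = (1_000, 200_000)
    n_nested_distractors: int = 3
    n_identical_flank_distractors: int = 3
    n_duplication_distractors: int = 3
    te_arm_weight: float = 3.0  # per-bp placement weight, arms vs center
    te_center_weight: float = 1.0
    allow_te_indels: bool = False
    flank_pad: int = 50  # flank length copied for identical-flank distractors
    rng_seed: int = 0

    def __post_init__(self):
        if self.arm_snp_rate < self.center_snp_rate:
            raise ValueError("arm SNP rate must be >= center SNP rate")
        if min(
            self.n_intra_moves,
            self.n_inter_moves,
            self.n_nested_distractors,
            self.n_identical_flank_distractors,
            self.n_duplication_distractors,
        ) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.intra_distance_range
        if not 0 < lo <= hi:
            raise ValueError("bad intra_distance_range")


@dataclass(frozen=True)
class PlantedMovement:
    te_id: str
    kind: str  # intra | inter | flank_distractor | nested_distractor | duplication
    src_chrom: str
    src_start: int  # reference frame
    src_end: int
    dest_chrom: str
    dest_ref_pos: int  # insertion point in the reference frame
    dest_query_start: int  # TE start in the query frame
    distance: int | None  # query frame; None for inter/duplication
    insert_offset: int = 0  # offset of the TE within the inserted segment


@dataclass
class TruthTable:
    ref_tes: list[TECopy]
    query_tes: list[TECopy]
    roles: dict[str, str]
    movements: list[PlantedMovement]
    fingerprints: dict[str, list[tuple[int, str, str]]]

    def movement_by_te(self) -> dict[str, PlantedMovement]:
        return {m.te_id: m for m in self.movements}


def expected_verdicts(truth: TruthTable) -> dict[str, str]:
    """Truth te_id -> the verdict a correct detector should assign."""
    mapping = {
        INTRA_MOVE: "intra",
        INTER_MOVE: "inter",
        FLANK_DISTRACTOR: "excluded_flank",
        NESTED_DISTRACTOR: "excluded_nested",
        DUPLICATION: "ambiguous_duplication",
    }
    return {m.te_id: mapping[m.kind] for m in truth.movements}


# ---------------------------------------------------------------------------
# helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length, dtype=np.int64)]).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.searchsorted(_BASES, arr)
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        code[hit] = (code[hit] + shift) % 4
        arr = _BASES[code]
    return bytes(arr).decode()


def make_te_library(
    family_specs: tuple[TEFamilySpec, ...], seed: int
) -> dict[str, str]:
    """Uniform-random consensus per family, reproducible under the seed."""
    rng = np.random.default_rng(seed)
    return {
        spec.name: _random_seq(rng, spec.consensus_length) for spec in family_specs
    }


def _chrom_names(n: int) -> list[str]:
    if n <= len(_CHROM_NAMES):
        return _CHROM_NAMES[:n]
    return _CHROM_NAMES + [f"chr{i}" for i in range(len(_CHROM_NAMES) + 1, n + 1)]


def _arm_bounds(length: int, arm_fraction: float) -> tuple[int, int]:
    import math

    b1 = int(math.ceil(length * arm_fraction - 0.5))
    b2 = int(math.ceil(length * (1 - arm_fraction) - 0.5))
    return b1, b2


def _sample_domain_positions(
    rng: np.random.Generator, length: int, arm_fraction: float, arm_rate: float, center_rate: float
) -> np.ndarray:
    """Positions of per-bp Bernoulli events with arm/center rates."""
    b1, b2 = _arm_bounds(length, arm_fraction)
    u = rng.random(length)
    rates = np.full(length, center_rate)
    rates[:b1] = arm_rate
    rates[b2:] = arm_rate
    return np.nonzero(u < rates)[0]


def _sample_position(
    rng: np.random.Generator,
    length: int,
    arm_fraction: float,
    arm_weight: float,
    center_weight: float,
) -> int:
    b1, b2 = _arm_bounds(length, arm_fraction)
    arm_bp = b1 + (length - b2)
    center_bp = b2 - b1
    p_arm = arm_weight * arm_bp / (arm_weight * arm_bp + center_weight * center_bp)
    if rng.random() < p_arm:
        k = int(rng.integers(0, arm_bp))
        return k if k < b1 else b2 + (k - b1)
    return b1 + int(rng.integers(0, center_bp))


class _Blocked:
    """Per-chromosome interval sets for collision-free sampling."""

    def __init__(self):
        self._ivs: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        self._ivs.setdefault(chrom, []).append((start, end))

    def hits(self, chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in self._ivs.get(chrom, ()))


# ---------------------------------------------------------------------------
# reference simulation


@dataclass
class ReferenceTruth:
    roles: dict[str, str]
    families: dict[str, TEFamilySpec]


def simulate_reference(
    params: SimulationParams,
    library: dict[str, str] | None = None,
    family_specs: tuple[TEFamilySpec, ...] = DEFAULT_FAMILIES,
) -> tuple[GenomeAssembly, list[TECopy], ReferenceTruth]:
    """Random background chromosomes with arm-biased TE copies.

    Each copy is the family consensus mutated at its per-copy divergence so
    copies are distinguishable.  `n_nested_distractors` same-family TE
    fragments are planted inside existing copies.
    """
    rng = np.random.default_rng([params.rng_seed, 0])
    if library is None:
        library = make_te_library(family_specs, params.rng_seed)
    names = _chrom_names(params.n_chromosomes)
    L = params.chromosome_length

    total_te_bp = sum(s.consensus_length * s.copy_number for s in family_specs)
    if total_te_bp > 0.5 * params.n_chromosomes * L:
        raise ValueError("infeasible packing: TE bp exceeds 50% of genome")

    backgrounds = {name: _random_seq(rng, L) for name in names}

    # choose insertion sites in the background frame, 150 bp apart
    placements: dict[str, list[tuple[int, str, TEFamilySpec]]] = {n: [] for n in names}
    taken: dict[str, list[int]] = {n: [] for n in names}
    for spec in family_specs:
        consensus = library[spec.name]
        for _ in range(spec.copy_number):
            seq = _mutate(rng, consensus, spec.per_copy_divergence)
            for _attempt in range(1000):
                chrom = names[int(rng.integers(0, len(names)))]
                pos = _sample_position(
                    rng, L, params.arm_fraction, params.te_arm_weight, params.te_center_weight
                )
                lo = bisect.bisect_left(taken[chrom], pos - 150)
                hi = bisect.bisect_right(taken[chrom], pos + 150)
                if lo == hi and 300 <= pos <= L - 300:
                    break
            else:
                raise RuntimeError("could not place TE copy without collision")
            bisect.insort(taken[chrom], pos)
            placements[chrom].append((pos, seq, spec))

    # nested distractors: a same-family fragment inside an existing copy
    flat = [
        (chrom, idx)
        for chrom in names
        for idx in range(len(placements[chrom]))
        if len(placements[chrom][idx][1]) >= 280
    ]
    if params.n_nested_distractors > len(flat):
        raise ValueError("not enough TE copies to host nested distractors")
    nested: dict[tuple[str, int], tuple[int, str, TEFamilySpec]] = {}
    if params.n_nested_distractors:
        picks = rng.choice(len(flat), size=params.n_nested_distractors, replace=False)
        for p in sorted(int(x) for x in picks):
            chrom, idx = flat[p]
            pos, outer_seq, spec = placements[chrom][idx]
            inner_len = max(150, len(outer_seq) // 3)
            inner_seq = _mutate(
                rng, library[spec.name][:inner_len], spec.per_copy_divergence
            )
            off = int(rng.integers(50, len(outer_seq) - inner_len - 50 + 1))
            nested[(chrom, idx)] = (off, inner_seq, spec)

    # materialize
    chroms: dict[str, str] = {}
    tes: list[TECopy] = []
    roles: dict[str, str] = {}
    families: dict[str, TEFamilySpec] = {}
    raw: list[tuple[str, int, int, TEFamilySpec, str]] = []  # chrom,start,end,spec,role
    for chrom in names:
        recs = sorted(
            ((pos, seq, spec, idx) for idx, (pos, seq, spec) in enumerate(placements[chrom])),
            key=lambda t: t[0],
        )
        parts = []
        cur = 0
        delta = 0
        for pos, seq, spec, idx in recs:
            parts.append(backgrounds[chrom][cur:pos])
            start = pos + delta
            if (chrom, idx) in nested:
                off, inner_seq, ispec = nested[(chrom, idx)]
                composite = seq[:off] + inner_seq + seq[off:]
                raw.append((chrom, start, start + len(composite), spec, ROLE_NESTED_OUTER))
                raw.append(
                    (chrom, start + off, start + off + len(inner_seq), ispec, ROLE_NESTED_INNER)
                )
                parts.append(composite)
                delta += len(composite)
            else:
                raw.append((chrom, start, start + len(seq), spec, ROLE_NORMAL))
                parts.append(seq)
                delta += len(seq)
            cur = pos
        parts.append(backgrounds[chrom][cur:])
        chroms[chrom] = "".join(parts)

    assembly = GenomeAssembly(chroms)
    raw.sort(key=lambda t: (_chrom_sort_key(t[0]), t[1], -(t[2] - t[1])))
    for i, (chrom, start, end, spec, role) in enumerate(raw, start=1):
        te_id = f"te_{i:04d}"
        tes.append(
            TECopy(
                te_id=te_id,
                chrom=chrom,
                start=start,
                end=end,
                strand="+",
                family=spec.name,
                te_class=spec.te_class,
                sequence=assembly.fetch(chrom, start, end),
            )
        )
        roles[te_id] = role
        families[te_id] = spec
    return assembly, tes, ReferenceTruth(roles=roles, families=families)


def _chrom_sort_key(name: str) -> int:
    try:
        return _CHROM_NAMES.index(name)
    except ValueError:
        return len(_CHROM_NAMES) + int(name.removeprefix("chr") or 0)


# ---------------------------------------------------------------------------
# query derivation


@dataclass
class _Op:
    chrom: str
    pos: int  # reference coordinate; insertion goes before this base
    del_len: int
    ins_seq: str
    tag: str
    q_start: int = -1


class _EditMap:
    """Reference -> query coordinate map induced by a set of edits."""

    def __init__(self, ops: list[_Op]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
        by_chrom: dict[str, list[_Op]] = {}
        for op in ops:
            by_chrom.setdefault(op.chrom, []).append(op)
        for chrom, chrom_ops in by_chrom.items():
            chrom_ops.sort(key=lambda o: o.pos)
            pos, del_end, cum = [], [], []
            delta = 0
            for op in chrom_ops:
                pos.append(op.pos)
                del_end.append(op.pos + op.del_len)
                delta += len(op.ins_seq) - op.del_len
                cum.append(delta)
            self._by_chrom[chrom] = (pos, del_end, cum)

    def map(self, chrom: str, p: int) -> int:
        if chrom not in self._by_chrom:
            return p
        pos, del_end, cum = self._by_chrom[chrom]
        i = bisect.bisect_right(pos, p) - 1
        if i < 0:
            return p
        if p < del_end[i]:  # inside a deleted span: collapse point
            prev = cum[i - 1] if i > 0 else 0
            return pos[i] + prev
        return p + cum[i]


def derive_query(
    reference: GenomeAssembly,
    ref_tes: list[TECopy],
    ref_truth: ReferenceTruth,
    params: SimulationParams,
) -> tuple[GenomeAssembly, list[TECopy], list[VariantRecord], TruthTable]:
    """Apply arm-biased background variants and planted TE movements.

    Returns the query assembly, its TE annotations, the query-vs-reference
    VCF records (all homozygous, all passing the retention filter), and the
    completed truth table with post-edit query coordinates.
    """
    rng = np.random.default_rng([params.rng_seed, 1])
    names = reference.names
    margin = 300
    pad = params.flank_pad + 10

    te_by_id = {te.te_id: te for te in ref_tes}
    blocked = _Blocked()
    for te in ref_tes:
        blocked.add(te.chrom, te.start - pad, te.end + pad)

    # --- select the TEs that move / act as distractors
    eligible = [
        te.te_id
        for te in ref_tes
        if ref_truth.roles[te.te_id] == ROLE_NORMAL
        and te.start >= margin
        and te.end <= len(reference.chromosomes[te.chrom]) - margin
    ]
    n_needed = (
        params.n_intra_moves
        + params.n_inter_moves
        + params.n_identical_flank_distractors
        + params.n_duplication_distractors
    )
    if n_needed > len(eligible):
        raise ValueError(
            f"requested {n_needed} movements/distractors but only "
            f"{len(eligible)} eligible TE copies"
        )
    chosen = [eligible[int(i)] for i in rng.choice(len(eligible), size=n_needed, replace=False)]
    intra_ids = chosen[: params.n_intra_moves]
    k = params.n_intra_moves
    inter_ids = chosen[k : k + params.n_inter_moves]
    k += params.n_inter_moves
    flank_ids = chosen[k : k + params.n_identical_flank_distractors]
    k += params.n_identical_flank_distractors
    dup_ids = chosen[k:]
    nested_ids = [
        te.te_id for te in ref_tes if ref_truth.roles[te.te_id] == ROLE_NESTED_INNER
    ][: params.n_nested_distractors]
    if len(nested_ids) < params.n_nested_distractors:
        raise ValueError("reference carries fewer nested distractors than requested")
    special = set(intra_ids + inter_ids + flank_ids + dup_ids + nested_ids)

    # --- background indels (never inside TEs by default)
    ops: list[_Op] = []
    center_indel_rate = (
        params.indel_rate * params.center_snp_rate / params.arm_snp_rate
        if params.arm_snp_rate > 0
        else 0.0
    )
    indel_spans = _Blocked()
    for chrom in names:
        clen = len(reference.chromosomes[chrom])
        positions = _sample_domain_positions(
            rng, clen, params.arm_fraction, params.indel_rate, center_indel_rate
        )
        for p in positions:
            p = int(p)
            length = int(rng.integers(1, params.indel_max_len + 1))
            is_del = bool(rng.random() < 0.5)
            span_end = p + length if is_del else p
            if p < margin or span_end > clen - margin:
                continue
            if not params.allow_te_indels and blocked.hits(chrom, p - 1, span_end + 1):
                continue
            if indel_spans.hits(chrom, p - 20, span_end + 20):
                continue
            if is_del:
                ops.append(_Op(chrom, p, length, "", "indel_del"))
            else:
                ops.append(_Op(chrom, p, 0, _random_seq(rng, length), "indel_ins"))
            indel_spans.add(chrom, p - 1, span_end + 1)

    # --- background SNPs
    snps: dict[str, dict[int, tuple[str, str]]] = {n: {} for n in names}
    for chrom in names:
        clen = len(reference.chromosomes[chrom])
        seq = reference.chromosomes[chrom]
        positions = _sample_domain_positions(
            rng, clen, params.arm_fraction, params.arm_snp_rate, params.center_snp_rate
        )
        for p in positions:
            p = int(p)
            if indel_spans.hits(chrom, p, p + 1):
                continue
            ref_base = seq[p]
            if ref_base == "N":
                continue
            alt = "ACGT"[("ACGT".index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
            snps[chrom][p] = (ref_base, alt)

    # --- forced fingerprint SNPs for every moved/distractor TE
    for te_id in sorted(special):
        te = te_by_id[te_id]
        has_snp = any(te.start <= p < te.end for p in snps[te.chrom])
        if not has_snp:
            p = te.start + int(rng.integers(5, te.length - 5))
            seq = reference.chromosomes[te.chrom]
            ref_base = seq[p]
            alt = "ACGT"[("ACGT".index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
            snps[te.chrom][p] = (ref_base, alt)

    def te_query_seq(te: TECopy) -> str:
        chars = list(te.sequence)
        for p, (ref_base, alt) in snps[te.chrom].items():
            if te.start <= p < te.end:
                chars[p - te.start] = alt
        return "".join(chars)

    def snp_applied(chrom: str, start: int, end: int) -> str:
        chars = list(reference.fetch(chrom, start, end))
        for p, (_, alt) in snps[chrom].items():
            if start <= p < end:
                chars[p - start] = alt
        return "".join(chars)

    # --- movements
    movements_raw: list[tuple[str, str, _Op, _Op | None, int]] = []
    # (te_id, kind, ins_op, del_op, insert_offset)

    def sample_destination(te: TECopy, same_chrom: bool) -> tuple[str, int]:
        lo, hi = params.intra_distance_range
        for _attempt in range(500):
            if same_chrom:
                chrom = te.chrom
                d = int(rng.integers(lo, hi + 1))
                dest = te.start + (d if rng.random() < 0.5 else -d)
            else:
                others = [n for n in names if n != te.chrom]
                chrom = others[int(rng.integers(0, len(others)))]
                clen = len(reference.chromosomes[chrom])
                dest = int(rng.integers(margin, clen - margin))
            clen = len(reference.chromosomes[chrom])
            if not margin <= dest <= clen - margin:
                continue
            if blocked.hits(chrom, dest - pad, dest + pad):
                continue
            if indel_spans.hits(chrom, dest - 2, dest + 2):
                continue
            return chrom, dest
        raise RuntimeError(f"no destination found for {te.te_id}")

    def plant(te_id: str, kind: str) -> None:
        te = te_by_id[te_id]
        qseq = te_query_seq(te)
        same_chrom = kind in (INTRA_MOVE, FLANK_DISTRACTOR, NESTED_DISTRACTOR, DUPLICATION)
        chrom, dest = sample_destination(te, same_chrom)
        offset = 0
        if kind == FLANK_DISTRACTOR:
            up = snp_applied(te.chrom, te.start - params.flank_pad, te.start)
            down = snp_applied(te.chrom, te.end, te.end + params.flank_pad)
            ins = up + qseq + down
            offset = params.flank_pad
        else:
            ins = qseq
        ins_op = _Op(chrom, dest, 0, ins, f"{kind}:{te_id}")
        del_op = None
        if kind != DUPLICATION:
            del_op = _Op(te.chrom, te.start, te.length, "", f"excise:{te_id}")
        movements_raw.append((te_id, kind, ins_op, del_op, offset))
        ops.append(ins_op)
        if del_op is not None:
            ops.append(del_op)
        blocked.add(chrom, dest - pad, dest + pad)

    for te_id in intra_ids:
        plant(te_id, INTRA_MOVE)
    for te_id in inter_ids:
        plant(te_id, INTER_MOVE)
    for te_id in flank_ids:
        plant(te_id, FLANK_DISTRACTOR)
    for te_id in nested_ids:
        plant(te_id, NESTED_DISTRACTOR)
    for te_id in dup_ids:
        plant(te_id, DUPLICATION)

    # --- materialize query chromosomes
    query_chroms: dict[str, str] = {}
    for chrom in names:
        chrom_ops = sorted((op for op in ops if op.chrom == chrom), key=lambda o: o.pos)
        for a, b in zip(chrom_ops, chrom_ops[1:]):
            if a.pos + a.del_len > b.pos:
                raise RuntimeError("internal error: overlapping edit operations")
        base = snp_applied(chrom, 0, len(reference.chromosomes[chrom]))
        parts = []
        cur = 0
        delta = 0
        for op in chrom_ops:
            parts.append(base[cur : op.pos])
            op.q_start = op.pos + delta
            parts.append(op.ins_seq)
            delta += len(op.ins_seq) - op.del_len
            cur = op.pos + op.del_len
        parts.append(base[cur:])
        query_chroms[chrom] = "".join(parts)
    query = GenomeAssembly(query_chroms)
    emap = _EditMap(ops)

    # --- query TE annotations
    moved_ids = {te_id for te_id, kind, *_ in movements_raw if kind != DUPLICATION}
    query_tes: list[TECopy] = []
    for te in ref_tes:
        if te.te_id in moved_ids:
            continue
        qs = emap.map(te.chrom, te.start)
        qe = emap.map(te.chrom, te.end)
        query_tes.append(
            replace(te, start=qs, end=qe, sequence=query.fetch(te.chrom, qs, qe))
        )
    for te_id, kind, ins_op, _del_op, offset in movements_raw:
        te = te_by_id[te_id]
        qs = ins_op.q_start + offset
        qe = qs + te.length
        new_id = f"{te_id}_dup" if kind == DUPLICATION else te_id
        query_tes.append(
            replace(
                te,
                te_id=new_id,
                chrom=ins_op.chrom,
                start=qs,
                end=qe,
                sequence=query.fetch(ins_op.chrom, qs, qe),
            )
        )
    query_tes.sort(key=lambda t: (_chrom_sort_key(t.chrom), t.start, -t.length))

    # --- truth movements
    movements: list[PlantedMovement] = []
    for te_id, kind, ins_op, _del_op, offset in movements_raw:
        te = te_by_id[te_id]
        dest_q = ins_op.q_start + offset
        if kind in (INTRA_MOVE, FLANK_DISTRACTOR, NESTED_DISTRACTOR):
            distance = abs(dest_q - emap.map(te.chrom, te.start))
        else:
            distance = None
        movements.append(
            PlantedMovement(
                te_id=te_id,
                kind=kind,
                src_chrom=te.chrom,
                src_start=te.start,
                src_end=te.end,
                dest_chrom=ins_op.chrom,
                dest_ref_pos=ins_op.pos,
                dest_query_start=dest_q,
                distance=distance,
                insert_offset=offset,
            )
        )

    # --- VCF records
    records: list[VariantRecord] = []

    def depths() -> tuple[float, int, int]:
        qual = round(30 + float(rng.random()) * 30, 1)
        total = int(rng.integers(30, 80))
        alt = total - int(rng.integers(0, 3))
        return qual, alt, total

    for chrom in names:
        seq = reference.chromosomes[chrom]
        entries: list[tuple[int, str, str]] = []
        for p, (ref_base, alt) in snps[chrom].items():
            entries.append((p + 1, ref_base, alt))
        for op in ops:
            if op.chrom != chrom or not op.tag.startswith("indel"):
                continue
            anchor = seq[op.pos - 1]
            if op.del_len:
                entries.append((op.pos, seq[op.pos - 1 : op.pos + op.del_len], anchor))
            else:
                entries.append((op.pos, anchor, anchor + op.ins_seq))
        entries.sort(key=lambda t: t[0])
        for pos1, ref_allele, alt_allele in entries:
            qual, alt_depth, total = depths()
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos1,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    qual=qual,
                    alt_depth=alt_depth,
                    total_depth=total,
                    zygosity="hom",
                )
            )

    fingerprints = {
        te.te_id: sorted(
            (p - te.start, rb, ab)
            for p, (rb, ab) in snps[te.chrom].items()
            if te.start <= p < te.end
        )
        for te in ref_tes
    }
    truth = TruthTable(
        ref_tes=ref_tes,
        query_tes=query_tes,
        roles=ref_truth.roles,
        movements=movements,
        fingerprints={k: v for k, v in fingerprints.items() if v},
    )
    return query, query_tes, records, truth


# ---------------------------------------------------------------------------
# one-call interface and writers


@dataclass
class SimulationResult:
    params: SimulationParams
    family_specs: tuple[TEFamilySpec, ...]
    reference: GenomeAssembly
    ref_tes: list[TECopy]
    query: GenomeAssembly
    query_tes: list[TECopy]
    variants: list[VariantRecord]
    truth: TruthTable

    def save(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref_fa": outdir / "ref.fa",
            "query_fa": outdir / "query.fa",
            "ref_te": outdir / "ref_te.gff3",
            "query_te": outdir / "query_te.gff3",
            "vcf": outdir / "variants.vcf",
            "truth_movements": outdir / "truth_movements.tsv",
            "truth_te": outdir / "truth_te.tsv",
        }
        write_fasta(self.reference, paths["ref_fa"])
        write_fasta(self.query, paths["query_fa"])
        write_gff_te(self.ref_tes, paths["ref_te"])
        write_gff_te(self.query_tes, paths["query_te"])
        write_vcf(self.variants, self.reference.lengths, paths["vcf"])
        with open(paths["truth_movements"], "w") as fh:
            fh.write(
                "te_id\tkind\tsrc_chrom\tsrc_start\tsrc_end\tdest_chrom\t"
                "dest_ref_pos\tdest_query_start\tdistance\tinsert_offset\n"
            )
            for m in self.truth.movements:
                dist = "." if m.distance is None else str(m.distance)
                fh.write(
                    f"{m.te_id}\t{m.kind}\t{m.src_chrom}\t{m.src_start}\t"
                    f"{m.src_end}\t{m.dest_chrom}\t{m.dest_ref_pos}\t"
                    f"{m.dest_query_start}\t{dist}\t{m.insert_offset}\n"
                )
        with open(paths["truth_te"], "w") as fh:
            fh.write("te_id\tchrom\tstart\tend\tfamily\tte_class\trole\tn_fingerprint_snps\n")
            for te in self.ref_tes:
                nfp = len(self.truth.fingerprints.get(te.te_id, ()))
                fh.write(
                    f"{te.te_id}\t{te.chrom}\t{te.start}\t{te.end}\t{te.family}\t"
                    f"{te.te_class}\t{self.truth.roles[te.te_id]}\t{nfp}\n"
                )
        return paths


def simulate(
    params: SimulationParams | None = None,
    family_specs: tuple[TEFamilySpec, ...] = DEFAULT_FAMILIES,
) -> SimulationResult:
    """Generate a reference/query pair with planted movements and truth."""
    if params is None:
        params = SimulationParams()
    library = make_te_library(family_specs, params.rng_seed)
    reference, ref_tes, ref_truth = simulate_reference(params, library, family_specs)
    query, query_tes, variants, truth = derive_query(
        reference, ref_tes, ref_truth, params
    )
    return SimulationResult(
        params=params,
        family_specs=family_specs,
        reference=reference,
        ref_tes=ref_tes,
        query=query,
        query_tes=query_tes,
        variants=variants,
        truth=truth,
    )
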