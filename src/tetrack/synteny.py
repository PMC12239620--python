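"""Collinear-block synteny map between two assemblies and coordinate lift.

Anchors are k-mers that occur exactly once in each genome counting both
strands (MUM-style).  Anchors sharing a chromosome pair, relative
orientation and alignment diagonal are chained into collinear blocks, so
within any block the base-level mapping between the genomes is an exact
offset (forward) or reflection (reverse).  Chains are broken at anchor gaps
larger than `max_gap`.  Passing the repeat annotation as `mask` drops
blocks confined to a single annotated repeat — without it, a relocated
repeat's own unique k-mers would form a short block at its destination and
the lift would follow the moved element instead of the collinear backbone.

For strain pairs of low divergence this anchoring is adequate and trivially
auditable; a PAF from an external whole-genome aligner can be imported into
the identical block type instead.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np

from .io import GenomeAssembly, PafRow

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class SyntenyBlock:
    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    orientation: str  # forward | reverse

    def __post_init__(self):
        if self.ref_end <= self.ref_start or self.query_end <= self.query_start:
            raise ValueError("degenerate synteny block")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class LiftResult:
    query_chrom: str
    pos: int
    orientation: str
    interpolated: bool


class SyntenyMap:
    """Blocks sorted by (ref_chrom, ref_start), binary-searchable by
    reference coordinate; no two blocks contain the same reference base."""

    def __init__(self, blocks: list[SyntenyBlock], stats: dict | None = None):
        blocks = _resolve_ref_overlaps(blocks)
        self.blocks = sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start))
        self.stats = stats or {}
        self._by_chrom: dict[str, list[SyntenyBlock]] = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.ref_chrom, []).append(b)
        self._starts = {
            c: [b.ref_start for b in bl] for c, bl in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.blocks)

    def lift(self, ref_chrom: str, ref_pos: int) -> LiftResult | None:
        """Alignment-expected query coordinate of a reference position.

        Inside a block the lift is exact.  Between (or beyond) blocks of a
        chromosome the preceding block's frame is extended forward and the
        result flagged `interpolated`: any structural difference at or
        after the queried position (for example the excision of the element
        starting there) does not perturb the upstream frame, whereas the
        following block's frame would be shifted by it.  The following
        block is used only when no preceding block exists.  Returns None
        (unplaced) when the reference chromosome has no blocks at all.
        """
        chrom_blocks = self._by_chrom.get(ref_chrom)
        if not chrom_blocks:
            return None
        starts = self._starts[ref_chrom]
        idx = bisect.bisect_right(starts, ref_pos) - 1
        if idx >= 0:
            b = chrom_blocks[idx]
            if ref_pos < b.ref_end:
                return LiftResult(
                    b.query_chrom, _in_block(b, ref_pos), b.orientation, False
                )
        else:
            b = chrom_blocks[0]  # before the first block: extend it backward
        return LiftResult(b.query_chrom, _in_block(b, ref_pos), b.orientation, True)


def _in_block(b: SyntenyBlock, ref_pos: int) -> int:
    if b.orientation == FORWARD:
        return b.query_start + (ref_pos - b.ref_start)
    return b.query_end - 1 - (ref_pos - b.ref_start)


def _trim_block(b: SyntenyBlock, s: int, e: int) -> SyntenyBlock | None:
    """Restrict a block to the reference span [s, e), shifting the query
    span by the same amounts (exact: blocks are constant-diagonal)."""
    s, e = max(s, b.ref_start), min(e, b.ref_end)
    if e <= s:
        return None
    d1, d2 = s - b.ref_start, b.ref_end - e
    if not d1 and not d2:
        return b
    if b.orientation == FORWARD:
        qs, qe = b.query_start + d1, b.query_end - d2
    else:
        qs, qe = b.query_start + d2, b.query_end - d1
    return SyntenyBlock(b.ref_chrom, s, e, b.query_chrom, qs, qe, b.orientation)


def _resolve_ref_overlaps(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Make blocks non-overlapping on the reference axis.

    A block strictly containing another is split around it: the contained
    block is direct local evidence for its own span, whereas the container
    merely chained across a gap (offsets that cancel — a deletion followed
    by an equal-sized insertion — can return a chain to an earlier
    diagonal, spanning foreign territory).  Remaining partial overlaps are
    resolved by trimming the shorter block; junction-crossing
    pseudo-anchors can extend a block a few bases past a true breakpoint.
    """
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    out: list[SyntenyBlock] = []
    for chrom_blocks in by_chrom.values():
        work = list(chrom_blocks)
        # phase 1: split strict containers around contained blocks
        changed = True
        while changed:
            changed = False
            for a in sorted(work, key=lambda b: -b.ref_span):
                inner = [
                    b
                    for b in work
                    if b is not a
                    and a.ref_start <= b.ref_start
                    and b.ref_end <= a.ref_end
                    and b.ref_span < a.ref_span
                ]
                if not inner:
                    continue
                hole_s = min(b.ref_start for b in inner)
                hole_e = max(b.ref_end for b in inner)
                work.remove(a)
                for piece in (
                    _trim_block(a, a.ref_start, hole_s),
                    _trim_block(a, hole_e, a.ref_end),
                ):
                    if piece is not None:
                        work.append(piece)
                changed = True
                break
        # phase 2: trim partial overlaps, longer block first
        kept: list[SyntenyBlock] = []
        for b in sorted(work, key=lambda b: -b.ref_span):
            s, e = b.ref_start, b.ref_end
            dead = False
            for o in kept:
                if e <= o.ref_start or o.ref_end <= s:
                    continue
                if o.ref_start <= s and e <= o.ref_end:
                    dead = True
                    break
                if s < o.ref_start and o.ref_end < e:
                    dead = True  # kept block strictly inside; cannot split
                    break
                if o.ref_start <= s:
                    s = o.ref_end
                else:
                    e = o.ref_start
            if dead:
                continue
            trimmed = _trim_block(b, s, e)
            if trimmed is not None:
                kept.append(trimmed)
        out.extend(kept)
    return out


# ---------------------------------------------------------------------------
# k-mer anchoring

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i


def _kmer_codes(seq: str, k: int):
    """Canonical k-mer codes, with the strand of the canonical form.

    Returns (codes uint64, fwd_is_canonical bool) for every window, with
    code == 2**63 marking windows containing N.
    """
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = arr.size - k + 1
    if n <= 0:
        return (np.empty(0, np.uint64), np.empty(0, bool))
    valid_base = arr < 4
    ok = np.ones(n, dtype=bool)
    # window is valid iff all k bases valid
    cnt = np.cumsum(np.concatenate(([0], valid_base.astype(np.int64))))
    ok = (cnt[k:] - cnt[:-k]) == k
    a = np.where(valid_base, arr, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | a[j : j + n]
        rev |= (np.uint64(3) - a[j : j + n]) << np.uint64(2 * j)
    fwd_is_canon = fwd <= rev
    canon = np.where(fwd_is_canon, fwd, rev)
    canon[~ok] = np.uint64(1) << np.uint64(63)
    return canon, fwd_is_canon


def _unique_kmer_table(assembly: GenomeAssembly, k: int):
    codes_all, chrom_all, pos_all, strand_all = [], [], [], []
    names = assembly.names
    for ci, name in enumerate(names):
        codes, fwd = _kmer_codes(assembly.chromosomes[name], k)
        codes_all.append(codes)
        chrom_all.append(np.full(codes.size, ci, dtype=np.int32))
        pos_all.append(np.arange(codes.size, dtype=np.int64))
        strand_all.append(fwd)
    codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.uint64)
    chrom = np.concatenate(chrom_all) if chrom_all else np.empty(0, np.int32)
    pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
    strand = np.concatenate(strand_all) if strand_all else np.empty(0, bool)
    sentinel = np.uint64(1) << np.uint64(63)
    keep = codes != sentinel
    codes, chrom, pos, strand = codes[keep], chrom[keep], pos[keep], strand[keep]
    ucodes, first_idx, counts = np.unique(codes, return_index=True, return_counts=True)
    single = counts == 1
    idx = first_idx[single]
    return ucodes[single], chrom[idx], pos[idx], strand[idx], names


def build_anchor_map(
    ref: GenomeAssembly,
    query: GenomeAssembly,
    k: int = 21,
    max_gap: int = 10_000,
    min_anchors: int = 5,
    min_block_span: int = 0,
    mask=None,
) -> SyntenyMap:
    """Anchor-based synteny map from k-mers unique in both genomes.

    k must be odd (a canonical k-mer is then never its own reverse
    complement).  Anchors are grouped by (ref chrom, query chrom,
    orientation, diagonal) and runs split at gaps > max_gap; runs of at
    least `min_anchors` anchors spanning at least `min_block_span` on the
    reference become blocks.  `mask` is an optional list of reference
    intervals (objects with chrom/start/end, e.g. the TE annotation): a
    block whose reference span falls entirely within one masked interval
    (expanded by k) is discarded, since such a block reflects the repeat
    copy itself rather than the collinear backbone.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    rcodes, rchrom, rpos, rstrand, rnames = _unique_kmer_table(ref, k)
    qcodes, qchrom, qpos, qstrand, qnames = _unique_kmer_table(query, k)
    common, ri, qi = np.intersect1d(rcodes, qcodes, return_indices=True)
    if common.size == 0:
        logger.warning("no unique shared k-mers; empty synteny map")
        return SyntenyMap([], {"n_anchors": 0})

    a_rchrom = rchrom[ri]
    a_rpos = rpos[ri]
    a_qchrom = qchrom[qi]
    a_qpos = qpos[qi]
    same_strand = rstrand[ri] == qstrand[qi]
    # diagonal key: q - r for forward pairs, q + r for reverse pairs
    diag = np.where(same_strand, a_qpos - a_rpos, a_qpos + a_rpos)

    # Anchors in reference order; a run is cut at ANY change of
    # (query chrom, orientation, diagonal) or at a gap > max_gap.  Cutting
    # on the globally sorted sequence means an anchor of a different
    # diagonal always interrupts a run, so a chain can never bridge
    # across territory that belongs to another diagonal (offsets that
    # cancel would otherwise let a chain span foreign ground).
    order = np.lexsort((a_rpos, a_rchrom))
    blocks: list[SyntenyBlock] = []
    group_key = np.stack(
        [same_strand[order].astype(np.int64), a_rchrom[order], a_qchrom[order], diag[order]],
        axis=1,
    )
    rp = a_rpos[order]
    boundaries = np.nonzero(
        np.any(group_key[1:] != group_key[:-1], axis=1) | (np.diff(rp) > max_gap)
    )[0]
    run_starts = np.concatenate(([0], boundaries + 1))
    run_ends = np.concatenate((boundaries + 1, [rp.size]))
    for s, e in zip(run_starts, run_ends):
        if e - s < min_anchors:
            continue
        fwd, rc, qc, d = group_key[s]
        r0, r1 = int(rp[s]), int(rp[e - 1])
        if r1 + k - r0 < min_block_span:
            continue
        if fwd:
            qs, qe = r0 + int(d), r1 + int(d) + k
            orient = FORWARD
        else:
            qs, qe = int(d) - r1, int(d) - r0 + k
            orient = REVERSE
        blocks.append(
            SyntenyBlock(
                ref_chrom=rnames[int(rc)],
                ref_start=r0,
                ref_end=r1 + k,
                query_chrom=qnames[int(qc)],
                query_start=qs,
                query_end=qe,
                orientation=orient,
            )
        )
    if mask:
        blocks = _drop_masked_blocks(blocks, mask, k)
    stats = {"n_anchors": int(common.size), "n_blocks": len(blocks)}
    return SyntenyMap(blocks, stats)


def _drop_masked_blocks(
    blocks: list[SyntenyBlock], mask, k: int
) -> list[SyntenyBlock]:
    """Discard blocks whose reference span lies entirely within one masked
    interval expanded by k (junction-crossing anchors reach at most k-1
    bases past a repeat boundary)."""
    merged: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in mask:
        by_chrom.setdefault(iv.chrom, []).append((iv.start - k, iv.end + k))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    kept = []
    for b in blocks:
        ivs = merged.get(b.ref_chrom, ())
        i = bisect.bisect_right([s for s, _ in ivs], b.ref_start) - 1
        contained = i >= 0 and ivs[i][1] >= b.ref_end
        if not contained:
            kept.append(b)
    return kept


def blocks_from_paf(paf_rows: list[PafRow], min_len: int = 1_000) -> SyntenyMap:
    """Synteny map from PAF rows (target = reference, query = query).

    Rows whose reference span is below `min_len` are dropped; reference
    overlaps are resolved by keeping the longer row.
    """
    rows = [r for r in paf_rows if r.target_end - r.target_start >= min_len]
    kept: list[PafRow] = []
    for row in sorted(rows, key=lambda r: -(r.target_end - r.target_start)):
        if any(
            row.target_name == o.target_name
            and row.target_start < o.target_end
            and o.target_start < row.target_end
            for o in kept
        ):
            continue
        kept.append(row)
    blocks = [
        SyntenyBlock(
            ref_chrom=row.target_name,
            ref_start=row.target_start,
            ref_end=row.target_end,
            query_chrom=row.query_name,
            query_start=row.query_start,
            query_end=row.query_end,
            orientation=FORWARD if row.strand == "+" else REVERSE,
        )
        for row in kept
    ]
    return SyntenyMap(blocks, {"n_paf_rows": len(paf_rows)})


def write_blocks_tsv(smap: SyntenyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref_chrom\tref_start\tref_end\tquery_chrom\tquery_start\t"
            "query_end\torientation\n"
        )
        for b in smap.blocks:
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.query_chrom}\t"
                f"{b.query_start}\t{b.query_end}\t{b.orientation}\n"
            )
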