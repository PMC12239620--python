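"""Classify each cross-referenced TE as unmoved, intrachromosomally moved,
interchromosomally moved, ambiguous, or excluded.

A matched TE is a movement candidate when its observed query start departs
from the alignment-expected start by more than `tolerance` (same
chromosome: intrachromosomal; different chromosome: interchromosomal).
Candidates are then screened: a copy nested inside a same-family TE is
excluded (movement within the enveloping element cannot be inferred), and a
candidate whose 50-bp flanks at the old and new loci are too similar
(identity >= 0.90 under asm5-style local alignment) is excluded as a likely
alignment artifact.  A projected sequence found at two query loci is
ambiguous between duplication and transposition and is reported as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .align import AlignParams, local_align
from .io import GenomeAssembly, TECopy
from .matching import MULTIPLE, NONE, TEMatch, UNIQUE
from .synteny import SyntenyMap

logger = logging.getLogger(__name__)

UNMOVED = "unmoved"
INTRA = "intra"
INTER = "inter"
AMBIGUOUS_DUPLICATION = "ambiguous_duplication"
EXCLUDED_NESTED = "excluded_nested"
EXCLUDED_FLANK = "excluded_flank"
UNPLACED = "unplaced"

VERDICTS = (
    UNMOVED,
    INTRA,
    INTER,
    AMBIGUOUS_DUPLICATION,
    EXCLUDED_NESTED,
    EXCLUDED_FLANK,
    UNPLACED,
)


@dataclass(frozen=True)
class FlankPair:
    """Up to 50 bp immediately upstream/downstream of a TE interval."""

    upstream: str
    downstream: str
    up_truncated: bool = False
    down_truncated: bool = False


@dataclass(frozen=True)
class MovementCall:
    ref_te_id: str
    query_te_ids: tuple[str, ...]
    verdict: str
    family: str = ""
    expected_chrom: str | None = None
    expected_pos: int | None = None
    observed_chrom: str | None = None
    observed_pos: int | None = None
    distance: int | None = None  # intra only
    identity_up: float | None = None
    identity_down: float | None = None
    note: str = ""

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def extract_flanks(
    genome: GenomeAssembly, te: TECopy, flank_len: int = 50
) -> FlankPair:
    """50-bp flanks, clipped (and flagged truncated) at chromosome ends."""
    length = len(genome.chromosomes[te.chrom])
    up_start = max(0, te.start - flank_len)
    down_end = min(length, te.end + flank_len)
    return FlankPair(
        upstream=genome.fetch(te.chrom, up_start, te.start),
        downstream=genome.fetch(te.chrom, te.end, down_end),
        up_truncated=te.start - up_start < flank_len,
        down_truncated=down_end - te.end < flank_len,
    )


def nested_exclusion(te: TECopy, all_tes_same_genome: list[TECopy]) -> bool:
    """True iff `te` is fully contained in a different same-family TE."""
    for other in all_tes_same_genome:
        if (
            other.te_id != te.te_id
            and other.chrom == te.chrom
            and other.family == te.family
            and other.start <= te.start
            and te.end <= other.end
            and (other.start, other.end) != (te.start, te.end)
        ):
            return True
    return False


def _flank_identity(a: str, b: str, params: AlignParams) -> float:
    if not a or not b:
        return 0.0
    return local_align(a, b, params).identity


def call_movements(
    matches: list[TEMatch],
    ref_tes: list[TECopy],
    query_tes: list[TECopy],
    synteny_map: SyntenyMap,
    ref_genome: GenomeAssembly,
    query_genome: GenomeAssembly,
    tolerance: int = 100,
    flank_identity_max: float = 0.90,
    align_params: AlignParams | None = None,
    flank_len: int = 50,
    flank_rule: str = "either",
    flank_filter_inter: bool = True,
) -> list[MovementCall]:
    """One verdict per cross-referenced TE.

    Steps per unique match: lift the reference start to its
    alignment-expected query coordinate; compare with the observed query
    start (|delta| <= tolerance: unmoved; larger on the same chromosome:
    intra candidate; different chromosome: inter candidate); exclude nested
    candidates; exclude candidates whose old/new flanks align at >=
    `flank_identity_max` identity.  Matches hitting two or more query loci
    are reported as ambiguous_duplication directly.

    flank_rule: 'either' rejects when either flank pair reaches the
    threshold; 'both' requires both; 'concat' aligns the concatenated
    flanks.  flank_filter_inter=False restricts the flank screen to the
    intrachromosomal candidate list.
    """
    if align_params is None:
        align_params = AlignParams()
    if flank_rule not in ("either", "both", "concat"):
        raise ValueError(f"unknown flank_rule {flank_rule!r}")
    ref_by_id = {te.te_id: te for te in ref_tes}
    query_by_id = {te.te_id: te for te in query_tes}
    ref_by_chrom: dict[str, list[TECopy]] = {}
    for te in ref_tes:
        ref_by_chrom.setdefault(te.chrom, []).append(te)
    query_by_chrom: dict[str, list[TECopy]] = {}
    for te in query_tes:
        query_by_chrom.setdefault(te.chrom, []).append(te)

    calls: list[MovementCall] = []
    for m in matches:
        if m.match_class == NONE:
            continue
        try:
            rte = ref_by_id[m.ref_te_id]
        except KeyError:
            raise KeyError(f"TE id {m.ref_te_id!r} absent from reference annotations")
        if m.match_class == MULTIPLE:
            calls.append(
                MovementCall(
                    ref_te_id=m.ref_te_id,
                    query_te_ids=m.query_te_ids,
                    verdict=AMBIGUOUS_DUPLICATION,
                    family=rte.family,
                    note="exact sequence found at multiple query loci",
                )
            )
            continue
        qid = m.query_te_ids[0]
        try:
            qte = query_by_id[qid]
        except KeyError:
            raise KeyError(f"TE id {qid!r} absent from query annotations")

        lifted = synteny_map.lift(rte.chrom, rte.start)
        if lifted is None:
            calls.append(
                MovementCall(
                    ref_te_id=m.ref_te_id,
                    query_te_ids=m.query_te_ids,
                    verdict=UNPLACED,
                    family=rte.family,
                    observed_chrom=qte.chrom,
                    observed_pos=qte.start,
                    note="reference start not liftable",
                )
            )
            continue

        common = dict(
            ref_te_id=m.ref_te_id,
            query_te_ids=m.query_te_ids,
            family=rte.family,
            expected_chrom=lifted.query_chrom,
            expected_pos=lifted.pos,
            observed_chrom=qte.chrom,
            observed_pos=qte.start,
        )
        if qte.chrom != lifted.query_chrom:
            candidate = INTER
            distance = None
        else:
            delta = abs(qte.start - lifted.pos)
            if delta <= tolerance:
                calls.append(MovementCall(verdict=UNMOVED, **common))
                continue
            candidate = INTRA
            distance = delta

        # nested exclusion on both genomes' annotations
        if nested_exclusion(rte, ref_by_chrom.get(rte.chrom, [])) or nested_exclusion(
            qte, query_by_chrom.get(qte.chrom, [])
        ):
            calls.append(
                MovementCall(
                    verdict=EXCLUDED_NESTED,
                    distance=distance,
                    note="nested in a same-family TE",
                    **common,
                )
            )
            continue

        # flank-similarity filter
        apply_flanks = candidate == INTRA or flank_filter_inter
        id_up = id_down = None
        if apply_flanks:
            rfl = extract_flanks(ref_genome, rte, flank_len)
            qfl = extract_flanks(query_genome, qte, flank_len)
            if flank_rule == "concat":
                ident = _flank_identity(
                    rfl.upstream + rfl.downstream,
                    qfl.upstream + qfl.downstream,
                    align_params,
                )
                id_up = id_down = ident
                too_similar = ident >= flank_identity_max
            else:
                id_up = _flank_identity(rfl.upstream, qfl.upstream, align_params)
                id_down = _flank_identity(rfl.downstream, qfl.downstream, align_params)
                if flank_rule == "either":
                    too_similar = max(id_up, id_down) >= flank_identity_max
                else:
                    too_similar = min(id_up, id_down) >= flank_identity_max
            if too_similar:
                calls.append(
                    MovementCall(
                        verdict=EXCLUDED_FLANK,
                        distance=distance,
                        identity_up=id_up,
                        identity_down=id_down,
                        note="old/new flanks too similar to evidence movement",
                        **common,
                    )
                )
                continue

        calls.append(
            MovementCall(
                verdict=candidate,
                distance=distance,
                identity_up=id_up,
                identity_down=id_down,
                **common,
            )
        )
    return calls


def summarize_by_family(calls: list[MovementCall]) -> pd.DataFrame:
    """Counts of inter/intra verdicts per TE family, with a Total row."""
    families = sorted({c.family for c in calls if c.family})
    rows = []
    for fam in families:
        fam_calls = [c for c in calls if c.family == fam]
        rows.append(
            {
                "family": fam,
                "inter": sum(c.verdict == INTER for c in fam_calls),
                "intra": sum(c.verdict == INTRA for c in fam_calls),
            }
        )
    df = pd.DataFrame(rows, columns=["family", "inter", "intra"])
    total = pd.DataFrame(
        [{"family": "Total", "inter": df["inter"].sum(), "intra": df["intra"].sum()}]
    )
    return pd.concat([df, total], ignore_index=True)


def write_movements_tsv(calls: list[MovementCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref_te_id\tquery_te_ids\tverdict\tfamily\texpected_chrom\t"
            "expected_pos\tobserved_chrom\tobserved_pos\tdistance\t"
            "identity_up\tidentity_down\tnote\n"
        )

        def fmt(x):
            return "." if x is None else (f"{x:.4f}" if isinstance(x, float) else str(x))

        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.ref_te_id,
                        ";".join(c.query_te_ids) or ".",
                        c.verdict,
                        c.family or ".",
                        fmt(c.expected_chrom),
                        fmt(c.expected_pos),
                        fmt(c.observed_chrom),
                        fmt(c.observed_pos),
                        fmt(c.distance),
                        fmt(c.identity_up),
                        fmt(c.identity_down),
                        c.note or ".",
                    ]
                )
                + "\n"
            )
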