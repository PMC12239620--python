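"""Readers/writers for the standard formats the pipeline touches.

Internal convention: every coordinate in memory is 0-based, half-open.
Conversion to/from 1-based conventions (VCF, GFF3) happens only here, at
the format boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class GenomeAssembly:
    """Named chromosome sequences; the coordinate frame for everything else.

    Chromosome order is preserved; sequences are uppercase A/C/G/T/N.
    """

    def __init__(self, chromosomes: dict[str, str]):
        chroms: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if name in chroms:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            if not set(seq) <= _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"non-DNA characters in {name!r}: {bad}")
            chroms[name] = seq
        self.chromosomes = chroms

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring of `chrom` over the half-open interval [start, end)."""
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start},{end}) outside {chrom} (len {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeAssembly)
            and self.chromosomes == other.chromosomes
        )


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele of a VCF record (multi-allelic sites are split)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    qual: float
    alt_depth: int | None
    total_depth: int | None
    zygosity: str  # "hom" | "het"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele")
        if (
            self.alt_depth is not None
            and self.total_depth is not None
            and self.alt_depth > self.total_depth
        ):
            raise ValueError("alt_depth exceeds total_depth")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def start(self) -> int:
        """0-based start of the affected reference span."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based exclusive end of the affected reference span."""
        return self.pos - 1 + len(self.ref_allele)


@dataclass(frozen=True)
class Interval:
    """BED-convention interval: 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TECopy:
    """One annotated transposon interval with its extracted sequence.

    `sequence` is the + strand of its assembly regardless of the annotated
    strand, so offsets into it are plain genome offsets.
    """

    te_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    sequence: str = ""

    def __post_init__(self):
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length disagrees with interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PafRow:
    """The 12 mandatory PAF columns."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    aln_len: int
    mapq: int


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeAssembly:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record: {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(records)


def write_fasta(assembly: GenomeAssembly, path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.chromosomes.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# VCF


def _zygosity_from_gt(gt, chrom, pos) -> str:
    if gt is None or all(a is None for a in gt):
        logger.warning("missing GT at %s:%d; treating as hom", chrom, pos)
        return "hom"
    alleles = [a for a in gt if a is not None]
    if len(set(alleles)) == 1 and alleles[0] != 0:
        return "hom"
    return "het"


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF 4.x file; multi-allelic sites split one record per ALT.

    Depths come from the first sample's AD/DP fields when present.
    """
    out: list[VariantRecord] = []
    save = pysam.set_verbosity(0)
    try:
        vf = pysam.VariantFile(str(path))
    finally:
        pysam.set_verbosity(save)
    with vf:
        for rec in vf:
            sample = rec.samples[0] if rec.samples else None
            gt = sample.get("GT") if sample is not None else None
            ad = sample.get("AD") if sample is not None else None
            dp = sample.get("DP") if sample is not None else None
            if dp is None and "DP" in rec.info:
                dp = rec.info["DP"]
            for ai, alt in enumerate(rec.alts or ()):
                alt_depth = None
                if ad is not None and len(ad) > ai + 1 and ad[ai + 1] is not None:
                    alt_depth = int(ad[ai + 1])
                zyg = "hom"
                if gt is not None:
                    called = [a for a in gt if a is not None]
                    if not called:
                        zyg = _zygosity_from_gt(None, rec.chrom, rec.pos)
                    elif all(a == ai + 1 for a in called):
                        zyg = "hom"
                    else:
                        zyg = "het"
                else:
                    zyg = _zygosity_from_gt(None, rec.chrom, rec.pos)
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=str(alt),
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        alt_depth=alt_depth,
                        total_depth=int(dp) if dp is not None else None,
                        zygosity=zyg,
                    )
                )
    return out


def write_vcf(records: list[VariantRecord], contig_lengths: dict[str, int], path) -> None:
    """Write records as a minimal single-sample VCF 4.2 with GT:AD:DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in records:
            gt = "1/1" if r.zygosity == "hom" else "0/1"
            total = r.total_depth if r.total_depth is not None else 0
            altd = r.alt_depth if r.alt_depth is not None else 0
            ad = f"{total - altd},{altd}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t"
                f"{r.qual:g}\t.\t.\tGT:AD:DP\t{gt}:{ad}:{total}\n"
            )


def filter_variants(
    records: list[VariantRecord],
    min_qual: float = 30.0,
    min_alt_depth: int = 10,
    min_total_depth: int = 30,
    hom_only: bool = True,
) -> list[VariantRecord]:
    """Retain variants with QUAL >= 30, >= 10 variant reads and >= 30 total
    high-quality reads (and, by default, homozygous calls only).

    Records missing depth annotations are rejected with a logged warning.
    Order-preserving and idempotent.
    """
    kept = []
    n_missing = 0
    for r in records:
        if r.alt_depth is None or r.total_depth is None:
            n_missing += 1
            continue
        if r.qual < min_qual:
            continue
        if r.alt_depth < min_alt_depth or r.total_depth < min_total_depth:
            continue
        if hom_only and r.zygosity != "hom":
            continue
        kept.append(r)
    if n_missing:
        logger.warning("%d variant records lacked depth annotations; dropped", n_missing)
    return kept


# ---------------------------------------------------------------------------
# BED / GFF3 / PAF


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            label = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(Interval(chrom, start, end, strand=strand, label=label))
    return out


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, val = item.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def read_gff_te(path, assembly: GenomeAssembly | None = None) -> list[TECopy]:
    """Read TE annotations from GFF3 (1-based inclusive -> half-open).

    Records carry `family=` and `te_class=` attributes; if an assembly is
    supplied the + strand sequence of each interval is extracted.
    """
    out = []
    counter = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, _, start1, end1, _, strand, _, attr_text = f[:9]
            attrs = _parse_gff_attributes(attr_text)
            counter += 1
            start, end = int(start1) - 1, int(end1)
            seq = assembly.fetch(chrom, start, end) if assembly is not None else ""
            out.append(
                TECopy(
                    te_id=attrs.get("ID", f"te_{counter}"),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else ".",
                    family=attrs.get("family", ""),
                    te_class=attrs.get("te_class", ""),
                    sequence=seq,
                )
            )
    return out


def write_gff_te(tes: list[TECopy], path, source: str = "tetrack") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for te in tes:
            fh.write(
                f"{te.chrom}\t{source}\ttransposable_element\t{te.start + 1}\t"
                f"{te.end}\t.\t{te.strand if te.strand in '+-' else '.'}\t.\t"
                f"ID={te.te_id};family={te.family};te_class={te.te_class}\n"
            )


def read_paf(path) -> list[PafRow]:
    """Read the 12 mandatory PAF columns; malformed rows are skipped."""
    out = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                n_bad += 1
                continue
            try:
                out.append(
                    PafRow(
                        query_name=f[0],
                        query_len=int(f[1]),
                        query_start=int(f[2]),
                        query_end=int(f[3]),
                        strand=f[4],
                        target_name=f[5],
                        target_len=int(f[6]),
                        target_start=int(f[7]),
                        target_end=int(f[8]),
                        n_match=int(f[9]),
                        aln_len=int(f[10]),
                        mapq=int(f[11]),
                    )
                )
            except ValueError:
                n_bad += 1
    if n_bad:
        logger.warning("skipped %d malformed PAF rows", n_bad)
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
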