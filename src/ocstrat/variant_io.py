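"""Readers and writers for somatic variant, SV and copy-number formats.

Small variants come in as VCF 4.x (PASS records only, multiallelics split),
structural variants as VCF-with-SVTYPE or a simple breakpoint TSV, and copy
number as a PURPLE-like segment TSV.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "INS", "TRA")
MAJOR_CN_TOL = 1e-6


class FileFormatError(ValueError):
    """Raised when an input file violates its documented format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def variant_class(ref: str, alt: str) -> str:
    """Derive the variant class {SNV, MNV, INS, DEL} from VCF-style alleles."""
    if ref == alt:
        raise ValueError(f"ref equals alt: {ref}")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "DEL" if len(ref) > len(alt) else "INS"


@dataclass(frozen=True, order=True)
class SomaticVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        variant_class(self.ref, self.alt)  # validates ref != alt

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    def minimal(self) -> tuple[int, str, str]:
        """Strip the shared prefix; return (pos of first changed base, ref, alt).

        For an anchored VCF indel like pos=10 ACG>A this yields (11, "CG", "")
        i.e. the deleted bases start at position 11.
        """
        pos, ref, alt = self.pos, self.ref, self.alt
        while ref and alt and ref[0] == alt[0]:
            pos += 1
            ref, alt = ref[1:], alt[1:]
        while ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        return pos, ref, alt


@dataclass(frozen=True)
class StructuralVariant:
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        inter = self.chrom1 != self.chrom2
        if inter != (self.svtype == "TRA"):
            raise ValueError("svtype TRA iff breakpoints on different chromosomes")
        if self.svtype != "TRA" and abs(self.pos2 - self.pos1) < 1:
            raise ValueError("non-TRA SV must span at least 1 bp")

    @property
    def span_bp(self) -> int | None:
        if self.svtype == "TRA":
            return None
        return abs(self.pos2 - self.pos1)


@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    total_cn: float
    major_cn: float

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if self.total_cn < 0 or self.major_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.major_cn > self.total_cn + MAJOR_CN_TOL:
            raise ValueError(
                f"major_cn {self.major_cn} exceeds total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    tumor_purity: float

    def __post_init__(self):
        if not 0.0 <= self.tumor_purity <= 1.0:
            raise ValueError(f"purity {self.tumor_purity} outside [0, 1]")


# ---------------------------------------------------------------------------
# Small variants (VCF)
# ---------------------------------------------------------------------------


def read_small_variants(path) -> list[SomaticVariant]:
    """Read PASS somatic small variants from a VCF, splitting multiallelics.

    Records whose FILTER is anything other than PASS (or '.') are dropped.
    Symbolic or breakend ALT alleles are skipped with a warning.  Exact
    duplicate variants after splitting are deduplicated with a warning.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FileFormatError(f"cannot parse VCF {path}: {exc}") from exc
    out: list[SomaticVariant] = []
    seen: set[tuple[str, int, str, str]] = set()
    contigs = set(vcf.header.contigs)
    missing_contigs: set[str] = set()
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if contigs and rec.chrom not in contigs:
                missing_contigs.add(rec.chrom)
            for alt in rec.alts or ():
                if alt is None or alt == "*" or alt.startswith("<") or any(
                    c in alt for c in "[]"
                ):
                    warnings.warn(
                        f"skipping symbolic ALT {alt!r} at {rec.chrom}:{rec.pos}"
                    )
                    continue
                key = (rec.chrom, rec.pos, rec.ref, alt)
                if key in seen:
                    warnings.warn(f"duplicate record {rec.chrom}:{rec.pos} {rec.ref}>{alt}")
                    continue
                seen.add(key)
                out.append(SomaticVariant(rec.chrom, rec.pos, rec.ref, alt))
    for chrom in sorted(missing_contigs):
        warnings.warn(f"contig {chrom} absent from VCF header; records kept")
    return out


VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
"""


def write_small_variants(variants, path, contig_lengths=None) -> None:
    """Write variants to a minimal VCF 4.2 with all records PASS."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(v.chrom for v in variants):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

SV_TSV_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "svtype"]


def read_sv(path, dialect: str = "tsv") -> list[StructuralVariant]:
    """Read SVs from a breakpoint TSV or a VCF with SVTYPE INFO tags.

    Unknown svtype strings are rejected with a warning and counted; the
    count is logged at the end of the read.
    """
    if dialect == "tsv":
        return _read_sv_tsv(path)
    if dialect == "vcf":
        return _read_sv_vcf(path)
    raise ValueError(f"unknown SV dialect {dialect!r}")


def _make_sv(chrom1, pos1, chrom2, pos2, svtype) -> StructuralVariant:
    # TRA is definitional: interchromosomal breakends are translocations
    # whatever the caller labelled them.
    if chrom1 != chrom2:
        svtype = "TRA"
    elif svtype == "TRA":
        raise ValueError("TRA with both breakpoints on one chromosome")
    return StructuralVariant(chrom1, int(pos1), chrom2, int(pos2), svtype)


def _read_sv_tsv(path) -> list[StructuralVariant]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FileFormatError(f"cannot parse SV TSV {path}: {exc}") from exc
    missing = [c for c in SV_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"SV TSV {path} missing columns {missing}")
    out, rejected = [], 0
    for row in df.itertuples(index=False):
        svtype = str(row.svtype).upper()
        if svtype == "BND":
            svtype = "TRA" if row.chrom1 != row.chrom2 else "INV"
        if svtype not in SV_TYPES:
            warnings.warn(f"rejecting SV with unknown svtype {row.svtype!r}")
            rejected += 1
            continue
        out.append(_make_sv(str(row.chrom1), row.pos1, str(row.chrom2), row.pos2, svtype))
    if rejected:
        log.warning("rejected %d SV records with unknown svtype", rejected)
    return out


def _parse_bnd_mate(alt: str) -> tuple[str, int] | None:
    for br in "[]":
        if br in alt:
            inner = alt.split(br)[1]
            chrom, _, pos = inner.partition(":")
            if pos:
                return chrom, int(pos)
    return None


def _read_sv_vcf(path) -> list[StructuralVariant]:
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FileFormatError(f"cannot parse SV VCF {path}: {exc}") from exc
    out, rejected = [], 0
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            svtype = str(rec.info.get("SVTYPE", "")).upper()
            if not svtype:
                raise FileFormatError(f"record {rec.chrom}:{rec.pos} lacks SVTYPE")
            chrom2, pos2 = rec.chrom, rec.stop
            if svtype == "BND":
                mate = _parse_bnd_mate(rec.alts[0]) if rec.alts else None
                if mate is None:
                    warnings.warn(f"unparseable BND ALT at {rec.chrom}:{rec.pos}")
                    rejected += 1
                    continue
                chrom2, pos2 = mate
                svtype = "TRA" if chrom2 != rec.chrom else "INV"
            elif "CHR2" in rec.info:
                chrom2 = str(rec.info["CHR2"])
            if svtype not in SV_TYPES:
                warnings.warn(f"rejecting SV with unknown svtype {svtype!r}")
                rejected += 1
                continue
            out.append(_make_sv(rec.chrom, rec.pos, chrom2, pos2, svtype))
    if rejected:
        log.warning("rejected %d SV records", rejected)
    return out


def write_sv(svs, path) -> None:
    df = pd.DataFrame(
        [(s.chrom1, s.pos1, s.chrom2, s.pos2, s.svtype) for s in svs],
        columns=SV_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------

CNA_COLUMNS = ["chrom", "start", "end", "total_cn", "major_cn"]


def read_cna(path) -> list[CopyNumberSegment]:
    """Read copy-number segments; sorted per chromosome, overlap rejected."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FileFormatError(f"cannot parse CNA TSV {path}: {exc}") from exc
    missing = [c for c in CNA_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"CNA TSV {path} missing columns {missing}")
    segments = [
        CopyNumberSegment(str(r.chrom), int(r.start), int(r.end), float(r.total_cn), float(r.major_cn))
        for r in df.itertuples(index=False)
    ]
    return validate_segments(segments)


def validate_segments(segments) -> list[CopyNumberSegment]:
    """Sort segments per chromosome and verify non-overlap."""
    out: list[CopyNumberSegment] = []
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: (s.start, s.end))
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise FileFormatError(
                    f"overlapping segments on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        out.extend(segs)
    return out


def write_cna(segments, path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.total_cn, s.major_cn) for s in segments],
        columns=CNA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata and purity filter
# ---------------------------------------------------------------------------


def read_samples(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(str(r.sample_id), str(r.patient_id), float(r.tumor_purity))
        for r in df.itertuples(index=False)
    ]


def write_samples(samples, path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.patient_id, s.tumor_purity) for s in samples],
        columns=["sample_id", "patient_id", "tumor_purity"],
    ).to_csv(path, sep="\t", index=False)


def filter_by_purity(samples, min_purity: float = 0.20) -> list[SampleMeta]:
    """Keep samples with tumor purity strictly above ``min_purity``."""
    if not 0.0 <= min_purity <= 1.0:
        raise ValueError("min_purity must be in [0, 1]")
    return [s for s in samples if s.tumor_purity > min_purity]


def read_fasta(path) -> "object":
    from .reference import ReferenceGenome

    return ReferenceGenome.from_fasta(path)
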