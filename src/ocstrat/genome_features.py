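"""Per-sample genomic feature extraction.

Converts somatic events into the feature vectors used for signature
refitting and clustering: SBS-96 trinucleotide context counts, DBS-78
doublet counts, an ID-83-style indel category scheme, SV categories split
at 10 kb span, length-weighted ploidy fractions, whole-genome-duplication
status, and genome-wide tumor mutational burden (TMB).

Conventions
-----------
* SBS keys are pyrimidine-centred ("A[C>A]G"); purine-reference variants
  are reverse-complemented including flanks.
* DBS keys follow the COSMIC DBS-78 canonicalization (10 reference
  doublets; palindromic references take the lexicographically smaller of
  alt / revcomp(alt)).
* Indel keys use a SigProfiler-like text form, e.g. "1:Del:T:5" (1 bp T
  deletion in a 5-long homopolymer), "3:Del:M:2" (3 bp deletion with 2 bp
  flanking microhomology), "2:Ins:R:1" (2 bp insertion with one existing
  copy of the motif adjacent in the reference).  Size and count labels cap
  at the COSMIC bin edges; labels are documented in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ReferenceGenome, revcomp
from .variant_io import CopyNumberSegment, SomaticVariant, StructuralVariant

# Mappable (non-N) length of the GRCh37 reference, used as TMB denominator.
MAPPABLE_GENOME_BP = 2_858_674_662

SV_SPAN_SPLIT_BP = 10_000

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

SBS96_KEYS: list[str] = [
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5 in _FLANKS
    for f3 in _FLANKS
]

# The ten canonical DBS reference doublets of the COSMIC DBS-78 scheme.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DBS_PALINDROMIC = {"AT", "CG", "GC", "TA"}


def _dbs_alts(ref: str) -> list[str]:
    alts = [
        a + b
        for a in _FLANKS
        for b in _FLANKS
        if a != ref[0] and b != ref[1]
    ]
    if ref in _DBS_PALINDROMIC:
        alts = sorted({min(alt, revcomp(alt)) for alt in alts})
    return alts


DBS78_KEYS: list[str] = [
    f"{ref}>{alt}" for ref in DBS_CANONICAL_REFS for alt in _dbs_alts(ref)
]
assert len(DBS78_KEYS) == 78


def _id83_keys() -> list[str]:
    keys = []
    for base in "CT":
        keys += [f"1:Del:{base}:{h}" for h in (1, 2, 3, 4, 5, 6)]
    for base in "CT":
        keys += [f"1:Ins:{base}:{h}" for h in (0, 1, 2, 3, 4, 5)]
    for size in (2, 3, 4, 5):
        keys += [f"{size}:Del:R:{r}" for r in (1, 2, 3, 4, 5, 6)]
    for size in (2, 3, 4, 5):
        keys += [f"{size}:Ins:R:{r}" for r in (0, 1, 2, 3, 4, 5)]
    mh = {2: [1], 3: [1, 2], 4: [1, 2, 3], 5: [1, 2, 3, 4, 5]}
    for size, lens in mh.items():
        keys += [f"{size}:Del:M:{m}" for m in lens]
    return keys


ID83_KEYS: list[str] = _id83_keys()
assert len(ID83_KEYS) == 83

SV10_KEYS: list[str] = [
    f"{t}.{b}" for t in ("DEL", "DUP", "INV", "INS") for b in ("short", "long")
] + ["TRA"]

# Collapsed indel families used as clustering features (repeat-context
# insertions/deletions, microhomology deletions, and the rest).
INDEL_FAMILIES = (
    "ins_repeat",
    "ins_other",
    "del_repeat",
    "del_mh",
    "del_other",
)

_SBS_INDEX = {k: i for i, k in enumerate(SBS96_KEYS)}
_DBS_INDEX = {k: i for i, k in enumerate(DBS78_KEYS)}
_ID_INDEX = {k: i for i, k in enumerate(ID83_KEYS)}
_SV_INDEX = {k: i for i, k in enumerate(SV10_KEYS)}


def indel_family(key: str) -> str:
    """Collapse an ID-83 key into one of the five clustering families.

    Homopolymer-context 1 bp events count as repeat context; insertions
    with no adjacent copy and 1 bp events outside any run count as other.
    """
    size, kind, ctx, n = key.split(":")
    n = int(n)
    if kind == "Ins":
        if ctx == "R":
            return "ins_repeat" if n >= 1 else "ins_other"
        return "ins_repeat" if n >= 1 else "ins_other"
    if ctx == "M":
        return "del_mh"
    if ctx == "R":
        return "del_repeat" if n >= 2 else "del_other"
    return "del_repeat" if n >= 2 else "del_other"


# ---------------------------------------------------------------------------
# Context classification
# ---------------------------------------------------------------------------


def classify_sbs_context(v: SomaticVariant, ref_genome: ReferenceGenome) -> str | None:
    """SBS-96 key for an SNV, or None when a flank is missing or ambiguous."""
    if v.vclass != "SNV":
        raise ValueError("classify_sbs_context requires an SNV")
    f5 = ref_genome.base(v.chrom, v.pos - 1)
    f3 = ref_genome.base(v.chrom, v.pos + 1)
    if f5 not in set(_FLANKS) or f3 not in set(_FLANKS):
        return None
    ref, alt = v.ref, v.alt
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref, alt = revcomp(ref), revcomp(alt)
        f5, f3 = revcomp(f3), revcomp(f5)
    return f"{f5}[{ref}>{alt}]{f3}"


def classify_dbs(v: SomaticVariant) -> str:
    """COSMIC DBS-78 key for a length-2 MNV."""
    if v.vclass != "MNV" or len(v.ref) != 2:
        raise ValueError("classify_dbs requires a doublet substitution")
    ref, alt = v.ref.upper(), v.alt.upper()
    if ref not in DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if ref in _DBS_PALINDROMIC:
        alt = min(alt, revcomp(alt))
    key = f"{ref}>{alt}"
    if key not in _DBS_INDEX:
        raise ValueError(f"not a doublet substitution: {v.ref}>{v.alt}")
    return key


def _run_length(ref: ReferenceGenome, chrom: str, pos: int, base: str,
                exclude: tuple[int, int] | None = None) -> int:
    """Length of the homopolymer of ``base`` through ``pos`` (1-based)."""
    n = 0
    p = pos
    while ref.base(chrom, p) == base:
        n += 1
        p -= 1
    p = pos + 1
    while ref.base(chrom, p) == base:
        n += 1
        p += 1
    return n


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel(v: SomaticVariant, ref_genome: ReferenceGenome) -> str:
    """ID-83-style key for a left-aligned insertion or deletion.

    Repeat copies and microhomology lengths are found by direct scanning of
    the reference around the event.  Events at contig edges where flanks
    are unavailable fall back to the non-repeat bins.
    """
    if v.vclass not in ("INS", "DEL"):
        raise ValueError("classify_indel requires an insertion or deletion")
    pos, dref, dalt = v.minimal()
    chrom = v.chrom
    if v.vclass == "DEL":
        seq = dref
        size = len(seq)
        if size == 1:
            base = seq
            if base in "AG":
                base = revcomp(base)
            h = min(_run_length(ref_genome, chrom, pos, seq), 6)
            return f"1:Del:{base}:{max(h, 1)}"
        size_lab = min(size, 5)
        # count tandem copies of the deleted motif (including itself)
        copies = 1
        p = pos + size
        while ref_genome.slice(chrom, p, p + size - 1) == seq:
            copies += 1
            p += size
        p = pos - size
        while p >= 1 and ref_genome.slice(chrom, p, p + size - 1) == seq:
            copies += 1
            p -= size
        if copies >= 2:
            return f"{size_lab}:Del:R:{min(copies, 6)}"
        right = ref_genome.slice(chrom, pos + size, pos + 2 * size - 2)
        left = ref_genome.slice(chrom, max(pos - size + 1, 1), pos - 1)
        mh = max(_lcp(seq, right), _lcp(seq[::-1], left[::-1]))
        mh = min(mh, size - 1)
        if mh >= 1:
            mh_cap = {2: 1, 3: 2, 4: 3, 5: 5}[size_lab]
            return f"{size_lab}:Del:M:{min(mh, mh_cap)}"
        return f"{size_lab}:Del:R:1"
    # insertion: inserted bases sit between pos-1 and pos
    seq = dalt
    size = len(seq)
    if size == 1:
        base = seq
        if base in "AG":
            base = revcomp(base)
        h = 0
        p = pos
        while ref_genome.base(chrom, p) == seq:
            h += 1
            p += 1
        p = pos - 1
        while p >= 1 and ref_genome.base(chrom, p) == seq:
            h += 1
            p -= 1
        return f"1:Ins:{base}:{min(h, 5)}"
    size_lab = min(size, 5)
    copies = 0
    p = pos
    while ref_genome.slice(chrom, p, p + size - 1) == seq:
        copies += 1
        p += size
    p = pos - size
    while p >= 1 and ref_genome.slice(chrom, p, p + size - 1) == seq:
        copies += 1
        p -= size
    return f"{size_lab}:Ins:R:{min(copies, 5)}"


def categorize_sv(sv: StructuralVariant) -> str:
    """SV category key: svtype x {short, long} at 10 kb, TRA unsplit."""
    if sv.svtype == "TRA":
        return "TRA"
    bucket = "short" if sv.span_bp < SV_SPAN_SPLIT_BP else "long"
    return f"{sv.svtype}.{bucket}"


# ---------------------------------------------------------------------------
# ContextCounts
# ---------------------------------------------------------------------------


@dataclass
class ContextCounts:
    """Per-sample context count vectors plus totals."""

    sbs96: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    dbs: np.ndarray = field(default_factory=lambda: np.zeros(78, dtype=np.int64))
    indel: np.ndarray = field(default_factory=lambda: np.zeros(83, dtype=np.int64))
    sv10: np.ndarray = field(default_factory=lambda: np.zeros(9, dtype=np.int64))
    total_snv_mnv_indel: int = 0
    total_sv: int = 0

    def snv6(self) -> np.ndarray:
        """Counts per substitution class (C>A ... T>G)."""
        return self.sbs96.reshape(6, 16).sum(axis=1)

    def dbs_total(self) -> int:
        return int(self.dbs.sum())

    def indel_total(self) -> int:
        return int(self.indel.sum())

    def indel_families(self) -> np.ndarray:
        out = np.zeros(len(INDEL_FAMILIES), dtype=np.int64)
        fam_idx = {f: i for i, f in enumerate(INDEL_FAMILIES)}
        for key, count in zip(ID83_KEYS, self.indel):
            out[fam_idx[indel_family(key)]] += count
        return out

    def mh_deletions(self) -> int:
        return int(
            sum(c for k, c in zip(ID83_KEYS, self.indel) if ":Del:M:" in k)
        )

    def as_series(self) -> pd.Series:
        keys = SBS96_KEYS + DBS78_KEYS + ID83_KEYS + SV10_KEYS
        vals = np.concatenate([self.sbs96, self.dbs, self.indel, self.sv10])
        return pd.Series(vals, index=keys)


def count_contexts(
    variants: list[SomaticVariant],
    svs: list[StructuralVariant],
    ref_genome: ReferenceGenome,
) -> ContextCounts:
    """Count all mutation contexts for one sample.

    SNVs with unclassifiable flanks stay in the TMB totals but are excluded
    from the SBS-96 vector (a warning is emitted).  MNVs longer than 2 bp
    count toward totals but not toward DBS-78.
    """
    cc = ContextCounts()
    skipped_flank = 0
    for v in variants:
        cc.total_snv_mnv_indel += 1
        vclass = v.vclass
        if vclass == "SNV":
            key = classify_sbs_context(v, ref_genome)
            if key is None:
                skipped_flank += 1
                continue
            cc.sbs96[_SBS_INDEX[key]] += 1
        elif vclass == "MNV":
            if len(v.ref) == 2:
                cc.dbs[_DBS_INDEX[classify_dbs(v)]] += 1
        else:
            cc.indel[_ID_INDEX[classify_indel(v, ref_genome)]] += 1
    for sv in svs:
        cc.sv10[_SV_INDEX[categorize_sv(sv)]] += 1
        cc.total_sv += 1
    if skipped_flank:
        warnings.warn(
            f"{skipped_flank} SNVs excluded from SBS-96 (flank missing or N)"
        )
    return cc


# ---------------------------------------------------------------------------
# Ploidy, WGD, TMB
# ---------------------------------------------------------------------------

DIPLOID_LOW, DIPLOID_HIGH = 1.5, 2.5
WGD_MAJOR_PLOIDY = 1.5
WGD_MIN_AUTOSOMES = 10


@dataclass(frozen=True)
class PloidyProfile:
    frac_haploid: float
    frac_diploid: float
    frac_polyploid: float
    mean_ploidy: float
    wgd: bool

    def __post_init__(self):
        total = self.frac_haploid + self.frac_diploid + self.frac_polyploid
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ploidy fractions sum to {total}, not 1")
        if self.mean_ploidy <= 0:
            raise ValueError("mean ploidy must be positive")


def ploidy_fractions(
    segments: list[CopyNumberSegment], wgd: bool = False
) -> PloidyProfile:
    """Length-weighted haploid/diploid/polyploid genome fractions.

    Diploid is the closed interval [1.5, 2.5]; below is haploid, above is
    polyploid.
    """
    if not segments:
        raise ValueError("ploidy_fractions requires at least one segment")
    lengths = np.array([s.length for s in segments], dtype=float)
    cn = np.array([s.total_cn for s in segments])
    total = lengths.sum()
    hap = lengths[cn < DIPLOID_LOW].sum() / total
    dip = lengths[(cn >= DIPLOID_LOW) & (cn <= DIPLOID_HIGH)].sum() / total
    poly = lengths[cn > DIPLOID_HIGH].sum() / total
    # remove float drift so the invariant holds exactly
    dip = 1.0 - hap - poly
    mean_ploidy = float((lengths * cn).sum() / total)
    return PloidyProfile(float(hap), float(dip), float(poly), mean_ploidy, wgd)


def call_wgd(
    segments: list[CopyNumberSegment], autosome_names: list[str] | None = None
) -> bool:
    """Whole-genome duplication call.

    A sample is WGD when the length-weighted mean major-allele ploidy
    exceeds 1.5 in more than 10 autosomes.
    """
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    if autosome_names is None:
        autosome_names = list(by_chrom)
    n_above = 0
    for chrom in autosome_names:
        segs = by_chrom.get(chrom)
        if not segs:
            continue
        lengths = np.array([s.length for s in segs], dtype=float)
        major = np.array([s.major_cn for s in segs])
        if (lengths * major).sum() / lengths.sum() > WGD_MAJOR_PLOIDY:
            n_above += 1
    return n_above > WGD_MIN_AUTOSOMES


@dataclass(frozen=True)
class TmbValue:
    tmb: float
    denominator_bp: int = MAPPABLE_GENOME_BP

    def __post_init__(self):
        if self.tmb < 0:
            raise ValueError("TMB must be non-negative")


def compute_tmb(total_mutations: int) -> TmbValue:
    """Genome-wide mutations (SNV + MNV + indel) per mappable megabase."""
    if total_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    return TmbValue(total_mutations / (MAPPABLE_GENOME_BP / 1e6))


def context_table(counts_by_sample: dict[str, ContextCounts]) -> pd.DataFrame:
    """One row per sample, columns = all context keys (TSV-ready)."""
    return pd.DataFrame(
        {sid: cc.as_series() for sid, cc in counts_by_sample.items()}
    ).T
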