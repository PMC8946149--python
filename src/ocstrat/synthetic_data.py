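"""Synthetic metastatic ovarian-cancer cohort generator.

Generates everything the analysis pipeline consumes — a 22-autosome toy
reference, per-sample small-variant/SV/copy-number calls, clinical records
and gene events — from seven archetypes that mirror the qualitative
contrasts the stratification is designed to detect:

* ``hrd_diploid``   — HR-deficient, near-diploid, microhomology-deletion
  and short-SV rich, NF1 events frequent, favorable response.
* ``hrd_wgd``       — HR-deficient after whole-genome duplication, short
  tandem duplications dominate the SV spectrum.
* ``genome_stable`` — few mutations and SVs, diploid, LGSC-enriched, poor
  response.
* ``long_dup``      — tandem-duplicator phenotype, duplication span mode
  around 231 kb, TP53 plus CCNE1-pathway events.
* ``mixed``         — intermediate everything.
* ``aging``         — clock-like signatures (CpG C>T and T>C) dominate.
* ``repeat_ctr``    — repeat-context indels and C>T load, KRAS/TP53
  mutually exclusive, worst survival.

Every stage of the pipeline can recover the corresponding generator knob
(statistical closure): context spectra refit to the generating signature
mixture, ploidy fractions and WGD to the archetype targets, the HRD proxy
to the archetype's HRD flag, and clustering to the archetype labels.
Identical (config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, Treatment, write_clinical
from .genome_features import SBS96_KEYS, DBS78_KEYS, classify_indel
from .reference import ReferenceGenome, revcomp, toy_chrom_names, write_fasta
from .signatures import SignatureCatalog, packaged_catalog
from .actionability import GeneEvent, SampleEvents
from .variant_io import (
    CopyNumberSegment,
    SampleMeta,
    SomaticVariant,
    StructuralVariant,
    write_cna,
    write_samples,
    write_small_variants,
    write_sv,
)

BIOPSY_BASE_DATE = dt.date(2019, 6, 1)


# ---------------------------------------------------------------------------
# Archetype specification
# ---------------------------------------------------------------------------


@dataclass
class ClinicalModel:
    response_probs: dict[str, float]  # over CR/PR/SD/PD/NA
    death_rate_per_day: float  # exponential survival rate
    histology_weights: dict[str, float]
    primary_frac: float = 0.15

    def __post_init__(self):
        for probs in (self.response_probs, self.histology_weights):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities sum to {total}, not 1")


@dataclass
class ArchetypeSpec:
    name: str
    n_samples: int
    snv_load: tuple[float, float]  # negative binomial (mean, dispersion)
    dbs_load: tuple[float, float]
    indel_load: tuple[float, float]
    signature_mix: dict[str, float]  # SBS catalog weights
    dbs_mix: dict[str, float]
    indel_profile: dict[str, float]  # generator family weights
    sv_profile: dict[str, tuple[float, float | None, float | None]]
    # svtype -> (mean count, span mode bp, log-normal sigma); TRA span None
    ploidy_target: tuple[float, bool]  # (mean total CN, WGD flag)
    gene_events: dict[str, tuple[str, float]]  # gene -> (event type, prob)
    exclusive_pairs: list[tuple[str, str]] = field(default_factory=list)
    clinical_model: ClinicalModel | None = None
    hrd: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for mix in (self.signature_mix, self.dbs_mix, self.indel_profile):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: mixture weights sum to {total}, not 1"
                )


INDEL_GEN_FAMILIES = (
    "del_1bp",
    "ins_1bp",
    "del_rep",
    "ins_rep",
    "del_mh",
    "del_other",
)

_HRD_INDELS = {
    "del_mh": 0.45,
    "del_rep": 0.10,
    "del_1bp": 0.20,
    "ins_1bp": 0.10,
    "ins_rep": 0.10,
    "del_other": 0.05,
}
_QUIET_INDELS = {
    "del_mh": 0.03,
    "del_rep": 0.12,
    "del_1bp": 0.35,
    "ins_1bp": 0.33,
    "ins_rep": 0.12,
    "del_other": 0.05,
}
_REPEAT_INDELS = {
    "del_mh": 0.03,
    "del_rep": 0.25,
    "del_1bp": 0.28,
    "ins_1bp": 0.15,
    "ins_rep": 0.25,
    "del_other": 0.04,
}


def default_archetypes() -> list[ArchetypeSpec]:
    """The seven default archetypes (120 samples total)."""
    return [
        ArchetypeSpec(
            name="hrd_diploid",
            n_samples=17,
            snv_load=(8000, 12),
            dbs_load=(80, 8),
            indel_load=(1200, 10),
            signature_mix={"SBS3": 0.55, "SBS1": 0.10, "SBS5": 0.15, "SBS31": 0.10, "SBS35": 0.10},
            dbs_mix={"DBS5": 0.6, "DBS2": 0.2, "DBS4": 0.2},
            indel_profile=dict(_HRD_INDELS),
            sv_profile={
                "DEL": (120, 220, 0.6),
                "DUP": (40, 30_000, 0.6),
                "INV": (15, 50_000, 1.0),
                "INS": (10, 500, 0.5),
                "TRA": (15, None, None),
            },
            ploidy_target=(2.1, False),
            gene_events={
                "TP53": ("mutation", 0.95),
                "NF1": ("mutation", 0.53),
                "BRCA2": ("mutation", 0.40),
            },
            clinical_model=ClinicalModel(
                {"CR": 0.10, "PR": 0.40, "SD": 0.20, "PD": 0.10, "NA": 0.20},
                0.0004,
                {"HGSC": 0.85, "endometrioid": 0.05, "clear-cell": 0.05, "serous-NOS": 0.05},
            ),
            hrd=True,
        ),
        ArchetypeSpec(
            name="hrd_wgd",
            n_samples=25,
            snv_load=(9000, 12),
            dbs_load=(90, 8),
            indel_load=(1300, 10),
            signature_mix={"SBS3": 0.50, "SBS1": 0.10, "SBS5": 0.20, "SBS31": 0.20},
            dbs_mix={"DBS5": 0.6, "DBS2": 0.25, "DBS4": 0.15},
            indel_profile=dict(_HRD_INDELS),
            sv_profile={
                "DEL": (80, 250, 0.6),
                "DUP": (100, 30_000, 0.6),
                "INV": (15, 50_000, 1.0),
                "INS": (10, 500, 0.5),
                "TRA": (15, None, None),
            },
            ploidy_target=(3.6, True),
            gene_events={
                "TP53": ("mutation", 0.95),
                "BRCA1": ("mutation", 0.40),
                "NF1": ("mutation", 0.08),
            },
            clinical_model=ClinicalModel(
                {"CR": 0.08, "PR": 0.37, "SD": 0.25, "PD": 0.10, "NA": 0.20},
                0.0007,
                {"HGSC": 0.90, "clear-cell": 0.05, "serous-NOS": 0.05},
            ),
            hrd=True,
        ),
        ArchetypeSpec(
            name="genome_stable",
            n_samples=20,
            snv_load=(550, 40),
            dbs_load=(10, 5),
            indel_load=(150, 15),
            signature_mix={"SBS1": 0.30, "SBS5": 0.60, "SBS40": 0.10},
            dbs_mix={"DBS2": 0.5, "DBS4": 0.5},
            indel_profile=dict(_QUIET_INDELS),
            sv_profile={
                "DEL": (4, 20_000, 1.0),
                "DUP": (3, 200_000, 1.0),
                "INV": (2, 40_000, 1.0),
                "INS": (2, 800, 0.6),
                "TRA": (2, None, None),
            },
            ploidy_target=(2.0, False),
            gene_events={
                "KRAS": ("hotspot", 0.40),
                "PIK3CA": ("hotspot", 0.15),
                "TP53": ("mutation", 0.20),
            },
            clinical_model=ClinicalModel(
                {"CR": 0.02, "PR": 0.13, "SD": 0.45, "PD": 0.25, "NA": 0.15},
                0.0015,
                {"LGSC": 0.60, "HGSC": 0.25, "serous-NOS": 0.15},
            ),
        ),
        ArchetypeSpec(
            name="long_dup",
            n_samples=11,
            snv_load=(4500, 12),
            dbs_load=(50, 8),
            indel_load=(500, 10),
            signature_mix={"SBS1": 0.20, "SBS5": 0.30, "SBS31": 0.25, "SBS13": 0.25},
            dbs_mix={"DBS5": 0.4, "DBS7": 0.4, "DBS11": 0.2},
            indel_profile=dict(_QUIET_INDELS),
            sv_profile={
                "DEL": (30, 20_000, 1.0),
                "DUP": (120, 231_000, 0.5),
                "INV": (15, 60_000, 1.0),
                "INS": (5, 800, 0.6),
                "TRA": (15, None, None),
            },
            ploidy_target=(3.2, True),
            gene_events={
                "TP53": ("mutation", 0.91),
                "CCNE1": ("amplification", 0.27),
                "FBXW7": ("mutation", 0.10),
            },
            clinical_model=ClinicalModel(
                {"CR": 0.03, "PR": 0.22, "SD": 0.35, "PD": 0.20, "NA": 0.20},
                0.0012,
                {"HGSC": 0.90, "serous-NOS": 0.10},
            ),
        ),
        ArchetypeSpec(
            name="mixed",
            n_samples=15,
            snv_load=(4000, 12),
            dbs_load=(40, 8),
            indel_load=(500, 10),
            signature_mix={
                "SBS1": 0.15,
                "SBS5": 0.25,
                "SBS31": 0.15,
                "SBS35": 0.15,
                "SBS40": 0.15,
                "SBS13": 0.15,
            },
            dbs_mix={"DBS2": 0.3, "DBS5": 0.3, "DBS7": 0.2, "DBS11": 0.2},
            indel_profile=dict(_QUIET_INDELS),
            sv_profile={
                "DEL": (40, 15_000, 1.2),
                "DUP": (20, 300_000, 0.8),
                "INV": (30, 40_000, 1.0),
                "INS": (10, 1_000, 0.8),
                "TRA": (30, None, None),
            },
            ploidy_target=(3.0, True),
            gene_events={
                "TP53": ("mutation", 0.60),
                "PIK3CA": ("hotspot", 0.15),
                "KRAS": ("amplification", 0.10),
            },
            clinical_model=ClinicalModel(
                {"CR": 0.04, "PR": 0.26, "SD": 0.35, "PD": 0.15, "NA": 0.20},
                0.0012,
                {"HGSC": 0.60, "serous-NOS": 0.15, "adenocarcinoma-NOS": 0.10, "endometrioid": 0.15},
            ),
        ),
        ArchetypeSpec(
            name="aging",
            n_samples=14,
            snv_load=(3000, 12),
            dbs_load=(25, 6),
            indel_load=(400, 10),
            signature_mix={"SBS1": 0.45, "SBS5": 0.45, "SBS40": 0.10},
            dbs_mix={"DBS2": 0.6, "DBS4": 0.4},
            indel_profile=dict(_QUIET_INDELS),
            sv_profile={
                "DEL": (15, 8_000, 1.2),
                "DUP": (10, 150_000, 0.8),
                "INV": (8, 40_000, 1.0),
                "INS": (5, 800, 0.6),
                "TRA": (8, None, None),
            },
            ploidy_target=(2.2, False),
            gene_events={
                "TP53": ("mutation", 0.50),
                "NF1": ("mutation", 0.10),
            },
            clinical_model=ClinicalModel(
                {"CR": 0.03, "PR": 0.22, "SD": 0.38, "PD": 0.17, "NA": 0.20},
                0.0013,
                {"HGSC": 0.55, "serous-NOS": 0.20, "unknown": 0.10, "carcinosarcoma": 0.05, "mucinous": 0.10},
            ),
        ),
        ArchetypeSpec(
            name="repeat_ctr",
            n_samples=18,
            snv_load=(6000, 12),
            dbs_load=(30, 6),
            indel_load=(900, 10),
            signature_mix={"SBS44": 0.55, "SBS1": 0.20, "SBS5": 0.25},
            dbs_mix={"DBS4": 0.5, "DBS11": 0.5},
            indel_profile=dict(_REPEAT_INDELS),
            sv_profile={
                "DEL": (20, 5_000, 1.0),
                "DUP": (10, 150_000, 0.8),
                "INV": (10, 40_000, 1.0),
                "INS": (15, 800, 0.6),
                "TRA": (10, None, None),
            },
            ploidy_target=(2.4, False),
            gene_events={
                "TP53": ("mutation", 0.50),
                "KRAS": ("hotspot", 0.50),
                "PIK3CA": ("hotspot", 0.20),
                "NF1": ("mutation", 0.15),
            },
            exclusive_pairs=[("TP53", "KRAS")],
            clinical_model=ClinicalModel(
                {"CR": 0.02, "PR": 0.18, "SD": 0.40, "PD": 0.25, "NA": 0.15},
                0.0022,
                {"HGSC": 0.35, "LGSC": 0.15, "serous-NOS": 0.15, "endometrioid": 0.15, "mucinous": 0.10, "unknown": 0.10},
            ),
        ),
    ]


@dataclass
class CohortConfig:
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    n_chroms: int = 22
    chrom_length: int = 1_000_000
    seed: int = 0
    # the reference is a fixed quantity across cohorts, so it gets its own
    # seed; resimulating a cohort varies the samples, not the genome
    reference_seed: int = 0

    @property
    def total_samples(self) -> int:
        return sum(a.n_samples for a in self.archetypes)


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------


def simulate_reference(
    seed: int, n_chroms: int = 22, length: int = 1_000_000
) -> ReferenceGenome:
    """Uniform-random toy autosomes; deterministic per seed."""
    if length < 10_000:
        raise ValueError("contig length must be at least 10 kb")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EF]))
    seqs = {}
    for chrom in toy_chrom_names(n_chroms):
        codes = rng.integers(0, 4, size=length)
        seqs[chrom] = "".join(np.array(list("ACGT"))[codes])
    return ReferenceGenome(seqs)


from functools import lru_cache


@lru_cache(maxsize=4)
def _reference_bundle(seed: int, n_chroms: int, length: int):
    """Cached (reference, k-mer sampler) pair; indexes are expensive."""
    ref = simulate_reference(seed, n_chroms, length)
    return ref, _KmerSampler(ref)


class _KmerSampler:
    """Uniform position sampling among k-mer occurrences in a reference."""

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self._flat: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = {}

    def _get(self, kmer: str):
        if kmer not in self._flat:
            per_chrom = self.ref.kmer_positions(kmer)
            chroms = list(per_chrom)
            sizes = np.array([len(per_chrom[c]) for c in chroms], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(sizes)])
            self._flat[kmer] = (chroms, cum, per_chrom)
        return self._flat[kmer]

    def sample(self, kmer: str, n: int, rng) -> list[tuple[str, int]]:
        chroms, cum, per_chrom = self._get(kmer)
        total = int(cum[-1])
        if total == 0:
            raise ValueError(f"k-mer {kmer} absent from reference")
        idx = np.sort(rng.choice(total, size=min(n, total), replace=False))
        which = np.searchsorted(cum, idx, side="right") - 1
        return [
            (chroms[c], int(per_chrom[chroms[c]][i - cum[c]]))
            for c, i in zip(which, idx)
        ]


# ---------------------------------------------------------------------------
# Per-sample simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSample:
    meta: SampleMeta
    variants: list[SomaticVariant]
    svs: list[StructuralVariant]
    segments: list[CopyNumberSegment]
    clinical: ClinicalRecord
    events: SampleEvents
    truth: dict


def _mix_to_spectrum(mix: dict[str, float], catalog: SignatureCatalog) -> np.ndarray:
    p = np.zeros(len(catalog.context_keys))
    for name, w in mix.items():
        p += w * catalog.profiles[catalog.names.index(name)]
    return p / p.sum()


def _nbinom(rng, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _simulate_snvs(
    rng, n: int, mix, catalog, sampler: _KmerSampler
) -> list[SomaticVariant]:
    spectrum = _mix_to_spectrum(mix, catalog)
    counts = rng.multinomial(n, spectrum)
    variants = []
    for key, m in zip(SBS96_KEYS, counts):
        if m == 0:
            continue
        f5, ref_base, alt_base, f3 = key[0], key[2], key[4], key[6]
        trinuc = f5 + ref_base + f3
        n_rev = int(rng.binomial(m, 0.5))
        n_fwd = m - n_rev
        if n_fwd:
            for chrom, start in sampler.sample(trinuc, n_fwd, rng):
                variants.append(SomaticVariant(chrom, start + 1, ref_base, alt_base))
        if n_rev:
            rc = revcomp(trinuc)
            for chrom, start in sampler.sample(rc, n_rev, rng):
                variants.append(
                    SomaticVariant(chrom, start + 1, revcomp(ref_base), revcomp(alt_base))
                )
    return variants


def _simulate_dbs(rng, n: int, mix, catalog, sampler) -> list[SomaticVariant]:
    spectrum = _mix_to_spectrum(mix, catalog)
    counts = rng.multinomial(n, spectrum)
    variants = []
    for key, m in zip(DBS78_KEYS, counts):
        if m == 0:
            continue
        ref_d, alt_d = key.split(">")
        n_rev = int(rng.binomial(m, 0.5))
        for strand, cnt in (("+", m - n_rev), ("-", n_rev)):
            if cnt == 0:
                continue
            r = ref_d if strand == "+" else revcomp(ref_d)
            a = alt_d if strand == "+" else revcomp(alt_d)
            for chrom, start in sampler.sample(r, cnt, rng):
                variants.append(SomaticVariant(chrom, start, r, a))
    return variants


_MAX_PLACEMENT_TRIES = 1000


def _random_pos(rng, ref: ReferenceGenome) -> tuple[str, int]:
    chroms = ref.contigs
    lengths = np.array([ref.length(c) for c in chroms], dtype=float)
    c = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
    return c, int(rng.integers(20, ref.length(c) - 20))


def _anchored_del(ref: ReferenceGenome, chrom: str, pos: int, size: int) -> SomaticVariant:
    anchor = ref.base(chrom, pos - 1)
    deleted = ref.slice(chrom, pos, pos + size - 1)
    return SomaticVariant(chrom, pos - 1, anchor + deleted, anchor)


def _anchored_ins(ref: ReferenceGenome, chrom: str, pos: int, seq: str) -> SomaticVariant:
    anchor = ref.base(chrom, pos - 1)
    return SomaticVariant(chrom, pos - 1, anchor, anchor + seq)


def _simulate_indels(
    rng, n: int, profile: dict[str, float], ref: ReferenceGenome
) -> list[SomaticVariant]:
    """Indels constructed to literally realize their generator family.

    Each candidate event is verified with the production classifier
    (:func:`ocstrat.genome_features.classify_indel`) and resampled until
    it lands in the requested family, up to 1000 tries.
    """
    fams = list(profile)
    weights = np.array([profile[f] for f in fams])
    counts = rng.multinomial(n, weights / weights.sum())
    out = []
    for fam, m in zip(fams, counts):
        for _ in range(m):
            out.append(_place_indel(rng, fam, ref))
    return out


def _place_indel(rng, family: str, ref: ReferenceGenome) -> SomaticVariant:
    for _ in range(_MAX_PLACEMENT_TRIES):
        chrom, pos = _random_pos(rng, ref)
        if family == "del_1bp":
            v = _anchored_del(ref, chrom, pos, 1)
            return v
        if family == "ins_1bp":
            base = "ACGT"[rng.integers(0, 4)]
            return _anchored_ins(ref, chrom, pos, base)
        if family == "ins_rep":
            size = int(rng.integers(2, 4))
            seq = ref.slice(chrom, pos, pos + size - 1)
            return _anchored_ins(ref, chrom, pos, seq)
        if family == "del_rep":
            size = 2
            if ref.slice(chrom, pos, pos + size - 1) == ref.slice(
                chrom, pos + size, pos + 2 * size - 1
            ):
                return _anchored_del(ref, chrom, pos, size)
            continue
        if family == "del_mh":
            size = int(rng.integers(3, 6))
            v = _anchored_del(ref, chrom, pos, size)
            if ":Del:M:" in classify_indel(v, ref):
                return v
            continue
        if family == "del_other":
            size = int(rng.integers(2, 4))
            v = _anchored_del(ref, chrom, pos, size)
            key = classify_indel(v, ref)
            if key.endswith(":Del:R:1"):
                return v
            continue
        raise ValueError(f"unknown indel family {family!r}")
    raise RuntimeError(
        f"could not place a {family} indel after {_MAX_PLACEMENT_TRIES} tries"
    )


def _simulate_svs(rng, profile, ref: ReferenceGenome) -> list[StructuralVariant]:
    out = []
    chroms = ref.contigs
    for svtype, (mean_count, mode, sigma) in profile.items():
        count = int(rng.poisson(mean_count))
        for _ in range(count):
            if svtype == "TRA":
                c1, c2 = rng.choice(len(chroms), size=2, replace=False)
                p1 = int(rng.integers(1000, ref.length(chroms[c1]) - 1000))
                p2 = int(rng.integers(1000, ref.length(chroms[c2]) - 1000))
                out.append(StructuralVariant(chroms[c1], p1, chroms[c2], p2, "TRA"))
                continue
            mu = np.log(mode) + sigma**2
            span = int(rng.lognormal(mu, sigma))
            c = chroms[int(rng.integers(0, len(chroms)))]
            max_span = ref.length(c) - 2000
            span = min(max(span, 50), max_span)
            p1 = int(rng.integers(1000, ref.length(c) - span - 999))
            out.append(StructuralVariant(c, p1, c, p1 + span, svtype))
    return out


def _simulate_cna(
    rng, arch: ArchetypeSpec, ref: ReferenceGenome
) -> list[CopyNumberSegment]:
    mean_cn, wgd = arch.ploidy_target
    segments = []
    for chrom in ref.contigs:
        length = ref.length(chrom)
        if wgd:
            major = float(np.clip(rng.normal(2.0, 0.2), 1.7, 3.0))
            minor = float(np.clip(rng.normal(mean_cn - 2.0, 0.3), 0.0, 3.0))
        else:
            major = float(np.clip(rng.normal(1.0, 0.12), 0.5, 1.45))
            minor = float(np.clip(rng.normal(mean_cn - 1.0, 0.25), 0.0, 1.45))
        base_total = major + minor
        n_seg = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(length - 2, size=n_seg - 1, replace=False) + 1) if n_seg > 1 else np.array([], dtype=int)
        starts = np.concatenate([[1], bounds + 1])
        ends = np.concatenate([bounds, [length]])
        for s, e in zip(starts, ends):
            if arch.name == "genome_stable":
                total = float(np.clip(rng.normal(2.0, 0.08), 1.6, 2.4))
                seg_major = min(major, total)
            else:
                total = float(max(base_total + rng.normal(0.0, 0.2), major))
                seg_major = major
            segments.append(
                CopyNumberSegment(chrom, int(s), int(e), round(total, 4), round(seg_major, 4))
            )
    return segments


def _simulate_events(rng, arch: ArchetypeSpec, sample_id: str) -> SampleEvents:
    drawn: dict[str, GeneEvent] = {}
    for gene, (etype, prob) in arch.gene_events.items():
        if rng.random() < prob:
            biallelic = etype == "mutation" and rng.random() < 0.4
            drawn[gene] = GeneEvent(gene, etype, biallelic)
    for a, b in arch.exclusive_pairs:
        if a in drawn and b in drawn:
            del drawn[a if rng.random() < 0.5 else b]
    return SampleEvents(sample_id, list(drawn.values()))


def _simulate_clinical(
    rng, arch: ArchetypeSpec, sample_id: str, patient_id: str
) -> ClinicalRecord:
    model = arch.clinical_model
    biopsy = BIOPSY_BASE_DATE + dt.timedelta(days=int(rng.integers(0, 365)))
    primary = rng.random() < model.primary_frac
    hist = list(model.histology_weights)
    histology = hist[
        int(rng.choice(len(hist), p=list(model.histology_weights.values())))
    ]
    grade = {
        "HGSC": "poor" if rng.random() < 0.8 else "moderate",
        "LGSC": "well",
    }.get(histology, "unknown")
    figo = ["III", "IV", "II", "unknown"][
        int(rng.choice(4, p=[0.55, 0.3, 0.07, 0.08]))
    ]
    site = ["peritoneum", "lymph node", "liver", "skin", "ovary"][
        int(rng.choice(5, p=[0.48, 0.25, 0.12, 0.05, 0.10]))
    ]
    treatments, recurrences = [], []
    if not primary:
        pre_stop = biopsy - dt.timedelta(days=int(rng.integers(120, 600)))
        pre_start = pre_stop - dt.timedelta(days=int(rng.integers(90, 150)))
        treatments.append(Treatment("carboplatin", "chemo", pre_start, pre_stop, True))
        treatments.append(Treatment("paclitaxel", "chemo", pre_start, pre_stop, True))
        if rng.random() < 0.3:
            treatments.append(
                Treatment("bevacizumab", "targeted", pre_start, pre_stop, True)
            )
        if rng.random() < 0.2:
            treatments.append(
                Treatment("tamoxifen", "hormonal", pre_stop, biopsy, True)
            )
        # recurrence that triggered the biopsy, after the last platinum stop
        gap = int(rng.exponential(250)) + 1
        recurrences.append(pre_stop + dt.timedelta(days=gap))
    post_start = biopsy + dt.timedelta(days=int(rng.integers(7, 30)))
    post_stop = post_start + dt.timedelta(days=int(rng.integers(90, 150)))
    treatments.append(Treatment("carboplatin", "chemo", post_start, post_stop, False))
    if rng.random() < 0.6:
        treatments.append(Treatment("paclitaxel", "chemo", post_start, post_stop, False))
    else:
        treatments.append(Treatment("gemcitabine", "chemo", post_start, post_stop, False))
    codes = list(model.response_probs)
    recist = codes[int(rng.choice(len(codes), p=list(model.response_probs.values())))]
    death_days = rng.exponential(1.0 / model.death_rate_per_day)
    censor_days = float(rng.uniform(200, 1500))
    followup = int(min(death_days, censor_days))
    vital = "dead" if death_days <= censor_days else "alive"
    return ClinicalRecord(
        sample_id=sample_id,
        patient_id=patient_id,
        disease_status="primary" if primary else "recurrent",
        histology=histology,
        grade=grade,
        figo=figo,
        biopsy_site=site,
        biopsy_date=biopsy,
        treatments=treatments,
        recist=recist,
        recurrence_dates=recurrences,
        followup_days=followup,
        vital_status=vital,
    )


def simulate_sample(
    arch: ArchetypeSpec,
    reference: ReferenceGenome,
    seed,
    sample_id: str = "S000",
    patient_id: str | None = None,
    sbs_catalog: SignatureCatalog | None = None,
    dbs_catalog: SignatureCatalog | None = None,
    sampler: _KmerSampler | None = None,
) -> SimulatedSample:
    """Simulate one sample of an archetype; deterministic per seed."""
    rng = np.random.default_rng(seed)
    sbs_catalog = sbs_catalog or packaged_catalog("sbs")
    dbs_catalog = dbs_catalog or packaged_catalog("dbs")
    sampler = sampler or _KmerSampler(reference)
    n_snv = _nbinom(rng, *arch.snv_load)
    n_dbs = _nbinom(rng, *arch.dbs_load)
    n_indel = _nbinom(rng, *arch.indel_load)
    variants = _simulate_snvs(rng, n_snv, arch.signature_mix, sbs_catalog, sampler)
    variants += _simulate_dbs(rng, n_dbs, arch.dbs_mix, dbs_catalog, sampler)
    variants += _simulate_indels(rng, n_indel, arch.indel_profile, reference)
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    svs = _simulate_svs(rng, arch.sv_profile, reference)
    segments = _simulate_cna(rng, arch, reference)
    patient_id = patient_id or f"P-{sample_id}"
    clinical = _simulate_clinical(rng, arch, sample_id, patient_id)
    events = _simulate_events(rng, arch, sample_id)
    meta = SampleMeta(sample_id, patient_id, round(float(rng.uniform(0.25, 0.95)), 3))
    truth = {
        "archetype": arch.name,
        "hrd": arch.hrd,
        "wgd": arch.ploidy_target[1],
        "signature_mix": dict(arch.signature_mix),
        "n_snv": n_snv,
        "n_indel": n_indel,
    }
    return SimulatedSample(meta, variants, svs, segments, clinical, events, truth)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    config: CohortConfig
    reference: ReferenceGenome
    samples: list[SimulatedSample]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "sample_id": s.meta.sample_id,
                    "archetype": s.truth["archetype"],
                    "hrd": s.truth["hrd"],
                    "wgd": s.truth["wgd"],
                    "n_snv": s.truth["n_snv"],
                    "n_indel": s.truth["n_indel"],
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Simulate a full cohort; optionally write it as a file bundle.

    The bundle contains reference.fasta, per-sample VCF / SV TSV / CNA
    TSV, clinical.tsv, samples.tsv, truth.tsv and a manifest.tsv, all
    byte-identical for identical (config, seed).
    """
    if config.total_samples < 2:
        raise ValueError("cohort must contain at least 2 samples")
    root = np.random.SeedSequence(config.seed)
    sample_seeds = root.spawn(config.total_samples)
    reference, sampler = _reference_bundle(
        config.reference_seed, config.n_chroms, config.chrom_length
    )
    sbs_cat = packaged_catalog("sbs")
    dbs_cat = packaged_catalog("dbs")
    samples = []
    idx = 0
    for arch in config.archetypes:
        for _ in range(arch.n_samples):
            idx += 1
            sid = f"S{idx:03d}"
            samples.append(
                simulate_sample(
                    arch,
                    reference,
                    sample_seeds[idx - 1],
                    sample_id=sid,
                    sbs_catalog=sbs_cat,
                    dbs_catalog=dbs_cat,
                    sampler=sampler,
                )
            )
    cohort = Cohort(config, reference, samples)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.reference, out / "reference.fasta")
    contig_lengths = {
        c: cohort.reference.length(c) for c in cohort.reference.contigs
    }
    manifest = []
    for s in cohort.samples:
        sid = s.meta.sample_id
        write_small_variants(s.variants, out / f"{sid}.vcf", contig_lengths)
        write_sv(s.svs, out / f"{sid}.sv.tsv")
        write_cna(s.segments, out / f"{sid}.cna.tsv")
        manifest.append(
            {
                "sample_id": sid,
                "vcf": f"{sid}.vcf",
                "sv": f"{sid}.sv.tsv",
                "cna": f"{sid}.cna.tsv",
            }
        )
    write_samples([s.meta for s in cohort.samples], out / "samples.tsv")
    write_clinical([s.clinical for s in cohort.samples], out / "clinical.tsv")
    cohort.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
    events_rows = [
        {
            "sample_id": s.meta.sample_id,
            "gene": e.gene,
            "event_type": e.event_type,
            "biallelic": e.biallelic,
        }
        for s in cohort.samples
        for e in s.events.events
    ]
    pd.DataFrame(
        events_rows, columns=["sample_id", "gene", "event_type", "biallelic"]
    ).to_csv(out / "gene_events.tsv", sep="\t", index=False)
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
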