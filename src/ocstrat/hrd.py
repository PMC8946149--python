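"""Transparent homologous-recombination-deficiency (HRD) proxy.

This is NOT CHORD.  It scores the two mutation-context feature families a
random-forest HRD classifier is built on — the fraction of indels that are
deletions with flanking microhomology, and the fraction of SVs that are
1–100 kb duplications — and applies explicit thresholds.  Calls on real
data are not comparable to published CHORD calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_features import ContextCounts
from .variant_io import StructuralVariant

SHORT_DUP_MIN_BP = 1_000
SHORT_DUP_MAX_BP = 100_000


@dataclass(frozen=True)
class HrdThresholds:
    """Proxy decision thresholds (invented defaults, configurable)."""

    mhdel_frac: float = 0.10
    shortdup_frac: float = 0.25


@dataclass(frozen=True)
class HrdCall:
    status: str  # proficient | deficient
    subtype: str  # none | BRCA1-type | BRCA2-type
    f_mhdel: float
    f_shortdup: float

    def __post_init__(self):
        if self.status not in ("proficient", "deficient"):
            raise ValueError(f"bad status {self.status}")
        if (self.subtype != "none") != (self.status == "deficient"):
            raise ValueError("subtype set iff deficient")
        for f in (self.f_mhdel, self.f_shortdup):
            if not 0.0 <= f <= 1.0:
                raise ValueError("feature fractions must be in [0, 1]")


def hrd_features(
    cc: ContextCounts, svs: list[StructuralVariant]
) -> tuple[float, float]:
    """(f_mhdel, f_shortdup) for one sample; 0 when the denominator is 0."""
    n_indel = cc.indel_total()
    f_mhdel = cc.mh_deletions() / n_indel if n_indel else 0.0
    n_sv = len(svs)
    if n_sv:
        n_shortdup = sum(
            1
            for sv in svs
            if sv.svtype == "DUP"
            and SHORT_DUP_MIN_BP <= sv.span_bp <= SHORT_DUP_MAX_BP
        )
        f_shortdup = n_shortdup / n_sv
    else:
        f_shortdup = 0.0
    return f_mhdel, f_shortdup


def classify_hrd_proxy(
    f_mhdel: float,
    f_shortdup: float,
    thresholds: HrdThresholds = HrdThresholds(),
) -> HrdCall:
    """Deficient iff either feature fraction crosses its threshold.

    The short-duplication phenotype is associated with BRCA1-type
    deficiency; deficient samples without it are called BRCA2-type.
    """
    deficient = (
        f_mhdel >= thresholds.mhdel_frac or f_shortdup >= thresholds.shortdup_frac
    )
    if not deficient:
        return HrdCall("proficient", "none", f_mhdel, f_shortdup)
    subtype = (
        "BRCA1-type" if f_shortdup >= thresholds.shortdup_frac else "BRCA2-type"
    )
    return HrdCall("deficient", subtype, f_mhdel, f_shortdup)
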