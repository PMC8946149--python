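"""Match per-sample gene events against a packaged actionability
evidence table and summarize targetability per cluster.

Evidence levels follow the validated-association (A) / clinical-evidence
(B) convention with on-/off-label flags; entries flagged as standard of
care for ovarian cancer (platinum agents, PARP inhibitors) are excluded
from matching.  The packaged table is a small synthetic fixture; fuller
database exports in the same TSV schema can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ALTERATION_CLASSES = (
    "hotspot_mutation",
    "any_mutation",
    "amplification",
    "deletion",
    "fusion",
)
EVENT_TYPES = ("mutation", "hotspot", "amplification", "deletion", "fusion")
LEVELS = ("A", "B")
LABELS = ("on", "off")

# total tier ordering, best first
TIER_ORDER = ("A-on", "A-off", "B-on", "B-off")

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class EvidenceEntry:
    gene: str
    alteration_class: str
    drug: str
    level: str  # A = validated association, B = clinical evidence
    label: str  # on- or off-label for ovarian cancer
    standard_of_care: bool = False

    def __post_init__(self):
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration class {self.alteration_class!r}")
        if self.level not in LEVELS or self.label not in LABELS:
            raise ValueError(f"bad level/label {self.level}/{self.label}")

    @property
    def tier(self) -> str:
        return f"{self.level}-{self.label}"


@dataclass(frozen=True)
class GeneEvent:
    gene: str
    event_type: str  # mutation | hotspot | amplification | deletion | fusion
    biallelic: bool = False

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass
class SampleEvents:
    sample_id: str
    events: list[GeneEvent] = field(default_factory=list)


@dataclass(frozen=True)
class ActionableMatch:
    gene: str
    event_type: str
    drug: str
    tier: str


def read_evidence(path=None) -> list[EvidenceEntry]:
    """Load an evidence TSV (defaults to the packaged synthetic fixture)."""
    path = path or (_DATA / "evidence_synthetic.tsv")
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            EvidenceEntry(
                gene=str(row.gene).upper(),
                alteration_class=row.alteration_class,
                drug=row.drug,
                level=row.level,
                label=row.label,
                standard_of_care=bool(row.standard_of_care),
            )
        )
    return entries


def _compatible(event_type: str, alteration_class: str) -> bool:
    if alteration_class == "hotspot_mutation":
        return event_type == "hotspot"
    if alteration_class == "any_mutation":
        return event_type in ("mutation", "hotspot")
    return event_type == alteration_class


def match_actionable(
    events: SampleEvents, db: list[EvidenceEntry]
) -> list[ActionableMatch]:
    """All evidence matches for one sample, best tier first.

    A hotspot event satisfies both hotspot-specific and any-mutation
    entries; copy-number and fusion classes match exactly.  Standard-of-
    care entries never match.
    """
    matches = []
    for ev in events.events:
        for entry in db:
            if entry.standard_of_care:
                continue
            if entry.gene != ev.gene.upper():
                continue
            if _compatible(ev.event_type, entry.alteration_class):
                matches.append(
                    ActionableMatch(entry.gene, ev.event_type, entry.drug, entry.tier)
                )
    matches.sort(key=lambda m: TIER_ORDER.index(m.tier))
    return matches


def best_tier(matches: list[ActionableMatch]) -> str | None:
    if not matches:
        return None
    return min(matches, key=lambda m: TIER_ORDER.index(m.tier)).tier


def targetable_fraction_per_cluster(
    matches_by_sample: dict[str, list[ActionableMatch]],
    labels: dict[str, int],
) -> dict[int, float]:
    """Fraction of samples per cluster with at least one actionable match."""
    missing = [s for s in labels if s not in matches_by_sample]
    if missing:
        raise ValueError(f"samples without match results: {missing}")
    out: dict[int, float] = {}
    for cluster in sorted(set(labels.values())):
        members = [s for s, c in labels.items() if c == cluster]
        hit = sum(1 for s in members if matches_by_sample[s])
        out[cluster] = hit / len(members)
    return out


def match_table(matches_by_sample: dict[str, list[ActionableMatch]]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": sid,
            "gene": m.gene,
            "event_type": m.event_type,
            "drug": m.drug,
            "tier": m.tier,
        }
        for sid, ms in matches_by_sample.items()
        for m in ms
    ]
    return pd.DataFrame(rows, columns=["sample_id", "gene", "event_type", "drug", "tier"])
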