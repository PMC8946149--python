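"""Clinical derivations: response grouping, platinum-free interval,
survival, rank-sum comparisons, and per-cluster summaries.

RECIST responses CR/PR form the favorable group and SD/PD the poor group;
clinical progression without imaging is recorded as PD upstream.  The
platinum-free interval (PFI) is the time from the last platinum stop date
to the next recurrence, binned at 183 days (the six-month
platinum-sensitivity boundary).  One-year survival excludes patients
censored alive before day 365 from both numerator and denominator so that
printed x/y pairs are reproducible; the Kaplan-Meier estimator (via
lifelines) is the principled alternative and is also provided.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HISTOLOGIES = (
    "HGSC",
    "LGSC",
    "serous-NOS",
    "adenocarcinoma-NOS",
    "clear-cell",
    "endometrioid",
    "carcinosarcoma",
    "mucinous",
    "unknown",
)
GRADES = ("well", "moderate", "poor", "unknown")
FIGO_STAGES = ("I", "II", "III", "IV", "unknown")
RECIST_CODES = ("CR", "PR", "SD", "PD", "NA")
DRUG_CLASSES = ("chemo", "targeted", "hormonal", "immuno")

PFI_BIN_DAYS = 183

PLATINUM_DRUGS = frozenset({"carboplatin", "cisplatin", "oxaliplatin"})

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class Treatment:
    drug: str
    drug_class: str  # chemo | targeted | hormonal | immuno
    start: dt.date
    stop: dt.date | None
    pre_biopsy: bool

    def __post_init__(self):
        if self.drug_class not in DRUG_CLASSES:
            raise ValueError(f"bad drug class {self.drug_class}")

    @property
    def is_platinum(self) -> bool:
        return self.drug.lower() in PLATINUM_DRUGS


@dataclass
class ClinicalRecord:
    sample_id: str
    patient_id: str
    disease_status: str  # primary | recurrent
    histology: str
    grade: str
    figo: str
    biopsy_site: str
    biopsy_date: dt.date
    treatments: list[Treatment] = field(default_factory=list)
    recist: str = "NA"
    recurrence_dates: list[dt.date] = field(default_factory=list)
    followup_days: int = 0
    vital_status: str = "alive"

    def __post_init__(self):
        if self.disease_status not in ("primary", "recurrent"):
            raise ValueError(f"bad disease status {self.disease_status}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"bad histology {self.histology}")
        if self.grade not in GRADES:
            raise ValueError(f"bad grade {self.grade}")
        if self.figo not in FIGO_STAGES:
            raise ValueError(f"bad FIGO stage {self.figo}")
        if self.recist not in RECIST_CODES:
            raise ValueError(f"bad RECIST code {self.recist}")
        if self.vital_status not in ("alive", "dead"):
            raise ValueError(f"bad vital status {self.vital_status}")
        if self.followup_days < 0:
            raise ValueError("followup_days must be non-negative")


def classify_serous_histology(grade: str) -> str:
    """Serous carcinoma subtype from differentiation grade.

    Poor and moderate differentiation map to HGSC, well to LGSC, and
    unknown grade to serous-NOS.
    """
    return {"poor": "HGSC", "moderate": "HGSC", "well": "LGSC"}.get(
        grade, "serous-NOS"
    )


def percent(x: int, y: int) -> int:
    """Nearest-integer percentage, half away from zero (e.g. 15/17 -> 88)."""
    if y == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return int(math.floor((200 * x + y) / (2 * y))) if x >= 0 else -percent(-x, y)


def group_response(recist: str) -> str:
    """CR/PR -> favorable, SD/PD -> poor, NA -> missing."""
    if recist in ("CR", "PR"):
        return "favorable"
    if recist in ("SD", "PD"):
        return "poor"
    if recist == "NA":
        return "missing"
    raise ValueError(f"unknown RECIST code {recist!r}")


def compute_pfi(record: ClinicalRecord) -> tuple[int | None, str]:
    """Platinum-free interval in days and its six-month bin.

    Returns (days, bin) with bin in {"<=6 months", ">6 months", "NA"}.
    NA when there is no platinum stop date or no subsequent recurrence.
    A recorded recurrence strictly before the last platinum stop is a data
    inconsistency and raises.
    """
    stops = [
        t.stop for t in record.treatments if t.is_platinum and t.stop is not None
    ]
    if not stops:
        return None, "NA"
    last_stop = max(stops)
    if not record.recurrence_dates:
        return None, "NA"
    after = [d for d in record.recurrence_dates if d >= last_stop]
    if not after:
        raise ValueError(
            f"{record.sample_id}: recurrence precedes last platinum stop"
        )
    days = (min(after) - last_stop).days
    return days, (">6 months" if days > PFI_BIN_DAYS else "<=6 months")


def one_year_survival(
    records: list[ClinicalRecord],
) -> tuple[int, int, int | None]:
    """(survivors, at_risk, percent) one year after biopsy.

    Patients censored alive before day 365 are excluded from both the
    numerator and denominator; the percent is rounded to the nearest
    integer (half away from zero).
    """
    survivors = at_risk = 0
    for r in records:
        if r.vital_status == "alive" and r.followup_days < 365:
            continue  # censored before one year: not informative
        at_risk += 1
        if r.followup_days >= 365:
            survivors += 1
    if at_risk == 0:
        return 0, 0, None
    return survivors, at_risk, percent(survivors, at_risk)


def km_curve(records: list[ClinicalRecord]):
    """Kaplan-Meier product-limit estimate of survival from biopsy.

    Returns a fitted ``lifelines.KaplanMeierFitter``; times are
    ``followup_days`` and events are deaths.
    """
    from lifelines import KaplanMeierFitter

    if not records:
        raise ValueError("km_curve requires at least one record")
    times = np.array([r.followup_days for r in records], dtype=float)
    if np.any(times < 0):
        raise ValueError("negative follow-up times")
    events = np.array([r.vital_status == "dead" for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return kmf


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) p-value."""
    from scipy.stats import mannwhitneyu

    return float(mannwhitneyu(x, y, alternative=alternative).pvalue)


def bonferroni(p: float, family_size: int) -> float:
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * family_size)


@dataclass
class ClusterSummary:
    cluster: int
    n: int
    favorable_n: int
    poor_n: int
    missing_response_n: int
    one_year_survivors_n: int
    at_risk_n: int
    one_year_percent: int | None
    histology_counts: dict[str, int]
    actionable_fraction: float

    def __post_init__(self):
        if self.favorable_n + self.poor_n + self.missing_response_n != self.n:
            raise ValueError("response counts do not partition the cluster")


def summarize_cluster(
    labels: dict[str, int],
    records: dict[str, ClinicalRecord],
    actionable: dict[str, bool] | None = None,
) -> list[ClusterSummary]:
    """Per-cluster clinical and actionability aggregates."""
    actionable = actionable or {}
    missing = [s for s in labels if s not in records]
    if missing:
        raise ValueError(f"labeled samples without clinical record: {missing}")
    out = []
    for cluster in sorted(set(labels.values())):
        members = [s for s, c in labels.items() if c == cluster]
        recs = [records[s] for s in members]
        resp = [group_response(r.recist) for r in recs]
        surv, at_risk, pct = one_year_survival(recs)
        hist: dict[str, int] = {}
        for r in recs:
            hist[r.histology] = hist.get(r.histology, 0) + 1
        n_act = sum(1 for s in members if actionable.get(s, False))
        out.append(
            ClusterSummary(
                cluster=cluster,
                n=len(members),
                favorable_n=resp.count("favorable"),
                poor_n=resp.count("poor"),
                missing_response_n=resp.count("missing"),
                one_year_survivors_n=surv,
                at_risk_n=at_risk,
                one_year_percent=pct,
                histology_counts=hist,
                actionable_fraction=n_act / len(members) if members else 0.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id",
    "patient_id",
    "disease_status",
    "histology",
    "grade",
    "figo",
    "biopsy_site",
    "biopsy_date",
    "treatments",
    "recist",
    "recurrence_dates",
    "followup_days",
    "vital_status",
]


def _fmt_date(d: dt.date | None) -> str:
    return d.isoformat() if d else ""


def _parse_date(s: str) -> dt.date | None:
    return dt.date.fromisoformat(s) if s else None


def _encode_treatments(ts: list[Treatment]) -> str:
    return ";".join(
        f"{t.drug}|{t.drug_class}|{_fmt_date(t.start)}|{_fmt_date(t.stop)}|"
        f"{'pre' if t.pre_biopsy else 'post'}"
        for t in ts
    )


def _decode_treatments(s: str) -> list[Treatment]:
    if not s or pd.isna(s):
        return []
    out = []
    for part in str(s).split(";"):
        drug, cls, start, stop, phase = part.split("|")
        out.append(
            Treatment(drug, cls, _parse_date(start), _parse_date(stop), phase == "pre")
        )
    return out


def write_clinical(records: list[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "disease_status": r.disease_status,
                "histology": r.histology,
                "grade": r.grade,
                "figo": r.figo,
                "biopsy_site": r.biopsy_site,
                "biopsy_date": _fmt_date(r.biopsy_date),
                "treatments": _encode_treatments(r.treatments),
                "recist": r.recist,
                "recurrence_dates": ";".join(
                    _fmt_date(d) for d in r.recurrence_dates
                ),
                "followup_days": r.followup_days,
                "vital_status": r.vital_status,
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ClinicalRecord(
                sample_id=str(row.sample_id),
                patient_id=str(row.patient_id),
                disease_status=row.disease_status,
                histology=row.histology,
                grade=row.grade,
                figo=str(row.figo),
                biopsy_site=row.biopsy_site,
                biopsy_date=_parse_date(row.biopsy_date),
                treatments=_decode_treatments(row.treatments),
                recist=row.recist,
                recurrence_dates=[
                    _parse_date(s)
                    for s in str(row.recurrence_dates).split(";")
                    if s
                ],
                followup_days=int(row.followup_days),
                vital_status=row.vital_status,
            )
        )
    return out


def drug_class_map() -> pd.DataFrame:
    """Packaged editable drug -> treatment-class mapping."""
    return pd.read_csv(_DATA / "drug_classes.tsv", sep="\t")
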