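"""Long-term outcome labels from CAPS symptom trajectories.

Remission is defined on the Clinician-Administered PTSD Scale (CAPS): a
subject whose CAPS total improves by at least 50% between baseline and
the long-term follow-up is *remitted*, otherwise *persistent*.  The
follow-up score (not the immediate post-treatment score) defines the
label; acute treatment response is available separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "ClinicalRecord",
    "OutcomeLabel",
    "improvement_fraction",
    "classify_outcome",
    "acute_response",
    "label_cohort",
    "read_clinical_csv",
    "write_labels_tsv",
]

REMITTED = "remitted"
PERSISTENT = "persistent"


@dataclass(frozen=True)
class ClinicalRecord:
    """CAPS total scores for one subject at three assessments."""

    subject_id: str
    caps_pre: float
    caps_post: float
    caps_followup: float

    def __post_init__(self) -> None:
        for name in ("caps_pre", "caps_post", "caps_followup"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class OutcomeLabel:
    subject_id: str
    label: Literal["remitted", "persistent"]
    improvement: float


def improvement_fraction(caps_pre: float, caps_followup: float) -> float:
    """Fractional CAPS improvement, ``(pre - followup) / pre``.

    Negative if symptoms worsened; requires a positive baseline score.
    """
    if caps_pre <= 0:
        raise ValueError(f"caps_pre must be positive to compute improvement, got {caps_pre}")
    return (caps_pre - caps_followup) / caps_pre


def classify_outcome(record: ClinicalRecord) -> OutcomeLabel:
    """Remitted iff follow-up improvement is 50% or greater (inclusive)."""
    imp = improvement_fraction(record.caps_pre, record.caps_followup)
    return OutcomeLabel(
        subject_id=record.subject_id,
        label=REMITTED if imp >= 0.5 else PERSISTENT,
        improvement=imp,
    )


def acute_response(record: ClinicalRecord) -> OutcomeLabel:
    """Immediate post-treatment response (same 50% rule, post-treatment CAPS).

    Not used by the prognosis classifier, which targets the long-term label.
    """
    imp = improvement_fraction(record.caps_pre, record.caps_post)
    return OutcomeLabel(
        subject_id=record.subject_id,
        label=REMITTED if imp >= 0.5 else PERSISTENT,
        improvement=imp,
    )


def label_cohort(records: Iterable[ClinicalRecord]) -> list[OutcomeLabel]:
    return [classify_outcome(r) for r in records]


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Load a clinical table with columns subject_id, caps_pre, caps_post, caps_followup."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "caps_pre", "caps_post", "caps_followup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return [
        ClinicalRecord(
            subject_id=str(row.subject_id),
            caps_pre=float(row.caps_pre),
            caps_post=float(row.caps_post),
            caps_followup=float(row.caps_followup),
        )
        for row in df.itertuples()
    ]


def write_labels_tsv(labels: Iterable[OutcomeLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"subject_id": l.subject_id, "improvement": l.improvement, "label": l.label}
         for l in labels]
    )
    df.to_csv(path, sep="\t", index=False)
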