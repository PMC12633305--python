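"""Longitudinal score trajectories and treatment-response evaluation.

Serial plasma samples from a patient under treatment are aligned to the
clinical timeline (treatments, radiological assessments, outcomes). Each
sample is labeled by the nearest disease-status assessment within a ±50
day window: stable disease, partial or complete response, and remission
are responders; progressive disease is a non-responder; samples with no
assessment inside the window stay unlabeled. Score distributions between
groups are compared with a two-sided Wilcoxon rank-sum test, and samples
can be stratified by time to relapse for minimal-residual-disease
read-outs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_MONTH = 30.44  # fixed-length months keep binning deterministic

TREATMENT_CATEGORIES = {"surgery", "chemo_start", "chemo_stop", "immunotherapy"}
ASSESSMENT_CATEGORIES = {"SD", "PR", "CR", "PD", "remission"}
OUTCOME_CATEGORIES = {"relapse", "death"}
RESPONDER_CATEGORIES = {"SD", "PR", "CR", "remission"}


def _as_date(d: str | date | datetime) -> date:
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, date):
        return d
    return date.fromisoformat(d)


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated clinical event for a patient."""

    patient_id: str
    date: date
    event_class: str  # treatment | assessment | outcome
    category: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", _as_date(self.date))
        allowed = {
            "treatment": TREATMENT_CATEGORIES,
            "assessment": ASSESSMENT_CATEGORIES,
            "outcome": OUTCOME_CATEGORIES,
        }
        if self.event_class not in allowed:
            raise ValueError(f"unknown event_class {self.event_class!r}")
        if self.category not in allowed[self.event_class]:
            raise ValueError(
                f"category {self.category!r} inconsistent with class {self.event_class!r}"
            )


@dataclass(frozen=True)
class SampleTimepoint:
    """One scored plasma sample on a patient's timeline."""

    patient_id: str
    date: date
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", _as_date(self.date))
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0,1]")


def label_response(
    sample: SampleTimepoint,
    events: Sequence[ClinicalEvent],
    window_days: int = 50,
) -> str:
    """Response label from the nearest disease-status assessment.

    Returns "R" (SD/PR/CR/remission), "NR" (PD), or "unlabeled" when the
    nearest assessment is farther than ``window_days`` or the patient has
    no assessments. Distance ties are broken toward the LATER assessment
    (disease state evolves forward). Deterministic regardless of the
    input event ordering.
    """
    if window_days < 0:
        raise ValueError("window_days must be nonnegative")
    assessments = [
        e
        for e in events
        if e.patient_id == sample.patient_id and e.event_class == "assessment"
    ]
    if not assessments:
        return "unlabeled"
    # minimal |gap|; ties toward the later date (largest date among minima)
    best = min(
        assessments,
        key=lambda e: (abs((e.date - sample.date).days), -e.date.toordinal()),
    )
    if abs((best.date - sample.date).days) > window_days:
        return "unlabeled"
    return "R" if best.category in RESPONDER_CATEGORIES else "NR"


@dataclass
class Trajectory:
    """One patient's ordered score series anchored at first treatment."""

    patient_id: str
    times_days: np.ndarray  # relative to anchor
    scores: np.ndarray
    anchor_date: date
    anchor_mode: str  # "first_treatment" | "first_sample"
    events: list[tuple[int, str, str]]  # (days since anchor, event_class, category)


def build_trajectory(
    patient_id: str,
    samples: Sequence[SampleTimepoint],
    events: Sequence[ClinicalEvent],
) -> Trajectory:
    """Time-ordered (days since first treatment, score) series with event
    annotations. Without any treatment event the first sample anchors t=0
    and ``anchor_mode`` flags the fallback."""
    own_samples = sorted(
        (s for s in samples if s.patient_id == patient_id), key=lambda s: s.date
    )
    if not own_samples:
        raise ValueError(f"no samples for patient {patient_id}")
    own_events = sorted(
        (e for e in events if e.patient_id == patient_id), key=lambda e: e.date
    )
    treatments = [e for e in own_events if e.event_class == "treatment"]
    if treatments:
        anchor, mode = treatments[0].date, "first_treatment"
    else:
        anchor, mode = own_samples[0].date, "first_sample"
    return Trajectory(
        patient_id=patient_id,
        times_days=np.array([(s.date - anchor).days for s in own_samples]),
        scores=np.array([s.score for s in own_samples]),
        anchor_date=anchor,
        anchor_mode=mode,
        events=[((e.date - anchor).days, e.event_class, e.category) for e in own_events],
    )


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) between two score groups.

    Small groups (both ≤ 10) use exact enumeration of all group
    assignments, which handles ties exactly; larger groups use the
    tie-corrected normal approximation. Returns (U of group a, p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.size <= 10 and b.size <= 10:
        n_perm = math.comb(a.size + b.size, a.size)
        method = stats.PermutationMethod(n_resamples=max(n_perm + 1, 200000))
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def time_to_event_bins(
    samples: Sequence[SampleTimepoint],
    relapse_dates: dict[str, date],
    bin_edges_months: Sequence[tuple[float, float]] = (
        (-22, -9),
        (-8, -7),
        (-6, -3),
        (-2, -1),
        (0, 3),
    ),
) -> dict[str, list[float]]:
    """Group sample scores by time to relapse, in fixed-length months.

    Each sample of a relapsing patient falls in the bin whose
    [lo, hi + 1) month range (half-open toward relapse) contains
    (sample date − relapse date) / 30.44 days; an edge sample goes to the
    later, closer-to-relapse bin. Samples of non-relapsing patients form
    the "No relapse" group; samples in gaps between the published bin
    ranges are reported under "unbinned" rather than silently merged.
    """
    edges = sorted((float(lo), float(hi)) for lo, hi in bin_edges_months)
    for (lo1, hi1), (lo2, _) in zip(edges, edges[1:]):
        if lo2 <= hi1:
            raise ValueError("overlapping time-to-relapse bins")
    groups: dict[str, list[float]] = {f"{lo:g} to {hi:g}": [] for lo, hi in edges}
    groups["No relapse"] = []
    groups["unbinned"] = []
    for s in samples:
        relapse = relapse_dates.get(s.patient_id)
        if relapse is None:
            groups["No relapse"].append(s.score)
            continue
        months = (s.date - _as_date(relapse)).days / DAYS_PER_MONTH
        placed = False
        for lo, hi in edges:
            if lo <= months < hi + 1:  # half-open toward relapse
                groups[f"{lo:g} to {hi:g}"].append(s.score)
                placed = True
                break
        if not placed:
            groups["unbinned"].append(s.score)
    return groups


# --- TSV I/O ---------------------------------------------------------------

def read_events(path: str | Path) -> list[ClinicalEvent]:
    """Read a clinical timeline TSV: patient_id, date (ISO-8601),
    event_class, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "date", "event_class", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events TSV missing columns: {sorted(missing)}")
    return [
        ClinicalEvent(r.patient_id, r.date, r.event_class, r.category)
        for r in df.itertuples()
    ]


def read_timepoints(path: str | Path) -> list[SampleTimepoint]:
    """Read scored sample timepoints TSV: patient_id, date, score."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "date", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scores TSV missing columns: {sorted(missing)}")
    return [
        SampleTimepoint(str(r.patient_id), str(r.date), float(r.score))
        for r in df.itertuples()
    ]


def write_events(events: Sequence[ClinicalEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "date": [e.date.isoformat() for e in events],
            "event_class": [e.event_class for e in events],
            "category": [e.category for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def write_timepoints(samples: Sequence[SampleTimepoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "date": [s.date.isoformat() for s in samples],
            "score": [round(s.score, 10) for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)
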