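"""Scale scores, composites, person-level aggregation and compliance.

A scale score at one timepoint is the mean of the scale's answered items on
the 1-7 continuum (hidden branch items are excluded, not imputed).  Two scales
are reported as composites so that their content matches the interview item
they mirror: the delusions score augments the delusion items with the
grandiosity, somatic-concern and suspiciousness scale means, and the
depression score augments the depression items with the hopelessness mean.
Person-level scores are unweighted means over all available timepoints, and a
participant is compliant when at least 33% of the scheduled entries (14 of 42
at defaults) were completed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .item_bank import ItemBank, ScaleDef, recode_grandiosity1
from .session_engine import SessionEntry

__all__ = [
    "ScaleScore",
    "PersonSummary",
    "ComplianceRule",
    "score_entry_scale",
    "composite_delusions",
    "composite_depression",
    "score_entry_all",
    "person_mean",
    "classify_compliance",
    "completion_percent",
    "summarise_person",
]


@dataclass(frozen=True)
class ScaleScore:
    participant_id: str
    day: int
    alarm_index: int
    scale_id: str
    value: float  # mean on the 1-7 continuum


class ComplianceRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    fraction_threshold: float = Field(default=0.33, gt=0, le=1)
    n_possible: int = Field(default=42, ge=1)

    @property
    def threshold_count(self) -> int:
        """Smallest completed-entry count meeting the fraction (14 of 42)."""
        return math.ceil(round(self.fraction_threshold * self.n_possible, 9))


@dataclass(frozen=True)
class PersonSummary:
    participant_id: str
    scale_means: Mapping[str, float]
    n_completed: int
    n_possible: int
    compliant: bool


def _item_values(entry: SessionEntry, scale: ScaleDef) -> list[float]:
    values: list[float] = []
    for item in scale.items:
        raw = entry.responses.get(item.item_id)
        if raw is None:
            continue
        values.append(float(recode_grandiosity1(raw)) if item.recode == "grandiosity1" else float(raw))
    return values


def score_entry_scale(entry: SessionEntry, scale: ScaleDef) -> Optional[float]:
    """Mean of the scale's answered items at this timepoint, recodes applied.

    Returns None when no item of the scale was displayed and answered (the
    score is undefined, never zero).
    """
    if not entry.completed:
        return None
    values = _item_values(entry, scale)
    return sum(values) / len(values) if values else None


def composite_delusions(entry: SessionEntry, bank_view: ItemBank) -> Optional[float]:
    """Delusions score: each delusion item plus three informing scale means.

    Components are the individual delusion item responses followed by the
    grandiosity, somatic-concern and suspiciousness scale means, all weighted
    equally; with no delusions configured the score is the mean of the three
    scale means alone.
    """
    if not entry.completed or entry.set != 2:
        return None
    components = _item_values(entry, bank_view.scale("delusions"))
    for sid in ("grandiosity", "somatic_concern", "suspiciousness"):
        m = score_entry_scale(entry, bank_view.scale(sid))
        if m is not None:
            components.append(m)
    return sum(components) / len(components) if components else None


def composite_depression(entry: SessionEntry, bank_view: ItemBank) -> Optional[float]:
    """Depression score: each depression item plus the hopelessness scale mean."""
    if not entry.completed or entry.set != 1:
        return None
    components = _item_values(entry, bank_view.scale("depression"))
    hope = score_entry_scale(entry, bank_view.scale("hopelessness"))
    if hope is not None:
        components.append(hope)
    return sum(components) / len(components) if components else None


def score_entry_all(entry: SessionEntry, bank_view: ItemBank) -> dict[str, float]:
    """All reportable scale scores for one completed entry.

    Plain scales are item means; ``depression`` and ``delusions`` are reported
    as their composites.
    """
    if not entry.completed:
        return {}
    out: dict[str, float] = {}
    for scale in bank_view.scales_in_set(entry.set):
        if scale.composite == "depression_composite":
            value = composite_depression(entry, bank_view)
        elif scale.composite == "delusions_composite":
            value = composite_delusions(entry, bank_view)
        else:
            value = score_entry_scale(entry, scale)
        if value is not None:
            out[scale.scale_id] = value
    return out


def person_mean(scores: Sequence[float]) -> Optional[float]:
    """Unweighted mean over available timepoints; None for an empty series."""
    scores = [s for s in scores if s is not None]
    return sum(scores) / len(scores) if scores else None


def classify_compliance(n_completed: int, rule: ComplianceRule | None = None) -> bool:
    """Compliant iff the completed count reaches the threshold (>= 14 of 42)."""
    rule = rule or ComplianceRule()
    if not 0 <= n_completed <= rule.n_possible:
        raise ValueError(f"n_completed must lie in 0..{rule.n_possible}, got {n_completed}")
    return n_completed >= rule.threshold_count


def completion_percent(n_completed: int, n_possible: int) -> int:
    """Completion rate as a percentage rounded half-up to the nearest integer."""
    if n_possible <= 0:
        raise ValueError("n_possible must be positive")
    return int(math.floor(100.0 * n_completed / n_possible + 0.5))


def summarise_person(
    entries: Iterable[SessionEntry],
    bank_view: ItemBank,
    rule: ComplianceRule | None = None,
) -> PersonSummary:
    """Aggregate one participant's entries into per-scale means and compliance."""
    rule = rule or ComplianceRule()
    entries = list(entries)
    pids = {e.participant_id for e in entries}
    if len(pids) != 1:
        raise ValueError(f"entries must belong to a single participant, got {sorted(pids)}")
    series: dict[str, list[float]] = {}
    n_completed = 0
    for entry in sorted(entries, key=lambda e: e.alarm_index):
        if not entry.completed:
            continue
        n_completed += 1
        for sid, value in score_entry_all(entry, bank_view).items():
            series.setdefault(sid, []).append(value)
    means = {sid: person_mean(vals) for sid, vals in series.items()}
    return PersonSummary(
        participant_id=pids.pop(),
        scale_means={k: v for k, v in means.items() if v is not None},
        n_completed=n_completed,
        n_possible=rule.n_possible,
        compliant=classify_compliance(min(n_completed, rule.n_possible), rule),
    )
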