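"""Administration of one prompted session: set alternation, branching, capture."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from .item_bank import (
    ItemBank,
    analogue_to_likert,
    evaluate_branch,
)

__all__ = ["SessionEntry", "assign_set", "administer_session", "REACTIVITY_ITEM_IDS"]

#: Stable ids for the two reactivity (safety) statements appended to every
#: session; they belong to no symptom scale.
REACTIVITY_ITEM_IDS = ("reactivity_thoughts", "reactivity_mood")

#: Responder signature: analogue-slider position in [0, 1] for a given item id.
Responder = Callable[[str], float]


@dataclass(frozen=True)
class SessionEntry:
    """Item-level record of one prompted assessment occasion."""

    participant_id: str
    day: int
    alarm_index: int  # 1-based within the whole run
    set: int
    responses: Mapping[str, int] = field(default_factory=dict)  # item_id -> likert 1..7
    status: str = "completed"  # completed | missed
    first_of_day: bool = False
    answered_at: int | None = None  # minutes since midnight, if known

    @property
    def completed(self) -> bool:
        return self.status == "completed"


def assign_set(global_alarm_index: int) -> int:
    """Alternate the two item sets across prompts: odd alarms set 1, even set 2."""
    if global_alarm_index < 1:
        raise ValueError("alarm index is 1-based")
    return 1 if global_alarm_index % 2 == 1 else 2


def administer_session(
    bank_view: ItemBank,
    set_number: int,
    responder: Responder,
    *,
    participant_id: str = "P001",
    day: int = 1,
    alarm_index: int = 1,
    first_of_day: bool = False,
    answered_at: int | None = None,
) -> SessionEntry:
    """Run one session of the given set against a responder.

    Stems are presented in bank order; a branch item is presented iff its
    display condition holds given the responses captured so far.  Analogue
    positions are converted to the 7-point Likert scale at capture.  The two
    reactivity items are appended to every session.  Any responder failure
    (exception or out-of-range position) marks the whole entry missed: partial
    sessions carry no item data.
    """
    responses: dict[str, int] = {}
    try:
        for scale in bank_view.scales_in_set(set_number):
            for item in scale.items:
                if item.role == "branch" and not evaluate_branch(item.display_condition, responses):
                    continue
                responses[item.item_id] = analogue_to_likert(responder(item.item_id))
        for rid in REACTIVITY_ITEM_IDS:
            responses[rid] = analogue_to_likert(responder(rid))
    except Exception:
        return SessionEntry(
            participant_id=participant_id,
            day=day,
            alarm_index=alarm_index,
            set=set_number,
            responses={},
            status="missed",
            first_of_day=first_of_day,
        )
    return SessionEntry(
        participant_id=participant_id,
        day=day,
        alarm_index=alarm_index,
        set=set_number,
        responses=responses,
        status="completed",
        first_of_day=first_of_day,
        answered_at=answered_at,
    )
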