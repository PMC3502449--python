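"""Instrument definition: 14 branching symptom scales, delusion templates, recodes.

The momentary-assessment instrument covers 14 symptom constructs (12 mapped to
PANSS interview items, 2 to Calgary Depression Scale items) split into two sets
administered at alternating prompts.  Some items are *branches*: they are shown
only when an earlier stem response satisfies a display condition.  Responses are
captured on a visual-analogue scale and converted to a 7-point Likert scale;
the first grandiosity item is additionally recoded so that only self-appraisals
above the midpoint contribute to the score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BankValidationError",
    "BranchCondition",
    "ItemDef",
    "ScaleDef",
    "DelusionTemplate",
    "DelusionSelection",
    "ItemBank",
    "load_item_bank",
    "load_default_bank",
    "enumerate_question_counts",
    "configure_delusions",
    "analogue_to_likert",
    "recode_grandiosity1",
    "evaluate_branch",
]

SET_1_SCALES = frozenset(
    {
        "guilt",
        "hopelessness",
        "depression",
        "social_withdrawal",
        "conceptual_disorganisation",
        "excitement",
        "hallucinations",
    }
)
SET_2_SCALES = frozenset(
    {
        "anxiety",
        "grandiosity",
        "hostility",
        "somatic_concern",
        "guilty_ideas_of_reference",
        "suspiciousness",
        "delusions",
    }
)

#: Question-count bounds over all branch outcomes that a valid packaged bank
#: must reproduce (set 2 enumerated over 0, 1 and 2 configured delusions).
SET_1_COUNT_RANGE = (15, 30)
SET_2_COUNT_RANGE = (11, 31)

MAX_DELUSIONS = 2
DELUSION_SUB_ITEM_COUNT = 3
N_SCALES = 14
N_DELUSION_TEMPLATES = 6


class BankValidationError(ValueError):
    """Raised when an item-bank document violates a structural invariant."""


class BranchCondition(BaseModel):
    """Display condition of a branch item: show iff ``source <cmp> threshold``."""

    model_config = ConfigDict(frozen=True)

    source: str
    comparator: Literal[">=", ">", "=="]
    threshold: int = Field(ge=1, le=7)


class ItemDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    text: str
    role: Literal["stem", "branch"]
    display_condition: Optional[BranchCondition] = None
    recode: Literal["none", "grandiosity1"] = "none"

    @model_validator(mode="after")
    def _role_condition_consistent(self) -> "ItemDef":
        if self.role == "branch" and self.display_condition is None:
            raise BankValidationError(f"branch item {self.item_id!r} lacks a display_condition")
        if self.role == "stem" and self.display_condition is not None:
            raise BankValidationError(f"stem item {self.item_id!r} must not have a display_condition")
        return self


class ScaleDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    scale_id: str
    name: str
    set: Literal[1, 2]
    interview_map: str
    items: tuple[ItemDef, ...]
    composite: Literal["none", "delusions_composite", "depression_composite"] = "none"

    @property
    def stem_count(self) -> int:
        return sum(1 for it in self.items if it.role == "stem")


class DelusionTemplate(BaseModel):
    model_config = ConfigDict(frozen=True)

    template_id: str
    statement: str
    sub_items: tuple[str, str, str]


@dataclass(frozen=True)
class DelusionSelection:
    """Per-participant personalisation: at most two currently held beliefs."""

    participant_id: str
    template_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.template_ids) > MAX_DELUSIONS:
            raise BankValidationError(
                f"at most {MAX_DELUSIONS} delusion templates may be configured per participant; "
                f"got {len(self.template_ids)} for {self.participant_id!r}"
            )
        if len(set(self.template_ids)) != len(self.template_ids):
            raise BankValidationError(f"duplicate delusion template ids for {self.participant_id!r}")


class ItemBank(BaseModel):
    model_config = ConfigDict(frozen=True)

    scales: tuple[ScaleDef, ...]
    delusion_templates: tuple[DelusionTemplate, ...]
    reactivity_items: tuple[str, str]

    def scales_in_set(self, set_number: int) -> tuple[ScaleDef, ...]:
        return tuple(s for s in self.scales if s.set == set_number)

    def scale(self, scale_id: str) -> ScaleDef:
        for s in self.scales:
            if s.scale_id == scale_id:
                return s
        raise KeyError(scale_id)

    def template(self, template_id: str) -> DelusionTemplate:
        for t in self.delusion_templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)


# ---------------------------------------------------------------------------
# Response-scale conversions


def analogue_to_likert(position: float) -> int:
    """Convert an analogue-slider position in [0, 1] to a 7-point Likert value.

    Seven equal-width bins: bin ``k`` covers ``[(k-1)/7, k/7)`` with the top
    bin closed on the right, so 0.0 -> 1 and 1.0 -> 7.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError(f"analogue position must lie in [0, 1], got {position!r}")
    return min(int(position * 7) + 1, 7)


_GRANDIOSITY1_MAP = {1: 1, 2: 1, 3: 1, 4: 1, 5: 2, 6: 3, 7: 4}


def recode_grandiosity1(response: int) -> int:
    """Recode the first grandiosity item so only grandiose appraisals score.

    The item asks for a self-comparison (worse - better); ratings at or below
    the midpoint carry no grandiose content, so 1-4 -> 1, 5 -> 2, 6 -> 3, 7 -> 4.
    """
    if response not in _GRANDIOSITY1_MAP:
        raise ValueError(f"likert response must be an integer in 1..7, got {response!r}")
    return _GRANDIOSITY1_MAP[response]


def evaluate_branch(condition: BranchCondition, session_responses: Mapping[str, int]) -> bool:
    """True iff the condition's source item was answered and the comparison holds.

    An unanswered (hidden or skipped) source evaluates false: the branch stays
    hidden.
    """
    value = session_responses.get(condition.source)
    if value is None:
        return False
    if condition.comparator == ">=":
        return value >= condition.threshold
    if condition.comparator == ">":
        return value > condition.threshold
    return value == condition.threshold


# ---------------------------------------------------------------------------
# Enumeration of question counts


def _delusion_block_items(template: DelusionTemplate) -> tuple[ItemDef, ...]:
    """Materialise one configured belief as 1 statement + 3 sub-item questions."""
    tid = template.template_id
    items = [ItemDef(item_id=f"{tid}__stmt", text=template.statement, role="stem")]
    suffixes = ("preoccupation", "distress", "impact")
    for suffix, text in zip(suffixes, template.sub_items):
        items.append(ItemDef(item_id=f"{tid}__{suffix}", text=text, role="stem"))
    return tuple(items)


def _set_items(bank: ItemBank, set_number: int) -> list[ItemDef]:
    out: list[ItemDef] = []
    for scale in bank.scales_in_set(set_number):
        out.extend(scale.items)
    return out


def _count_bounds(items: list[ItemDef]) -> tuple[int, int]:
    """Exact (min, max) displayed-question count over satisfiable branch outcomes.

    Depth-first enumeration over representative response values of every item
    that gates at least one condition; items are visited in presentation order
    so chained conditions resolve against already-decided sources.
    """
    conds_by_source: dict[str, list[BranchCondition]] = {}
    for it in items:
        if it.display_condition is not None:
            conds_by_source.setdefault(it.display_condition.source, []).append(it.display_condition)

    # One representative response per equivalence class of condition outcomes:
    # two values of a source are interchangeable when every condition
    # referencing it evaluates identically on them.
    sources: dict[str, set[int]] = {}
    for src, conds in conds_by_source.items():
        seen: dict[tuple[bool, ...], int] = {}
        for v in range(1, 8):
            key = tuple(evaluate_branch(c, {src: v}) for c in conds)
            seen.setdefault(key, v)
        sources[src] = set(seen.values())

    known_ids = {it.item_id for it in items}
    for src in sources:
        if src not in known_ids:
            raise BankValidationError(f"branch condition references unknown item {src!r}")

    best = [len(items) + 1, -1]  # min, max

    def walk(idx: int, responses: dict[str, int], shown: int) -> None:
        if idx == len(items):
            best[0] = min(best[0], shown)
            best[1] = max(best[1], shown)
            return
        it = items[idx]
        displayed = it.role == "stem" or evaluate_branch(it.display_condition, responses)
        if not displayed:
            walk(idx + 1, responses, shown)
            return
        if it.item_id in sources:
            for v in sorted(sources[it.item_id]):
                responses[it.item_id] = v
                walk(idx + 1, responses, shown + 1)
            del responses[it.item_id]
        else:
            walk(idx + 1, responses, shown + 1)

    walk(0, {}, 0)
    return best[0], best[1]


def enumerate_question_counts(bank: ItemBank, set_number: int) -> tuple[int, int]:
    """Exact min/max number of questions a session of the given set can present.

    Set 2 is additionally enumerated over 0, 1 and 2 configured delusions (each
    configured belief contributes a fixed block of 4 questions).  Reactivity
    items belong to no scale and are not counted.
    """
    if set_number not in (1, 2):
        raise ValueError("set_number must be 1 or 2")
    if set_number == 1:
        return _count_bounds(_set_items(bank, 1))
    base = [it for s in bank.scales_in_set(2) if s.scale_id != "delusions" for it in s.items]
    lo, hi = _count_bounds(base)
    configured = len(bank.scale("delusions").items)
    if configured:
        # Participant view: the configured blocks are always administered.
        return lo + configured, hi + configured
    block = 1 + DELUSION_SUB_ITEM_COUNT
    # Pristine bank: enumerate over 0, 1 and 2 configured beliefs.
    return lo, hi + MAX_DELUSIONS * block


# ---------------------------------------------------------------------------
# Loading and validation


def _validate_bank(bank: ItemBank) -> ItemBank:
    if len(bank.scales) != N_SCALES:
        raise BankValidationError(
            f"item bank must define exactly {N_SCALES} scales, got {len(bank.scales)}: "
            f"{sorted(s.scale_id for s in bank.scales)}"
        )
    seen = [s.scale_id for s in bank.scales]
    if len(set(seen)) != len(seen):
        raise BankValidationError(f"duplicate scale ids: {sorted(seen)}")

    set1 = {s.scale_id for s in bank.scales_in_set(1)}
    set2 = {s.scale_id for s in bank.scales_in_set(2)}
    if set1 != SET_1_SCALES:
        raise BankValidationError(
            f"set 1 must contain exactly {sorted(SET_1_SCALES)}; got {sorted(set1)}"
        )
    if set2 != SET_2_SCALES:
        raise BankValidationError(
            f"set 2 must contain exactly {sorted(SET_2_SCALES)}; got {sorted(set2)}"
        )

    if len(bank.delusion_templates) != N_DELUSION_TEMPLATES:
        raise BankValidationError(
            f"exactly {N_DELUSION_TEMPLATES} delusion templates required, "
            f"got {len(bank.delusion_templates)}"
        )

    # Branch sources must resolve to an *earlier* item in the same set: this
    # both forbids dangling references and makes condition cycles impossible.
    for set_number in (1, 2):
        preceding: set[str] = set()
        for scale in bank.scales_in_set(set_number):
            for it in scale.items:
                if it.display_condition is not None:
                    src = it.display_condition.source
                    if src not in preceding:
                        raise BankValidationError(
                            f"branch item {it.item_id!r} references source {src!r} "
                            f"which does not precede it in set {set_number}"
                        )
                preceding.add(it.item_id)

    all_item_ids = [it.item_id for s in bank.scales for it in s.items]
    if len(set(all_item_ids)) != len(all_item_ids):
        dupes = sorted({i for i in all_item_ids if all_item_ids.count(i) > 1})
        raise BankValidationError(f"duplicate item ids: {dupes}")

    lo1, hi1 = enumerate_question_counts(bank, 1)
    if (lo1, hi1) != SET_1_COUNT_RANGE:
        raise BankValidationError(
            f"set 1 question-count range must be {SET_1_COUNT_RANGE}, enumeration gives ({lo1}, {hi1})"
        )
    lo2, hi2 = enumerate_question_counts(bank, 2)
    if (lo2, hi2) != SET_2_COUNT_RANGE:
        raise BankValidationError(
            f"set 2 question-count range must be {SET_2_COUNT_RANGE}, enumeration gives ({lo2}, {hi2})"
        )
    return bank


def load_item_bank(document: str | dict) -> ItemBank:
    """Parse and validate an item-bank JSON document.

    Parameters
    ----------
    document:
        JSON text or an already-parsed mapping with top-level keys
        ``scales``, ``delusion_templates`` and ``reactivity_items``.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise BankValidationError(f"item-bank document is not valid JSON: {exc}") from exc
    payload = {k: document[k] for k in ("scales", "delusion_templates", "reactivity_items")}
    bank = ItemBank.model_validate(payload)
    return _validate_bank(bank)


def load_default_bank() -> ItemBank:
    """Load the packaged default instrument."""
    text = resources.files("emadiary.data").joinpath("default_bank.json").read_text("utf-8")
    return load_item_bank(text)


def configure_delusions(bank: ItemBank, selection: DelusionSelection) -> ItemBank:
    """Personalise the bank: populate the delusions scale from selected templates.

    Returns a participant view in which the delusions scale carries one
    (statement + 3 sub-items) block per selected template; all other scales are
    untouched.  With an empty selection the delusion block is absent from
    administration.
    """
    blocks: list[ItemDef] = []
    for tid in selection.template_ids:
        try:
            template = bank.template(tid)
        except KeyError:
            raise BankValidationError(f"unknown delusion template {tid!r}") from None
        blocks.extend(_delusion_block_items(template))

    new_scales = tuple(
        s.model_copy(update={"items": tuple(blocks)}) if s.scale_id == "delusions" else s
        for s in bank.scales
    )
    return bank.model_copy(update={"scales": new_scales})
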