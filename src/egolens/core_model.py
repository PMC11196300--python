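"""Domain types for single-ego social context data.

The data model mirrors a two-part assessment design: personal social
network (PSN) waves elicited before and after an experience-sampling
(ESM) period, signal-contingent momentary assessments, and
event-contingent interaction logs linked to network members (alters).

Invariants are *reported*, never raised: :func:`validate_dataset`
returns a list of issues so that partially broken field data can still
be inspected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Iterable, Optional

ROLES = (
    "family",
    "friend",
    "romantic_partner",
    "fellow_student_or_colleague",
    "acquaintance",
    "other",
)
GENDERS = ("female", "male", "other", "unknown")
ORIGINS = ("wave1", "esm", "wave2")
WAVE_LABELS = ("pre", "post")
PROMPT_KINDS = ("morning", "evening", "random")
INTERACTION_MODES = ("face_to_face", "video_call", "phone_call")

#: Dichotomous relationship items rated per alter.
FLAG_NAMES = (
    "gives_emotional_support",
    "gives_practical_support",
    "can_be_myself",
    "discuss_personal_issues",
)

#: Age is stored as decade brackets, not integers.
AGE_BRACKETS = ("<20", "20-29", "30-39", "40-49", "50-59", "60-69", "70+", "unknown")

#: Single registry for all rating scales (inclusive lo/hi). Closeness,
#: interaction quality and momentary affect share the 0-10 scale;
#: contact frequency is a 7-point ordinal.
SCALES: dict[str, tuple[float, float]] = {
    "closeness": (0, 10),
    "contact_freq": (0, 6),
    "quality": (0, 10),
    "affect": (0, 10),
    "company_perception": (0, 10),
}

#: Interactions shorter than this are not logged (event-contingent rule).
MIN_EVENT_DURATION_MIN = 5.0


@dataclass
class Alter:
    """One network member (an alter) with relationship ratings."""

    alter_id: str
    display_name: str
    role: str
    gender: str = "unknown"
    age_bracket: str = "unknown"
    closeness: Optional[int] = None
    contact_freq_in_person: Optional[int] = None
    contact_freq_online: Optional[int] = None
    flags: dict[str, bool] = field(default_factory=dict)
    origin: str = "wave1"

    def ordinal_ratings(self) -> dict[str, Optional[int]]:
        return {
            "closeness": self.closeness,
            "contact_freq_in_person": self.contact_freq_in_person,
            "contact_freq_online": self.contact_freq_online,
        }


def _norm_tie(pair: Iterable[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class NetworkWave:
    """Alters and undirected alter-alter ties at one assessment wave.

    Ties are stored as an order-normalised, sorted edge list so that two
    waves with the same tie set compare equal regardless of input order.
    Duplicates and self-loops are kept (validation reports them).
    """

    label: str
    date: Optional[date]
    alters: list[Alter] = field(default_factory=list)
    ties: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ties = sorted(_norm_tie(t) for t in self.ties)

    def alter_ids(self) -> set[str]:
        return {a.alter_id for a in self.alters}

    def get(self, alter_id: str) -> Optional[Alter]:
        for a in self.alters:
            if a.alter_id == alter_id:
                return a
        return None


@dataclass
class Prompt:
    """One scheduled signal-contingent assessment moment."""

    prompt_id: str
    day_index: int
    kind: str
    scheduled_time: datetime
    window_start: datetime
    window_end: datetime


@dataclass
class MomentaryResponse:
    """Answer (or non-answer) to one prompt.

    Non-compliance is an explicit record with ``response_time=None`` so
    the schedule denominator stays visible to compliance computations.
    """

    prompt_ref: str
    response_time: Optional[datetime] = None
    affect: dict[str, float] = field(default_factory=dict)
    alone: Optional[bool] = None
    company_perception: Optional[float] = None
    activities: list[str] = field(default_factory=list)

    @property
    def answered(self) -> bool:
        return self.response_time is not None


@dataclass
class InteractionEvent:
    """One participant-logged social interaction (> 5 minutes)."""

    event_id: str
    start_time: datetime
    mode: str
    duration_min: float
    location: str = ""
    is_group: bool = False
    category: str = ""
    content_text: str = ""
    quality: dict[str, float] = field(default_factory=dict)
    affect: dict[str, float] = field(default_factory=dict)
    partner_ids: list[str] = field(default_factory=list)


@dataclass
class ParticipantDataset:
    """Everything collected for one ego across the study."""

    participant_id: str
    waves: list[NetworkWave] = field(default_factory=list)
    schedule: list[Prompt] = field(default_factory=list)
    responses: list[MomentaryResponse] = field(default_factory=list)
    events: list[InteractionEvent] = field(default_factory=list)
    roster: list[Alter] = field(default_factory=list)

    def wave(self, label: str) -> Optional[NetworkWave]:
        for w in self.waves:
            if w.label == label:
                return w
        return None

    def roster_ids(self) -> set[str]:
        return {a.alter_id for a in self.roster}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    subject_id: str = ""


ValidationReport = list  # list[ValidationIssue]


def _check_scale(
    value: Optional[float], scale: str, code: str, subject: str, what: str
) -> list[ValidationIssue]:
    if value is None:
        return []
    lo, hi = SCALES[scale]
    if not (lo <= value <= hi):
        return [
            ValidationIssue(
                "error", code, f"{what} {value!r} outside {lo}-{hi}", subject
            )
        ]
    return []


def _validate_alter(alter: Alter, where: str) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    sid = alter.alter_id
    if alter.role not in ROLES:
        issues.append(
            ValidationIssue("error", "bad_role", f"unknown role {alter.role!r} in {where}", sid)
        )
    if alter.origin not in ORIGINS:
        issues.append(
            ValidationIssue("error", "bad_origin", f"unknown origin {alter.origin!r}", sid)
        )
    issues += _check_scale(alter.closeness, "closeness", "score_out_of_range", sid, f"closeness in {where}")
    issues += _check_scale(
        alter.contact_freq_in_person, "contact_freq", "score_out_of_range", sid, "in-person contact frequency"
    )
    issues += _check_scale(
        alter.contact_freq_online, "contact_freq", "score_out_of_range", sid, "online contact frequency"
    )
    for name, val in alter.flags.items():
        if not isinstance(val, bool):
            issues.append(
                ValidationIssue("error", "non_boolean_flag", f"flag {name!r} = {val!r} is not boolean", sid)
            )
    return issues


def _validate_wave(wave: NetworkWave) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    if wave.label not in WAVE_LABELS:
        issues.append(
            ValidationIssue("error", "bad_wave_label", f"unknown wave label {wave.label!r}", wave.label)
        )
    seen: set[str] = set()
    for alter in wave.alters:
        if alter.alter_id in seen:
            issues.append(
                ValidationIssue(
                    "error", "duplicate_alter_id",
                    f"alter id {alter.alter_id!r} duplicated in wave {wave.label!r}",
                    alter.alter_id,
                )
            )
        seen.add(alter.alter_id)
        issues += _validate_alter(alter, f"wave {wave.label!r}")
    ids = wave.alter_ids()
    tie_seen: set[tuple[str, str]] = set()
    for a, b in wave.ties:
        if a == b:
            issues.append(
                ValidationIssue("error", "self_loop_tie", f"self-loop tie on {a!r} in wave {wave.label!r}", a)
            )
            continue
        if (a, b) in tie_seen:
            issues.append(
                ValidationIssue("error", "duplicate_tie", f"duplicate tie {a!r}-{b!r} in wave {wave.label!r}", a)
            )
        tie_seen.add((a, b))
        for end in (a, b):
            if end not in ids:
                issues.append(
                    ValidationIssue(
                        "error", "dangling_tie_endpoint",
                        f"tie endpoint {end!r} not in wave {wave.label!r}", end,
                    )
                )
    return issues


def validate_dataset(dataset: ParticipantDataset) -> ValidationReport:
    """Check every structural invariant; return all violations found.

    Pure: the dataset is never modified and repeated calls yield the
    same report. An empty report means the dataset is internally
    consistent.
    """
    issues: list[ValidationIssue] = []

    seen: set[str] = set()
    for alter in dataset.roster:
        if alter.alter_id in seen:
            issues.append(
                ValidationIssue("error", "duplicate_alter_id",
                                f"alter id {alter.alter_id!r} duplicated in roster", alter.alter_id)
            )
        seen.add(alter.alter_id)
        issues += _validate_alter(alter, "roster")
    roster_ids = dataset.roster_ids()

    labels_seen: set[str] = set()
    for wave in dataset.waves:
        if wave.label in labels_seen:
            issues.append(
                ValidationIssue("error", "duplicate_wave_label",
                                f"more than one wave labelled {wave.label!r}", wave.label)
            )
        labels_seen.add(wave.label)
        issues += _validate_wave(wave)

    prompt_ids = {p.prompt_id for p in dataset.schedule}
    for p in dataset.schedule:
        if not (p.window_start <= p.scheduled_time <= p.window_end):
            issues.append(
                ValidationIssue("error", "prompt_outside_window",
                                f"prompt {p.prompt_id!r} scheduled outside its window", p.prompt_id)
            )
        if p.kind not in PROMPT_KINDS:
            issues.append(
                ValidationIssue("error", "bad_prompt_kind",
                                f"unknown prompt kind {p.kind!r}", p.prompt_id)
            )

    for r in dataset.responses:
        if r.prompt_ref not in prompt_ids:
            issues.append(
                ValidationIssue("error", "dangling_prompt_ref",
                                f"response references unknown prompt {r.prompt_ref!r}", r.prompt_ref)
            )
        for item, score in r.affect.items():
            issues += _check_scale(score, "affect", "score_out_of_range", r.prompt_ref, f"affect {item!r}")
        if r.answered and r.company_perception is None:
            issues.append(
                ValidationIssue("error", "missing_company_perception",
                                f"answered prompt {r.prompt_ref!r} lacks company perception", r.prompt_ref)
            )
        if not r.answered and r.company_perception is not None:
            issues.append(
                ValidationIssue("error", "company_without_response",
                                f"unanswered prompt {r.prompt_ref!r} carries company perception", r.prompt_ref)
            )
        issues += _check_scale(
            r.company_perception, "company_perception", "score_out_of_range", r.prompt_ref, "company perception"
        )

    event_ids: set[str] = set()
    for e in dataset.events:
        if e.event_id in event_ids:
            issues.append(
                ValidationIssue("error", "duplicate_event_id", f"event id {e.event_id!r} duplicated", e.event_id)
            )
        event_ids.add(e.event_id)
        if not e.partner_ids:
            issues.append(
                ValidationIssue("error", "empty_partner_list",
                                f"event {e.event_id!r} has no interaction partner", e.event_id)
            )
        for pid in e.partner_ids:
            if pid not in roster_ids:
                issues.append(
                    ValidationIssue("error", "dangling_partner",
                                    f"event {e.event_id!r} references unknown partner {pid!r}", e.event_id)
                )
        if e.mode not in INTERACTION_MODES:
            issues.append(
                ValidationIssue("error", "bad_mode", f"unknown interaction mode {e.mode!r}", e.event_id)
            )
        if e.duration_min < MIN_EVENT_DURATION_MIN:
            issues.append(
                ValidationIssue("error", "short_duration",
                                f"event {e.event_id!r} shorter than the {MIN_EVENT_DURATION_MIN:g}-minute logging rule",
                                e.event_id)
            )
        for item, score in e.quality.items():
            issues += _check_scale(score, "quality", "score_out_of_range", e.event_id, f"quality {item!r}")
        for item, score in e.affect.items():
            issues += _check_scale(score, "affect", "score_out_of_range", e.event_id, f"affect {item!r}")

    if dataset.schedule:
        span_start = min(p.window_start for p in dataset.schedule) - timedelta(days=1)
        span_end = max(p.window_end for p in dataset.schedule) + timedelta(days=1)
        for e in dataset.events:
            if not (span_start <= e.start_time <= span_end):
                issues.append(
                    ValidationIssue("warning", "timestamp_out_of_span",
                                    f"event {e.event_id!r} outside the assessment period", e.event_id)
                )
        for r in dataset.responses:
            if r.response_time is not None and not (span_start <= r.response_time <= span_end):
                issues.append(
                    ValidationIssue("warning", "timestamp_out_of_span",
                                    f"response to {r.prompt_ref!r} outside the assessment period", r.prompt_ref)
                )
    return issues


_WS = re.compile(r"\s+")


def normalise_name(name: str) -> str:
    """Case-insensitive, whitespace-collapsed canonical form of a name."""
    return _WS.sub(" ", name.strip()).casefold()


def _next_alter_id(dataset: ParticipantDataset) -> str:
    existing = dataset.roster_ids()
    n = len(existing) + 1
    while f"a{n:03d}" in existing:
        n += 1
    return f"a{n:03d}"


def register_partner(
    dataset: ParticipantDataset, name: str, at: Optional[datetime] = None
) -> tuple[ParticipantDataset, str]:
    """Resolve an interaction-partner name against the roster.

    Names typed during ESM are matched case-insensitively with collapsed
    whitespace; an unseen name appends a new alter with ``origin="esm"``
    and role ``other`` (to be rated at the post-ESM network assessment)
    and is kept for all future assessments. Matching is exact after
    normalisation — no fuzzy merging.

    Returns the (mutated) dataset and the alter id the name resolved to.
    """
    if not name or not name.strip():
        raise ValueError("partner name must be non-empty")
    key = normalise_name(name)
    for alter in dataset.roster:
        if normalise_name(alter.display_name) == key:
            return dataset, alter.alter_id
    new = Alter(
        alter_id=_next_alter_id(dataset),
        display_name=_WS.sub(" ", name.strip()),
        role="other",
        origin="esm",
    )
    dataset.roster.append(new)
    return dataset, new.alter_id


def copy_alter(alter: Alter) -> Alter:
    """Deep-enough copy (flags dict duplicated)."""
    return replace(alter, flags=dict(alter.flags))
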