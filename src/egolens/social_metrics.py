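"""Every statistic shown in the feedback report.

Composition and structure of the personal network, interaction counts
and quality summaries per social role and per partner (with 95%
confidence intervals around the mean), the affect/interaction timeline,
the perception-vs-behaviour table, and content-term frequencies for the
word cloud.

Conventions
-----------
* A multi-partner (group) event counts once for *every* listed partner
  and once for each partner's role, so per-partner counts sum to more
  than the number of events whenever group events exist. Only one-on-one
  events keep the sums equal.
* Confidence intervals are two-sided t-intervals
  ``mean ± t(0.975, n-1) · s/√n`` by default (normal approximation by
  config); groups with fewer than two observations get no interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stopwords import STOPWORDS, TALKING_VERBS
from .core_model import ROLES, Alter, InteractionEvent, MomentaryResponse, NetworkWave


# ---------------------------------------------------------------- composition

def role_composition(wave: NetworkWave) -> dict[str, int]:
    """Number of network members per social role; zero roles included."""
    counts = {role: 0 for role in ROLES}
    for alter in wave.alters:
        counts[alter.role] = counts.get(alter.role, 0) + 1
    return counts


# --------------------------------------------------------------------- counts

def _role_of(roster_map: dict[str, Alter], alter_id: str) -> str:
    alter = roster_map.get(alter_id)
    return alter.role if alter else "other"


def interaction_counts(
    events: Sequence[InteractionEvent],
    roster: Sequence[Alter],
    by: str = "role",
) -> dict[str, int]:
    """Interaction counts per role or per partner.

    Every roster member (or every role) appears, with 0 when never
    involved. Each event increments every listed partner once; per-role
    counting increments the role once per listed partner of that role.
    """
    roster_map = {a.alter_id: a for a in roster}
    if by == "role":
        counts: dict[str, int] = {role: 0 for role in ROLES}
        for e in events:
            for pid in e.partner_ids:
                counts[_role_of(roster_map, pid)] += 1
        return counts
    if by == "partner":
        counts = {a.alter_id: 0 for a in roster}
        for e in events:
            for pid in e.partner_ids:
                counts[pid] = counts.get(pid, 0) + 1
        return counts
    raise ValueError(f"unknown grouping {by!r} (expected 'role' or 'partner')")


# -------------------------------------------------------------------- quality

@dataclass
class QualitySummary:
    group_key: str
    indicator: str
    points: list[float]
    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def n(self) -> int:
        return len(self.points)


def _interval(points: np.ndarray, method: str) -> tuple[Optional[float], Optional[float]]:
    n = len(points)
    if n < 2:
        return None, None
    m = float(points.mean())
    s = float(points.std(ddof=1))
    crit = stats.t.ppf(0.975, n - 1) if method == "t" else stats.norm.ppf(0.975)
    half = crit * s / np.sqrt(n)
    return m - half, m + half


def known_indicators(events: Sequence[InteractionEvent]) -> list[str]:
    names: set[str] = set()
    for e in events:
        names.update(e.quality)
    return sorted(names)


def quality_summary(
    events: Sequence[InteractionEvent],
    roster: Sequence[Alter],
    by: str = "role",
    indicator: str = "meaningfulness",
    method: str = "t",
) -> list[QualitySummary]:
    """Per-group raw quality points, mean, and 95% CI around the mean.

    Groups are ordered by descending n, then by group key, so the most
    frequently contacted partners come first in the report.
    """
    if events and indicator not in set(known_indicators(events)):
        raise KeyError(f"unknown quality indicator {indicator!r}")
    roster_map = {a.alter_id: a for a in roster}
    groups: dict[str, list[float]] = {}
    for e in events:
        if indicator not in e.quality:
            continue
        score = e.quality[indicator]
        keys = (
            {_role_of(roster_map, pid) for pid in e.partner_ids}
            if by == "role"
            else set(e.partner_ids)
        )
        for key in keys:
            groups.setdefault(key, []).append(score)

    out: list[QualitySummary] = []
    for key in sorted(groups, key=lambda k: (-len(groups[k]), k)):
        pts = np.asarray(groups[key], dtype=float)
        lo, hi = _interval(pts, method)
        out.append(
            QualitySummary(
                group_key=key, indicator=indicator, points=list(groups[key]),
                mean=float(pts.mean()), ci_low=lo, ci_high=hi,
            )
        )
    return out


# ------------------------------------------------------------------- timeline

@dataclass
class AffectPoint:
    time: datetime
    value: float
    source: str  # "prompt" | "event"


@dataclass
class EventPoint:
    time: datetime
    value: float
    role: str
    is_group: bool
    partner_ids: list[str]
    event_id: str


@dataclass
class TimelinePayload:
    affect_item: str
    indicator: str
    affect_series: list[AffectPoint] = field(default_factory=list)
    event_points: list[EventPoint] = field(default_factory=list)


def known_affect_items(
    responses: Sequence[MomentaryResponse], events: Sequence[InteractionEvent]
) -> list[str]:
    names: set[str] = set()
    for r in responses:
        names.update(r.affect)
    for e in events:
        names.update(e.affect)
    return sorted(names)


def affect_timeline(
    responses: Sequence[MomentaryResponse],
    events: Sequence[InteractionEvent],
    affect_item: str = "happiness",
    indicator: str = "meaningfulness",
    partner_filter: Optional[set[str]] = None,
    roster: Sequence[Alter] = (),
    schedule_times: Optional[dict[str, datetime]] = None,
) -> TimelinePayload:
    """Merge momentary affect with interaction events into one timeline.

    Affect comes from both answered prompts and event-level assessments,
    each point tagged with its source. A partner filter restricts the
    event points to events involving at least one filtered partner; the
    affect line is never filtered. Response times index prompt-level
    affect; unanswered prompts contribute nothing.
    """
    if (responses or events) and affect_item not in known_affect_items(responses, events):
        raise KeyError(f"unknown affect item {affect_item!r}")
    if events and indicator not in known_indicators(events):
        raise KeyError(f"unknown quality indicator {indicator!r}")
    roster_map = {a.alter_id: a for a in roster}

    affect: list[AffectPoint] = []
    for r in responses:
        if r.answered and affect_item in r.affect:
            affect.append(AffectPoint(time=r.response_time, value=r.affect[affect_item], source="prompt"))
    for e in events:
        if affect_item in e.affect:
            affect.append(AffectPoint(time=e.start_time, value=e.affect[affect_item], source="event"))
    affect.sort(key=lambda p: p.time)

    points: list[EventPoint] = []
    for e in events:
        if indicator not in e.quality:
            continue
        if partner_filter is not None and not (set(e.partner_ids) & partner_filter):
            continue
        points.append(
            EventPoint(
                time=e.start_time,
                value=e.quality[indicator],
                role=_role_of(roster_map, e.partner_ids[0]) if e.partner_ids else "other",
                is_group=e.is_group,
                partner_ids=list(e.partner_ids),
                event_id=e.event_id,
            )
        )
    points.sort(key=lambda p: p.time)
    return TimelinePayload(
        affect_item=affect_item, indicator=indicator,
        affect_series=affect, event_points=points,
    )


def interaction_detail(
    events: Sequence[InteractionEvent],
    event_id: str,
    roster: Sequence[Alter] = (),
) -> dict:
    """Full record of one logged interaction, for click-to-detail.

    Partner names are looked up from the roster as stored, so a
    pseudonymised dataset yields pseudonymous detail records.
    """
    roster_map = {a.alter_id: a for a in roster}
    for e in events:
        if e.event_id == event_id:
            return {
                "event_id": e.event_id,
                "start_time": e.start_time,
                "mode": e.mode,
                "duration_min": e.duration_min,
                "location": e.location,
                "is_group": e.is_group,
                "category": e.category,
                "content_text": e.content_text,
                "quality": dict(e.quality),
                "affect": dict(e.affect),
                "partner_ids": list(e.partner_ids),
                "partner_names": [
                    roster_map[p].display_name if p in roster_map else p for p in e.partner_ids
                ],
            }
    raise KeyError(f"unknown event id {event_id!r}")


# -------------------------------------------------- perception vs. behaviour

def perception_behavior_table(
    wave: NetworkWave,
    events: Sequence[InteractionEvent],
    closeness_quantile: float = 2 / 3,
    max_interactions: int = 0,
) -> pd.DataFrame:
    """Compare rated closeness with actual daily-life interaction.

    One row per wave alter: closeness, support flags, interaction count,
    mean quality across all indicators, and a discrepancy flag set when
    the alter sits in the top tercile of the wave's closeness ratings
    but was interacted with at most ``max_interactions`` times — the
    "good relationship, never reaches out" pattern. The rule's threshold
    is configurable; every input is echoed so users can judge for
    themselves.
    """
    counts = interaction_counts(events, wave.alters, by="partner")
    qsum: dict[str, list[float]] = {a.alter_id: [] for a in wave.alters}
    for e in events:
        scores = list(e.quality.values())
        if not scores:
            continue
        for pid in e.partner_ids:
            if pid in qsum:
                qsum[pid].extend(scores)

    clos = [a.closeness for a in wave.alters if a.closeness is not None]
    threshold = float(np.quantile(clos, closeness_quantile)) if clos else np.inf

    rows = []
    for a in wave.alters:
        n = counts.get(a.alter_id, 0)
        scores = qsum[a.alter_id]
        rows.append(
            {
                "alter_id": a.alter_id,
                "display_name": a.display_name,
                "role": a.role,
                "closeness": a.closeness,
                **{flag: a.flags.get(flag) for flag in sorted(a.flags)},
                "n_interactions": n,
                "mean_quality": float(np.mean(scores)) if scores else np.nan,
                "discrepancy": (
                    a.closeness is not None
                    and a.closeness >= threshold
                    and n <= max_interactions
                ),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ structure

@dataclass
class StructureResult:
    isolates: list[str]
    components: list[list[str]]  # sorted by size desc, then smallest id


def network_structure(wave: NetworkWave) -> StructureResult:
    """Connected components and isolates of the alter-alter tie graph."""
    g = nx.Graph()
    g.add_nodes_from(a.alter_id for a in wave.alters)
    g.add_edges_from(t for t in wave.ties if t[0] != t[1])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return StructureResult(
        isolates=sorted(nx.isolates(g)),
        components=comps,
    )


# ------------------------------------------------------------ word frequency

_TOKEN = re.compile(r"[^\W\d_]+", re.UNICODE)


def word_frequencies(
    events: Sequence[InteractionEvent],
    stopwords: Optional[Iterable[str]] = None,
    extra_exclusions: Optional[Iterable[str]] = None,
    language: str = "en",
) -> list[tuple[str, int]]:
    """Term frequencies over interaction descriptions, for the word cloud.

    Unicode word tokens, lowercased, no stemming. Common stop words and
    verbs for the activity of talking are removed (explicit lists
    override the shipped ``language`` defaults). Sorted by descending
    count, ties alphabetical.
    """
    stop = set(stopwords) if stopwords is not None else set(STOPWORDS[language])
    stop |= set(extra_exclusions) if extra_exclusions is not None else set(TALKING_VERBS)
    counts: dict[str, int] = {}
    for e in events:
        for token in _TOKEN.findall(e.content_text.lower()):
            if token in stop:
                continue
            counts[token] = counts.get(token, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
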