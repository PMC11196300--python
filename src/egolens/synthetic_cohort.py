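"""Fully synthetic single-participant datasets with known ground truth.

The simulator emulates the data-collection design the feedback assumes:
a role-structured personal network (10-80 alters, default 42), a 28-day
signal-contingent prompt schedule, event-contingent interaction logs
with per-partner quality ratings, and momentary affect coupled to
recent interaction quality through a first-order autoregressive model

    a_t = b + phi * (a_{t-1} - b) + gamma * (qbar_t - 5) + eps_t

where ``qbar_t`` is the mean quality of interactions since the previous
prompt (the coupling term is dropped when there were none) and
``eps_t ~ N(0, noise_sd)``.

Each alter i carries an integer latent quality mean ``mu_i`` in [0, 10]
derived from closeness; event quality scores are drawn from
``N(mu, sigma)``, clamped to [0, 10] and rounded to integers (matching
the granularity of a 0-10 rating). Scenario flags reproduce the
narratives the feedback is designed to reveal: a mid-study break-up
(romantic partner re-categorised as friend), network growth during ESM
(new partners first encountered in the interaction diary), additions at
the post assessment, and removals.

Everything is driven by one seeded generator, so a config maps to
exactly one dataset, byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import (
    AGE_BRACKETS,
    FLAG_NAMES,
    Alter,
    InteractionEvent,
    MomentaryResponse,
    NetworkWave,
    ParticipantDataset,
    copy_alter,
)
from .sampling_schedule import ScheduleConfig, generate_schedule
from .social_metrics import quality_summary

_FIRST_NAMES = (
    "Anna Bram Carlijn Daan Emma Floris Gwen Hugo Iris Jesse Kim Lars Mara "
    "Nina Otto Pim Quinn Rosa Sem Tess Umut Vera Wout Xander Yara Zoe Adam "
    "Britt Chris Dana Elias Femke Gijs Hanna Ivo Julia Koen Lotte Mila Noor "
    "Olaf Pia Ruben Sara Timo Ulla Victor Willem Xenia Yusuf"
).split()

_LOCATIONS = ("home", "campus", "cafe", "park", "work", "gym", "online")
_CATEGORIES = ("catch_up", "studying", "meal", "leisure", "practical", "deep_talk")
_ACTIVITIES = ("studying", "working", "relaxing", "commuting", "sports", "chores", "media")

#: Topic vocabulary for diary text; weights give the heavy head the
#: word cloud is meant to surface (food, plans, going somewhere).
_TOPICS = (
    ("food", 0.16), ("plans", 0.13), ("going", 0.11), ("music", 0.07),
    ("travel", 0.07), ("thesis", 0.06), ("movie", 0.06), ("dinner", 0.06),
    ("coffee", 0.06), ("party", 0.05), ("work", 0.05), ("holiday", 0.05),
    ("football", 0.04), ("concert", 0.035), ("weekend", 0.035),
)
_TALK_VERBS = ("talked", "chatted", "spoke")

_ROLE_CLOSENESS = {
    "family": 7.0,
    "friend": 6.0,
    "romantic_partner": 9.0,
    "fellow_student_or_colleague": 4.0,
    "acquaintance": 2.0,
    "other": 3.0,
}

_DEFAULT_ROLE_DIST = {
    "friend": 0.46,
    "family": 0.24,
    "fellow_student_or_colleague": 0.15,
    "acquaintance": 0.13,
    "other": 0.02,
}

_DEFAULT_WITHIN_DENSITY = {
    "family": 0.80,
    "friend": 0.35,
    "romantic_partner": 0.50,
    "fellow_student_or_colleague": 0.30,
    "acquaintance": 0.10,
    "other": 0.05,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of one simulated participant."""

    seed: int = 0
    n_alters: int = 42
    n_days: int = 28
    n_random_prompts: int = 4
    role_distribution: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ROLE_DIST))
    within_role_tie_density: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WITHIN_DENSITY)
    )
    between_role_tie_density: float = 0.04
    quality_sd: float = 1.5
    interactions_per_day: float = 3.0
    partner_temperature: float = 2.0
    group_event_prob: float = 0.2
    affect_baseline: float = 7.0
    affect_autocorr: float = 0.5
    affect_coupling: float = 0.3
    affect_noise_sd: float = 1.0
    coupling_indicator: str = "enjoyment"
    quality_indicators: tuple[str, ...] = ("meaningfulness", "enjoyment")
    compliance_prob: float = 0.85
    breakup: bool = False
    growth: int = 0
    growth_post: int = 0
    removals: int = 0

    def validate(self) -> None:
        if not (10 <= self.n_alters <= 80):
            raise ValueError("n_alters must be within 10-80")
        if abs(sum(self.role_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("role_distribution must sum to 1")
        if not (0 <= self.affect_autocorr < 1):
            raise ValueError("affect autocorrelation must be in [0, 1)")
        for d in (*self.within_role_tie_density.values(), self.between_role_tie_density):
            if not (0 <= d <= 1):
                raise ValueError("tie densities must be in [0, 1]")
        if self.quality_sd < 0 or self.interactions_per_day < 0:
            raise ValueError("quality_sd and interactions_per_day must be >= 0")
        if self.coupling_indicator not in self.quality_indicators:
            raise ValueError("coupling_indicator must be one of quality_indicators")


@dataclass
class SimulationTruth:
    """Latent quantities the feedback statistics should recover."""

    latent_quality: dict[str, int]  # alter_id -> mu_i
    entry_day: dict[str, int]  # ESM-growth alters: study day of first encounter
    breakup_day: Optional[int]
    removed_ids: list[str]


def _clip_int(x: float, lo: float = 0, hi: float = 10) -> int:
    return int(np.clip(round(x), lo, hi))


def _make_name(rng, used: set[str]) -> str:
    while True:
        name = f"{_FIRST_NAMES[rng.integers(len(_FIRST_NAMES))]} {chr(65 + rng.integers(26))}."
        if name not in used:
            used.add(name)
            return name


def _make_alter(rng, alter_id: str, role: str, origin: str, used_names: set[str]) -> Alter:
    closeness = _clip_int(_ROLE_CLOSENESS[role] + rng.normal(0, 1.5))
    p_flag = closeness / 12
    return Alter(
        alter_id=alter_id,
        display_name=_make_name(rng, used_names),
        role=role,
        gender=("female", "male", "other")[rng.choice(3, p=[0.48, 0.48, 0.04])],
        age_bracket=AGE_BRACKETS[rng.choice(len(AGE_BRACKETS) - 1, p=[0.25, 0.45, 0.1, 0.08, 0.06, 0.04, 0.02])],
        closeness=closeness,
        contact_freq_in_person=int(rng.integers(0, 7)),
        contact_freq_online=int(rng.integers(0, 7)),
        flags={name: bool(rng.random() < p_flag) for name in FLAG_NAMES},
        origin=origin,
    )


def _latent_mu(rng, closeness: Optional[int]) -> int:
    c = 5 if closeness is None else closeness
    return _clip_int(1.5 + 0.7 * c + rng.normal(0, 0.8), 0, 10)


def _sentence(rng) -> str:
    words, probs = zip(*_TOPICS)
    probs = np.asarray(probs) / sum(probs)
    t1, t2 = rng.choice(words, size=2, replace=False, p=probs)
    verb = _TALK_VERBS[rng.integers(len(_TALK_VERBS))]
    templates = (
        f"{verb} about {t1} and made {t2}",
        f"{verb} about {t1} then {t2}",
        f"we {verb} about the {t1} and about {t2}",
    )
    return templates[rng.integers(len(templates))]


def simulate_with_truth(config: SimulationConfig) -> tuple[ParticipantDataset, SimulationTruth]:
    """Generate one participant dataset plus its latent ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    used_names: set[str] = set()

    # --- pre-wave roster -------------------------------------------------
    roles_pool = list(config.role_distribution)
    probs = np.asarray([config.role_distribution[r] for r in roles_pool])
    roles = [roles_pool[i] for i in rng.choice(len(roles_pool), size=config.n_alters, p=probs)]
    if config.breakup and "romantic_partner" not in roles:
        roles[roles.index("friend") if "friend" in roles else 0] = "romantic_partner"
    seen_partner = False  # at most one romantic partner
    for i, r in enumerate(roles):
        if r == "romantic_partner":
            if seen_partner:
                roles[i] = "friend"
            seen_partner = True

    pre_alters = [
        _make_alter(rng, f"a{i + 1:03d}", role, "wave1", used_names)
        for i, role in enumerate(roles)
    ]
    partner_alter = next((a for a in pre_alters if a.role == "romantic_partner"), None)

    # --- ties (role-clustered) -------------------------------------------
    ties: list[tuple[str, str]] = []
    for i in range(len(pre_alters)):
        for j in range(i + 1, len(pre_alters)):
            a, b = pre_alters[i], pre_alters[j]
            if a.role == b.role:
                p = config.within_role_tie_density.get(a.role, 0.2)
            else:
                p = config.between_role_tie_density
            if rng.random() < p:
                ties.append((a.alter_id, b.alter_id))

    start = ScheduleConfig(seed=config.seed, n_days=config.n_days,
                           n_random=config.n_random_prompts)
    pre_wave = NetworkWave(
        label="pre", date=start.start_date - timedelta(days=1),
        alters=[copy_alter(a) for a in pre_alters], ties=ties,
    )

    # --- latent interaction quality --------------------------------------
    latent: dict[str, int] = {a.alter_id: _latent_mu(rng, a.closeness) for a in pre_alters}

    # --- growth: partners first encountered during ESM --------------------
    growth_alters: list[Alter] = []
    entry_day: dict[str, int] = {}
    for k in range(config.growth):
        aid = f"a{config.n_alters + k + 1:03d}"
        alter = Alter(
            alter_id=aid,
            display_name=_make_name(rng, used_names),
            role="other",
            gender=("female", "male", "other")[rng.choice(3, p=[0.48, 0.48, 0.04])],
            age_bracket=AGE_BRACKETS[int(rng.integers(0, 3))],
            origin="esm",
        )
        growth_alters.append(alter)
        entry_day[aid] = int(rng.integers(1, config.n_days + 1))
        latent[aid] = _latent_mu(rng, None)

    schedule = generate_schedule(start)
    tz = start.tz
    day0 = start.start_date
    breakup_day = config.n_days // 2 if config.breakup else None

    # components of the pre-wave graph, for co-occurring group partners
    g = nx.Graph()
    g.add_nodes_from(a.alter_id for a in pre_alters)
    g.add_edges_from(ties)
    comp_of: dict[str, list[str]] = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        for aid in members:
            comp_of[aid] = [m for m in members if m != aid]

    # --- events ------------------------------------------------------------
    def _closeness_eff(aid: str, day: int) -> float:
        alter = next((a for a in pre_alters if a.alter_id == aid), None)
        if alter is None:
            return 5.0
        if breakup_day and alter.role == "romantic_partner" and day >= breakup_day:
            return 3.0
        return float(alter.closeness if alter.closeness is not None else 5.0)

    events: list[InteractionEvent] = []
    eid = 0

    def _emit(day: int, minute: float, partners: list[str]) -> None:
        nonlocal eid
        eid += 1
        mu = float(np.mean([latent[p] for p in partners]))
        quality = {
            ind: _clip_int(rng.normal(mu, config.quality_sd)) if config.quality_sd > 0 else _clip_int(mu)
            for ind in config.quality_indicators
        }
        q_c = quality[config.coupling_indicator]
        affect_val = round(
            float(np.clip(
                config.affect_baseline
                + config.affect_coupling * (q_c - 5)
                + rng.normal(0, config.affect_noise_sd),
                0, 10,
            )), 1,
        )
        when = datetime.combine(day0 + timedelta(days=day - 1), time(0, 0), tz) + timedelta(
            minutes=minute
        )
        events.append(
            InteractionEvent(
                event_id=f"e{eid:04d}",
                start_time=when,
                mode=("face_to_face", "video_call", "phone_call")[rng.choice(3, p=[0.7, 0.1, 0.2])],
                duration_min=float(5 + int(rng.exponential(25))),
                location=_LOCATIONS[rng.integers(len(_LOCATIONS))],
                is_group=len(partners) > 1,
                category=_CATEGORIES[rng.integers(len(_CATEGORIES))],
                content_text=_sentence(rng),
                quality={k: float(v) for k, v in quality.items()},
                affect={"happiness": affect_val},
                partner_ids=partners,
            )
        )

    for day in range(1, config.n_days + 1):
        # each growth alter is first met through a forced solo interaction
        for aid, d in entry_day.items():
            if d == day:
                _emit(day, float(rng.uniform(9 * 60, 22 * 60)), [aid])
        eligible = [a.alter_id for a in pre_alters] + [
            aid for aid, d in entry_day.items() if d <= day
        ]
        weights = np.asarray(
            [math.exp(_closeness_eff(aid, day) / config.partner_temperature) for aid in eligible]
        )
        weights = weights / weights.sum()
        for _ in range(rng.poisson(config.interactions_per_day)):
            minute = float(rng.uniform(9 * 60, 22 * 60))
            primary = eligible[rng.choice(len(eligible), p=weights)]
            partners = [primary]
            if rng.random() < config.group_event_prob:
                pool = comp_of.get(primary, [])
                if pool:
                    k = int(rng.integers(1, min(3, len(pool)) + 1))
                    extra = rng.choice(len(pool), size=k, replace=False)
                    partners += [pool[i] for i in sorted(extra)]
            _emit(day, minute, partners)
    events.sort(key=lambda e: (e.start_time, e.event_id))

    # --- momentary responses (AR(1) affect with quality coupling) ----------
    responses: list[MomentaryResponse] = []
    prompts = sorted(schedule, key=lambda p: p.scheduled_time)
    mood = config.affect_baseline
    last_time = prompts[0].scheduled_time - timedelta(hours=12)
    for prompt in prompts:
        window = [
            e for e in events if last_time < e.start_time <= prompt.scheduled_time
        ]
        qbar = (
            float(np.mean([e.quality[config.coupling_indicator] for e in window]))
            if window
            else None
        )
        shock = config.affect_coupling * (qbar - 5) if qbar is not None else 0.0
        mood = (
            config.affect_baseline
            + config.affect_autocorr * (mood - config.affect_baseline)
            + shock
            + rng.normal(0, config.affect_noise_sd)
        )
        answered = bool(rng.random() < config.compliance_prob)
        if answered:
            happiness = round(float(np.clip(mood, 0, 10)), 1)
            relaxed = round(float(np.clip(mood + rng.normal(0, 0.8), 0, 10)), 1)
            acts = rng.choice(len(_ACTIVITIES), size=int(rng.integers(1, 3)), replace=False)
            responses.append(
                MomentaryResponse(
                    prompt_ref=prompt.prompt_id,
                    response_time=prompt.scheduled_time + timedelta(minutes=float(rng.uniform(0, 10))),
                    affect={"happiness": happiness, "relaxed": relaxed},
                    alone=not window,
                    company_perception=round(float(np.clip(rng.normal(7, 1.5), 0, 10)), 1),
                    activities=[_ACTIVITIES[i] for i in sorted(acts)],
                )
            )
        else:
            responses.append(MomentaryResponse(prompt_ref=prompt.prompt_id))
        last_time = prompt.scheduled_time

    # --- post wave ----------------------------------------------------------
    removable = [
        a.alter_id for a in pre_alters if a.role in ("acquaintance", "other")
    ] or [a.alter_id for a in pre_alters if a.role != "romantic_partner"]
    removed_ids = sorted(
        removable[i] for i in rng.choice(len(removable), size=min(config.removals, len(removable)), replace=False)
    )

    post_alters: list[Alter] = []
    for a in pre_alters:
        if a.alter_id in removed_ids:
            continue
        snap = copy_alter(a)
        if partner_alter is not None and config.breakup and a.alter_id == partner_alter.alter_id:
            snap.role = "friend"
            snap.closeness = _clip_int((snap.closeness or 5) - 3)
        elif rng.random() < 0.25 and snap.closeness is not None:
            snap.closeness = _clip_int(snap.closeness + rng.choice([-1, 1]))
        post_alters.append(snap)
    for a in growth_alters:
        snap = copy_alter(a)
        snap.role = ("friend", "acquaintance", "other")[rng.choice(3, p=[0.6, 0.3, 0.1])]
        snap.closeness = _clip_int(rng.normal(5, 2))
        snap.contact_freq_in_person = int(rng.integers(0, 7))
        snap.contact_freq_online = int(rng.integers(0, 7))
        p_flag = snap.closeness / 12
        snap.flags = {name: bool(rng.random() < p_flag) for name in FLAG_NAMES}
        post_alters.append(snap)
    wave2_alters: list[Alter] = []
    for k in range(config.growth_post):
        aid = f"a{config.n_alters + config.growth + k + 1:03d}"
        alter = _make_alter(rng, aid, "acquaintance", "wave2", used_names)
        wave2_alters.append(alter)
        post_alters.append(copy_alter(alter))

    post_ids = {a.alter_id for a in post_alters}
    post_ties = [t for t in ties if t[0] in post_ids and t[1] in post_ids]
    existing = [a.alter_id for a in pre_alters if a.alter_id in post_ids]
    for a in growth_alters + wave2_alters:
        for _ in range(int(rng.integers(0, 3))):
            other = existing[rng.integers(len(existing))]
            pair = tuple(sorted((a.alter_id, other)))
            if pair not in post_ties:
                post_ties.append(pair)

    post_wave = NetworkWave(
        label="post", date=day0 + timedelta(days=config.n_days),
        alters=post_alters, ties=post_ties,
    )

    roster = [copy_alter(a) for a in pre_alters] + [copy_alter(a) for a in growth_alters] + [
        copy_alter(a) for a in wave2_alters
    ]
    dataset = ParticipantDataset(
        participant_id=f"sim-{config.seed:06d}",
        waves=[pre_wave, post_wave],
        schedule=schedule,
        responses=responses,
        events=events,
        roster=roster,
    )
    truth = SimulationTruth(
        latent_quality=latent,
        entry_day=entry_day,
        breakup_day=breakup_day,
        removed_ids=removed_ids,
    )
    return dataset, truth


def simulate_participant(config: SimulationConfig) -> ParticipantDataset:
    """Generate one fully synthetic participant dataset."""
    return simulate_with_truth(config)[0]


def recovery_report(
    dataset: ParticipantDataset,
    config: SimulationConfig,
    indicator: Optional[str] = None,
    min_events: int = 2,
) -> pd.DataFrame:
    """Compare per-partner quality summaries against the latent means.

    Re-derives the ground truth from the config (the simulator is
    seed-deterministic) and reports, per alter with at least
    ``min_events`` contributing interactions: the latent mean, the
    estimated mean, the 95% CI and whether it covers the latent mean.
    """
    _, truth = simulate_with_truth(config)
    indicator = indicator or config.quality_indicators[0]
    rows = []
    for s in quality_summary(dataset.events, dataset.roster, by="partner", indicator=indicator):
        if s.n < min_events or s.group_key not in truth.latent_quality:
            continue
        mu = truth.latent_quality[s.group_key]
        covered = None
        if s.ci_low is not None:
            covered = bool(s.ci_low <= mu <= s.ci_high)
        rows.append(
            {
                "alter_id": s.group_key,
                "latent_mean": mu,
                "n_events": s.n,
                "estimated_mean": s.mean,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "covered": covered,
            }
        )
    return pd.DataFrame(rows)
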