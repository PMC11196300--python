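"""Shared fixtures: a tiny hand-built dataset and a simulated one."""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import pytest

from egolens.core_model import (
    Alter,
    InteractionEvent,
    MomentaryResponse,
    NetworkWave,
    ParticipantDataset,
    Prompt,
)
from egolens.synthetic_cohort import SimulationConfig, simulate_participant

TZ = timezone(timedelta(hours=2))
DAY1 = date(2021, 10, 4)


def ts(day: int, hour: int, minute: int = 0) -> datetime:
    return datetime(DAY1.year, DAY1.month, DAY1.day, tzinfo=TZ) + timedelta(
        days=day - 1, hours=hour, minutes=minute
    )


def make_alter(i: int, role: str = "friend", closeness: int = 5, **kw) -> Alter:
    return Alter(
        alter_id=f"a{i:03d}",
        display_name=kw.pop("display_name", f"Person {i}"),
        role=role,
        closeness=closeness,
        **kw,
    )


def make_prompt(day: int, kind: str, hour: int) -> Prompt:
    idx = {"morning": "morning", "evening": "evening"}.get(kind, "random1")
    return Prompt(
        prompt_id=f"d{day:02d}-{idx}",
        day_index=day,
        kind=kind,
        scheduled_time=ts(day, hour),
        window_start=ts(day, hour - 1),
        window_end=ts(day, hour + 1),
    )


def make_event(
    n: int, day: int, hour: int, partners: list[str], quality: float = 7.0, **kw
) -> InteractionEvent:
    return InteractionEvent(
        event_id=f"e{n:04d}",
        start_time=ts(day, hour),
        mode=kw.pop("mode", "face_to_face"),
        duration_min=kw.pop("duration_min", 30.0),
        quality=kw.pop("quality_map", {"meaningfulness": quality, "enjoyment": quality}),
        affect=kw.pop("affect", {"happiness": 7.0}),
        partner_ids=partners,
        is_group=len(partners) > 1,
        **kw,
    )


@pytest.fixture
def tiny_dataset() -> ParticipantDataset:
    """Three alters, two prompts, two events — small enough to hand-check."""
    alters = [
        make_alter(1, "friend", 8),
        make_alter(2, "family", 6),
        make_alter(3, "acquaintance", 2),
    ]
    wave = NetworkWave(label="pre", date=DAY1 - timedelta(days=1),
                       alters=alters, ties=[("a001", "a002")])
    prompts = [make_prompt(1, "morning", 9), make_prompt(1, "evening", 21)]
    responses = [
        MomentaryResponse(
            prompt_ref=prompts[0].prompt_id,
            response_time=prompts[0].scheduled_time + timedelta(minutes=3),
            affect={"happiness": 7.0},
            alone=False,
            company_perception=8.0,
        ),
        MomentaryResponse(prompt_ref=prompts[1].prompt_id),
    ]
    events = [
        make_event(1, 1, 12, ["a001"], 8.0, content_text="talked about food and plans"),
        make_event(2, 1, 15, ["a002"], 6.0, content_text="made plans for dinner"),
    ]
    return ParticipantDataset(
        participant_id="tiny",
        waves=[wave],
        schedule=prompts,
        responses=responses,
        events=events,
        roster=[Alter(**vars(a)) for a in alters],
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_alters=20, n_days=10, growth=4, removals=1, breakup=True)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    return simulate_participant(sim_config)
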