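"""On-disk schema for participant bundles and anonymised export.

A bundle is a directory of six text files:

* ``manifest.json`` — participant id, schema version, file list
* ``network_waves.json`` — per-wave alter snapshots and the tie edge list
* ``roster.csv`` — the evolving union of all alters with origin tags
* ``schedule.csv`` / ``responses.csv`` / ``events.csv`` — long format,
  one row per prompt / response / event

All writes are byte-deterministic for a fixed dataset (sorted JSON keys,
fixed column order, ``\\n`` newlines), so ``write(read(write(x)))`` is
byte-identical to ``write(x)`` and ``read(write(x)) == x``.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np

from .core_model import (
    Alter,
    InteractionEvent,
    MomentaryResponse,
    NetworkWave,
    ParticipantDataset,
    Prompt,
    validate_dataset,
)

SCHEMA_VERSION = 1

_FILES = (
    "manifest.json",
    "network_waves.json",
    "roster.csv",
    "schedule.csv",
    "responses.csv",
    "events.csv",
)

_ROSTER_COLS = (
    "alter_id", "display_name", "role", "gender", "age_bracket",
    "closeness", "contact_freq_in_person", "contact_freq_online", "flags", "origin",
)
_SCHEDULE_COLS = ("prompt_id", "day_index", "kind", "scheduled_time", "window_start", "window_end")
_RESPONSE_COLS = ("prompt_ref", "response_time", "affect", "alone", "company_perception", "activities")
_EVENT_COLS = (
    "event_id", "start_time", "mode", "duration_min", "location", "is_group",
    "category", "content_text", "quality", "affect", "partner_ids",
)


class BundleError(Exception):
    """Raised on any malformed or unreadable bundle; carries a code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


class InvalidDatasetError(Exception):
    """Refusal to write a dataset that fails validation."""

    def __init__(self, report):
        super().__init__(f"{len(report)} validation error(s); first: {report[0]}")
        self.report = report


@dataclass
class DatasetBundle:
    path: Path
    manifest: dict


@dataclass
class AnonymisationMap:
    mode: str  # "real_names" | "pseudonyms"
    mapping: dict[str, str]  # alter_id -> pseudonym label


def _jdump(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def _cell(value) -> str:
    """Serialise one CSV cell; maps/lists become compact JSON."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (dict, list)):
        return _jdump(value)
    if isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _opt_float(cell: str, *, row: int, col: str, path: str) -> Optional[float]:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise BundleError(
            "malformed_csv", f"{path} row {row}: non-numeric {col} {cell!r}"
        ) from None


def _opt_int(cell: str, *, row: int, col: str, path: str) -> Optional[int]:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError:
        raise BundleError("malformed_csv", f"{path} row {row}: non-integer {col} {cell!r}") from None


def _opt_dt(cell: str, *, row: int, col: str, path: str) -> Optional[datetime]:
    if cell == "":
        return None
    try:
        return datetime.fromisoformat(cell)
    except ValueError:
        raise BundleError("malformed_csv", f"{path} row {row}: bad timestamp {col} {cell!r}") from None


def _opt_bool(cell: str) -> Optional[bool]:
    return None if cell == "" else cell == "true"


def _alter_row(a: Alter) -> list[str]:
    return [
        a.alter_id, a.display_name, a.role, a.gender, a.age_bracket,
        _cell(a.closeness), _cell(a.contact_freq_in_person), _cell(a.contact_freq_online),
        _cell(a.flags), a.origin,
    ]


def _alter_from_json(d: dict) -> Alter:
    return Alter(
        alter_id=d["alter_id"],
        display_name=d["display_name"],
        role=d["role"],
        gender=d["gender"],
        age_bracket=d["age_bracket"],
        closeness=d["closeness"],
        contact_freq_in_person=d["contact_freq_in_person"],
        contact_freq_online=d["contact_freq_online"],
        flags=dict(d["flags"]),
        origin=d["origin"],
    )


def _alter_to_json(a: Alter) -> dict:
    return {
        "alter_id": a.alter_id,
        "display_name": a.display_name,
        "role": a.role,
        "gender": a.gender,
        "age_bracket": a.age_bracket,
        "closeness": a.closeness,
        "contact_freq_in_person": a.contact_freq_in_person,
        "contact_freq_online": a.contact_freq_online,
        "flags": {k: a.flags[k] for k in sorted(a.flags)},
        "origin": a.origin,
    }


def _write_csv(path: Path, cols, rows) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        writer.writerows(rows)


def write_dataset(dataset: ParticipantDataset, destination) -> DatasetBundle:
    """Write a validated dataset as a deterministic file bundle."""
    report = [i for i in validate_dataset(dataset) if i.severity == "error"]
    if report:
        raise InvalidDatasetError(report)
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)

    manifest = {
        "participant_id": dataset.participant_id,
        "schema_version": SCHEMA_VERSION,
        "files": sorted(f for f in _FILES if f != "manifest.json"),
    }
    (dest / "manifest.json").write_text(_jdump(manifest) + "\n", encoding="utf-8")

    waves = {
        "waves": [
            {
                "label": w.label,
                "date": w.date.isoformat() if w.date else None,
                "alters": [_alter_to_json(a) for a in w.alters],
                "ties": [list(t) for t in w.ties],
            }
            for w in dataset.waves
        ]
    }
    (dest / "network_waves.json").write_text(_jdump(waves) + "\n", encoding="utf-8")

    _write_csv(dest / "roster.csv", _ROSTER_COLS, (_alter_row(a) for a in dataset.roster))
    _write_csv(
        dest / "schedule.csv", _SCHEDULE_COLS,
        ([p.prompt_id, p.day_index, p.kind, _cell(p.scheduled_time), _cell(p.window_start), _cell(p.window_end)]
         for p in dataset.schedule),
    )
    _write_csv(
        dest / "responses.csv", _RESPONSE_COLS,
        ([r.prompt_ref, _cell(r.response_time), _cell(r.affect), _cell(r.alone),
          _cell(r.company_perception), _cell(r.activities)]
         for r in dataset.responses),
    )
    _write_csv(
        dest / "events.csv", _EVENT_COLS,
        ([e.event_id, _cell(e.start_time), e.mode, _cell(float(e.duration_min)), e.location,
          _cell(e.is_group), e.category, e.content_text, _cell(e.quality), _cell(e.affect),
          _cell(e.partner_ids)]
         for e in dataset.events),
    )
    return DatasetBundle(path=dest, manifest=manifest)


def _read_rows(path: Path, expected_cols) -> list[dict[str, str]]:
    if not path.exists():
        raise BundleError("missing_file", f"bundle file {path.name} is missing")
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise BundleError("malformed_csv", f"{path.name}: empty file") from None
        if header != list(expected_cols):
            raise BundleError("malformed_csv", f"{path.name}: unexpected header {header}")
        rows = []
        for i, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise BundleError("malformed_csv", f"{path.name} row {i}: wrong field count")
            rows.append(dict(zip(header, row), _row=i))
    return rows


def _jcell(cell: str, *, row: int, col: str, path: str):
    if cell == "":
        return {}
    try:
        return json.loads(cell)
    except json.JSONDecodeError:
        raise BundleError("malformed_csv", f"{path} row {row}: bad JSON in {col}") from None


def read_dataset(source) -> ParticipantDataset:
    """Reconstruct a :class:`ParticipantDataset` from a bundle directory."""
    src = Path(source)
    mpath = src / "manifest.json"
    if not mpath.exists():
        raise BundleError("missing_file", "manifest.json is missing")
    try:
        manifest = json.loads(mpath.read_text(encoding="utf-8"))
    except json.JSONDecodeError:
        raise BundleError("malformed_json", "manifest.json is not valid JSON") from None
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise BundleError(
            "schema_version_mismatch",
            f"bundle schema version {version!r}; this reader supports {SCHEMA_VERSION} only",
        )
    for fname in manifest.get("files", []):
        if not (src / fname).exists():
            raise BundleError("missing_file", f"bundle file {fname} is missing")

    wpath = src / "network_waves.json"
    try:
        wdoc = json.loads(wpath.read_text(encoding="utf-8"))
    except json.JSONDecodeError:
        raise BundleError("malformed_json", "network_waves.json is not valid JSON") from None
    waves = [
        NetworkWave(
            label=w["label"],
            date=date.fromisoformat(w["date"]) if w["date"] else None,
            alters=[_alter_from_json(a) for a in w["alters"]],
            ties=[tuple(t) for t in w["ties"]],
        )
        for w in wdoc["waves"]
    ]

    roster = []
    for r in _read_rows(src / "roster.csv", _ROSTER_COLS):
        i = r["_row"]
        roster.append(
            Alter(
                alter_id=r["alter_id"], display_name=r["display_name"], role=r["role"],
                gender=r["gender"], age_bracket=r["age_bracket"],
                closeness=_opt_int(r["closeness"], row=i, col="closeness", path="roster.csv"),
                contact_freq_in_person=_opt_int(r["contact_freq_in_person"], row=i,
                                                col="contact_freq_in_person", path="roster.csv"),
                contact_freq_online=_opt_int(r["contact_freq_online"], row=i,
                                             col="contact_freq_online", path="roster.csv"),
                flags=_jcell(r["flags"], row=i, col="flags", path="roster.csv"),
                origin=r["origin"],
            )
        )

    schedule = []
    for r in _read_rows(src / "schedule.csv", _SCHEDULE_COLS):
        i = r["_row"]
        schedule.append(
            Prompt(
                prompt_id=r["prompt_id"],
                day_index=int(r["day_index"]),
                kind=r["kind"],
                scheduled_time=_opt_dt(r["scheduled_time"], row=i, col="scheduled_time", path="schedule.csv"),
                window_start=_opt_dt(r["window_start"], row=i, col="window_start", path="schedule.csv"),
                window_end=_opt_dt(r["window_end"], row=i, col="window_end", path="schedule.csv"),
            )
        )

    responses = []
    for r in _read_rows(src / "responses.csv", _RESPONSE_COLS):
        i = r["_row"]
        activities = _jcell(r["activities"], row=i, col="activities", path="responses.csv")
        responses.append(
            MomentaryResponse(
                prompt_ref=r["prompt_ref"],
                response_time=_opt_dt(r["response_time"], row=i, col="response_time", path="responses.csv"),
                affect=_jcell(r["affect"], row=i, col="affect", path="responses.csv"),
                alone=_opt_bool(r["alone"]),
                company_perception=_opt_float(r["company_perception"], row=i,
                                              col="company_perception", path="responses.csv"),
                activities=activities if isinstance(activities, list) else [],
            )
        )

    events = []
    for r in _read_rows(src / "events.csv", _EVENT_COLS):
        i = r["_row"]
        partners = _jcell(r["partner_ids"], row=i, col="partner_ids", path="events.csv")
        duration = _opt_float(r["duration_min"], row=i, col="duration_min", path="events.csv")
        if duration is None:
            raise BundleError("malformed_csv", f"events.csv row {i}: missing duration_min")
        events.append(
            InteractionEvent(
                event_id=r["event_id"],
                start_time=_opt_dt(r["start_time"], row=i, col="start_time", path="events.csv"),
                mode=r["mode"],
                duration_min=duration,
                location=r["location"],
                is_group=r["is_group"] == "true",
                category=r["category"],
                content_text=r["content_text"],
                quality=_jcell(r["quality"], row=i, col="quality", path="events.csv"),
                affect=_jcell(r["affect"], row=i, col="affect", path="events.csv"),
                partner_ids=partners if isinstance(partners, list) else [],
            )
        )

    return ParticipantDataset(
        participant_id=manifest["participant_id"],
        waves=waves, schedule=schedule, responses=responses, events=events, roster=roster,
    )


def anonymise(
    dataset: ParticipantDataset,
    mode: str = "pseudonyms",
    seed: int = 0,
    redact_text: bool = False,
    date_shift_days: int = 0,
) -> tuple[ParticipantDataset, AnonymisationMap]:
    """Replace alter names with stable pseudonyms.

    ``mode="real_names"`` returns an unchanged copy and the identity
    map. In pseudonym mode every display name (roster and wave
    snapshots) becomes ``Contact NN``; label assignment is a seeded
    permutation of the roster so the same seed re-exports identically.
    Structure, ratings and event linkage are untouched, which keeps
    every downstream metric invariant. Optionally free text is redacted
    and all timestamps shifted by a uniform number of days (the study
    convention for hiding exact dates).
    """
    out = copy.deepcopy(dataset)
    if mode == "real_names":
        return out, AnonymisationMap(mode=mode, mapping={a.alter_id: a.display_name for a in out.roster})
    if mode != "pseudonyms":
        raise ValueError(f"unknown anonymisation mode {mode!r}")

    rng = np.random.default_rng(seed)
    ids = [a.alter_id for a in out.roster]
    order = rng.permutation(len(ids))
    width = max(2, len(str(len(ids))))
    mapping = {ids[i]: f"Contact {rank + 1:0{width}d}" for rank, i in enumerate(order)}

    for a in out.roster:
        a.display_name = mapping[a.alter_id]
    for w in out.waves:
        for a in w.alters:
            a.display_name = mapping.get(a.alter_id, a.display_name)
    if redact_text:
        for e in out.events:
            e.content_text = "[redacted]"
    if date_shift_days:
        delta = timedelta(days=date_shift_days)
        for w in out.waves:
            if w.date:
                w.date = w.date + delta
        for p in out.schedule:
            p.scheduled_time += delta
            p.window_start += delta
            p.window_end += delta
        for r in out.responses:
            if r.response_time is not None:
                r.response_time += delta
        for e in out.events:
            e.start_time += delta
    return out, AnonymisationMap(mode=mode, mapping=mapping)
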