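"""Two-wave network reconciliation: seeding, turnover and role change.

After the ESM period the network is re-elicited with the pre-wave
ratings and every ESM-encountered interaction partner pre-loaded on
screen (:func:`seed_post_wave`). :func:`reconcile` then classifies each
alter as stable, removed, or newly added — distinguishing members first
seen during ESM from members added at the post assessment — and lists
role changes and ordinal rating shifts among the stable members.

Identity across waves is by ``alter_id`` (the seeding flow preserves
ids), never by name: a rename is a rating edit, not member turnover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core_model import Alter, NetworkWave, copy_alter

STATUSES = ("stable", "removed", "added_during_esm", "added_post")


@dataclass
class ReconciliationResult:
    status: dict[str, str]  # alter_id -> one of STATUSES
    role_changes: list[tuple[str, str, str]]  # (alter_id, role_pre, role_post)
    rating_deltas: dict[str, dict[str, int]]  # alter_id -> item -> post - pre
    flag_flips: dict[str, list[str]]  # alter_id -> flags that flipped
    warnings: list[str] = field(default_factory=list)

    def ids_with_status(self, status: str) -> set[str]:
        return {aid for aid, s in self.status.items() if s == status}

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for s in self.status.values():
            out[s] += 1
        return out


def seed_post_wave(pre: NetworkWave, esm_roster: Iterable[Alter]) -> NetworkWave:
    """Draft the post-ESM wave from the pre wave and the ESM roster.

    Every pre-wave alter is carried over with all ratings intact; every
    ESM-only partner is appended with empty ratings (to be filled at
    the post assessment). Ties carry over from the pre wave. The draft
    has no assessment date yet.
    """
    pre_ids = pre.alter_ids()
    alters = [copy_alter(a) for a in pre.alters]
    seen = set(pre_ids)
    for alter in esm_roster:
        if alter.alter_id in pre_ids:
            continue
        if alter.alter_id in seen:
            raise ValueError(f"duplicate alter id {alter.alter_id!r} in ESM roster")
        seen.add(alter.alter_id)
        blank = copy_alter(alter)
        blank.closeness = None
        blank.contact_freq_in_person = None
        blank.contact_freq_online = None
        blank.flags = {}
        blank.origin = "esm"
        alters.append(blank)
    return NetworkWave(label="post", date=None, alters=alters, ties=list(pre.ties))


def _check_unique(wave: NetworkWave) -> None:
    ids = [a.alter_id for a in wave.alters]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate alter ids within wave {wave.label!r}: {dupes}")


def reconcile(
    pre: NetworkWave,
    post: NetworkWave,
    esm_roster: Iterable[Alter] = (),
) -> ReconciliationResult:
    """Partition alters by membership trajectory across the two waves.

    * in both waves → ``stable``
    * in the pre wave only → ``removed`` (actively deleted at the post
      assessment)
    * in the post wave only → ``added_during_esm`` if the alter was
      first seen as an ESM interaction partner, else ``added_post``

    An ESM-roster member absent from the post wave is classed removed
    with a warning (the participant declined to keep them). The four
    statuses always partition the union of all ids seen anywhere.
    """
    _check_unique(pre)
    _check_unique(post)
    pre_ids = pre.alter_ids()
    post_ids = post.alter_ids()
    esm_ids = {a.alter_id for a in esm_roster}

    status: dict[str, str] = {}
    warnings: list[str] = []
    for aid in pre_ids & post_ids:
        status[aid] = "stable"
    for aid in pre_ids - post_ids:
        status[aid] = "removed"
    for aid in post_ids - pre_ids:
        status[aid] = "added_during_esm" if aid in esm_ids else "added_post"
    for aid in esm_ids - pre_ids - post_ids:
        status[aid] = "removed"
        warnings.append(
            f"ESM partner {aid!r} was not kept in the post wave; classed as removed"
        )

    role_changes: list[tuple[str, str, str]] = []
    rating_deltas: dict[str, dict[str, int]] = {}
    flag_flips: dict[str, list[str]] = {}
    for aid in sorted(pre_ids & post_ids):
        a_pre = pre.get(aid)
        a_post = post.get(aid)
        if a_pre.role != a_post.role:
            role_changes.append((aid, a_pre.role, a_post.role))
        deltas: dict[str, int] = {}
        for item, v_pre in a_pre.ordinal_ratings().items():
            v_post = a_post.ordinal_ratings()[item]
            if v_pre is not None and v_post is not None and v_post != v_pre:
                deltas[item] = v_post - v_pre
        if deltas:
            rating_deltas[aid] = deltas
        flips = sorted(
            name
            for name in set(a_pre.flags) & set(a_post.flags)
            if a_pre.flags[name] != a_post.flags[name]
        )
        if flips:
            flag_flips[aid] = flips

    return ReconciliationResult(
        status=status,
        role_changes=role_changes,
        rating_deltas=rating_deltas,
        flag_flips=flag_flips,
        warnings=warnings,
    )


def tie_changes(pre: NetworkWave, post: NetworkWave) -> dict[str, list[tuple[str, str]]]:
    """Exploratory tie turnover between waves (added / dropped edges).

    Whether ties could be edited at the post assessment is an open
    design question; this is provided for inspection only.
    """
    pre_t = set(pre.ties)
    post_t = set(post.ties)
    return {
        "added": sorted(post_t - pre_t),
        "dropped": sorted(pre_t - post_t),
    }
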