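"""Post-wave seeding and two-wave membership/role-change analysis."""

import numpy as np
import pytest

from egolens.core_model import Alter, NetworkWave
from egolens.network_reconciliation import reconcile, seed_post_wave, tie_changes
from tests.conftest import make_alter


def _wave(label, ids, roles=None, ties=()):
    roles = roles or {}
    return NetworkWave(
        label=label, date=None,
        alters=[make_alter(int(i[1:]), roles.get(i, "friend")) for i in ids],
        ties=list(ties),
    )


def _ids(n, offset=0):
    return [f"a{i + offset:03d}" for i in range(1, n + 1)]


def set_oracle(pre_ids, post_ids, esm_ids):
    """Independent partition via plain set algebra."""
    pre, post, esm = set(pre_ids), set(post_ids), set(esm_ids)
    return {
        "stable": pre & post,
        "removed": (pre | esm) - post,
        "added_during_esm": (post - pre) & esm,
        "added_post": post - pre - esm,
    }


def test_empty_esm_roster_seeds_identity():
    pre = _wave("pre", _ids(5), ties=[("a001", "a002")])
    draft = seed_post_wave(pre, [])
    assert [a.alter_id for a in draft.alters] == [a.alter_id for a in pre.alters]
    assert draft.ties == pre.ties
    assert draft.label == "post"


def test_seeding_carries_ratings_and_blanks_new_partners():
    """Pre wave of 26 + 16 ESM-only partners -> draft of 42."""
    pre = _wave("pre", _ids(26))
    for a in pre.alters:
        a.closeness = 7
        a.flags = {"can_be_myself": True}
    esm = [make_alter(i, "other", origin="esm") for i in range(27, 43)]
    draft = seed_post_wave(pre, esm)
    assert len(draft.alters) == 42
    carried = [a for a in draft.alters if a.alter_id in pre.alter_ids()]
    assert all(a.closeness == 7 and a.flags == {"can_be_myself": True} for a in carried)
    blank = [a for a in draft.alters if a.alter_id not in pre.alter_ids()]
    assert len(blank) == 16
    assert all(a.closeness is None and a.flags == {} for a in blank)


def test_example_participant_sixteen_added_none_removed():
    """Post wave contains everyone plus 16 new ESM members."""
    pre = _wave("pre", _ids(26))
    esm = [make_alter(i, "other", origin="esm") for i in range(27, 43)]
    post = _wave("post", _ids(42))
    res = reconcile(pre, post, esm)
    counts = res.counts()
    assert counts["added_during_esm"] == 16
    assert counts["removed"] == 0
    assert counts["stable"] == 26


def test_breakup_reported_as_single_role_change():
    pre = _wave("pre", _ids(3), roles={"a002": "romantic_partner"})
    post = _wave("post", _ids(3), roles={"a002": "friend"})
    res = reconcile(pre, post)
    assert res.role_changes == [("a002", "romantic_partner", "friend")]


def test_identical_waves_all_stable():
    w = _wave("pre", _ids(6), ties=[("a001", "a002"), ("a003", "a004")])
    res = reconcile(w, w, [])
    assert set(res.status.values()) == {"stable"}
    assert res.role_changes == []
    assert res.rating_deltas == {}


def test_rating_deltas_only_where_both_rated():
    pre = _wave("pre", _ids(2))
    post = _wave("post", _ids(2))
    pre.alters[0].closeness, post.alters[0].closeness = 4, 7
    pre.alters[1].closeness, post.alters[1].closeness = 5, None
    res = reconcile(pre, post)
    assert res.rating_deltas == {"a001": {"closeness": 3}}


def test_flag_flips_reported():
    pre = _wave("pre", _ids(1))
    post = _wave("post", _ids(1))
    pre.alters[0].flags = {"can_be_myself": True, "gives_practical_support": False}
    post.alters[0].flags = {"can_be_myself": False, "gives_practical_support": False}
    res = reconcile(pre, post)
    assert res.flag_flips == {"a001": ["can_be_myself"]}


def test_esm_partner_dropped_at_post_is_removed_with_warning():
    pre = _wave("pre", _ids(2))
    post = _wave("post", _ids(2))
    esm = [make_alter(9, "other", origin="esm")]
    res = reconcile(pre, post, esm)
    assert res.status["a009"] == "removed"
    assert res.warnings


def test_duplicate_ids_within_wave_rejected():
    bad = NetworkWave(label="pre", date=None,
                      alters=[make_alter(1), make_alter(1)])
    with pytest.raises(ValueError):
        reconcile(bad, _wave("post", _ids(1)), [])


@pytest.mark.parametrize("seed", range(20))
def test_partition_matches_set_oracle_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    universe = _ids(30)
    pre_ids = [i for i in universe if rng.random() < 0.6]
    post_ids = [i for i in universe if rng.random() < 0.6]
    esm_ids = [i for i in universe if rng.random() < 0.3]
    res = reconcile(
        _wave("pre", pre_ids), _wave("post", post_ids),
        [make_alter(int(i[1:]), origin="esm") for i in esm_ids],
    )
    oracle = set_oracle(pre_ids, post_ids, esm_ids)
    for status, expected in oracle.items():
        assert res.ids_with_status(status) == expected
    # partition property
    assert sum(res.counts().values()) == len(set(pre_ids) | set(post_ids) | set(esm_ids))


def test_swapping_waves_maps_removed_to_added():
    pre = _wave("pre", _ids(8))
    post = _wave("post", _ids(6, offset=3))  # a004..a009
    fwd = reconcile(pre, post, [])
    back = reconcile(post, pre, [])
    assert fwd.ids_with_status("removed") == (
        back.ids_with_status("added_during_esm") | back.ids_with_status("added_post")
    )


def test_tie_changes_exploratory():
    pre = _wave("pre", _ids(3), ties=[("a001", "a002")])
    post = _wave("post", _ids(3), ties=[("a002", "a003")])
    delta = tie_changes(pre, post)
    assert delta == {"added": [("a002", "a003")], "dropped": [("a001", "a002")]}
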