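"""Feedback statistics: composition, counts, CIs, timeline, structure, terms."""

import numpy as np
import pytest

from egolens.core_model import Alter, NetworkWave
from egolens.social_metrics import (
    affect_timeline,
    interaction_counts,
    interaction_detail,
    network_structure,
    perception_behavior_table,
    quality_summary,
    role_composition,
    word_frequencies,
)
from tests.conftest import make_alter, make_event

# t-interval for {6,7,8,9,10}, cross-checked in R:
# qt(0.975, 4) = 2.776445105198; 8 +/- qt*sd/sqrt(5)
CI_5_SCORES = (6.036756838522, 9.963243161478)


def _wave(alters, ties=()):
    return NetworkWave(label="pre", date=None, alters=alters, ties=list(ties))


def test_role_composition_counts_and_zero_roles():
    wave = _wave(
        [make_alter(i, "friend") for i in range(1, 6)]
        + [make_alter(i, "family") for i in range(6, 9)]
        + [make_alter(i, "acquaintance") for i in range(9, 11)]
    )
    comp = role_composition(wave)
    assert (comp["friend"], comp["family"], comp["acquaintance"]) == (5, 3, 2)
    assert comp["romantic_partner"] == 0
    assert role_composition(_wave([])) == {r: 0 for r in comp}


def test_composition_difference_reveals_breakup():
    pre = _wave([make_alter(1, "romantic_partner"), make_alter(2, "friend")])
    post = _wave([make_alter(1, "friend"), make_alter(2, "friend")])
    assert role_composition(pre)["romantic_partner"] == 1
    assert role_composition(post)["romantic_partner"] == 0


def test_interaction_counts_zero_for_uncontacted_roster():
    roster = [make_alter(1), make_alter(2)]
    counts = interaction_counts([], roster, by="partner")
    assert counts == {"a001": 0, "a002": 0}


def test_multi_partner_event_counts_once_per_partner():
    roster = [make_alter(1, "friend"), make_alter(2, "friend"), make_alter(3, "family")]
    events = [make_event(1, 1, 12, ["a001", "a002", "a003"])]
    by_partner = interaction_counts(events, roster, by="partner")
    assert by_partner == {"a001": 1, "a002": 1, "a003": 1}
    assert sum(by_partner.values()) == 3 > len(events)
    by_role = interaction_counts(events, roster, by="role")
    assert by_role["friend"] == 2 and by_role["family"] == 1


def test_one_on_one_role_counts_sum_to_event_count():
    roster = [make_alter(1, "friend"), make_alter(2, "family")]
    events = [make_event(i, 1, 9 + i, ["a001" if i % 2 else "a002"]) for i in range(6)]
    by_role = interaction_counts(events, roster, by="role")
    assert sum(by_role.values()) == len(events)


def test_per_partner_counts_expose_within_role_differences():
    roster = [make_alter(1, "friend"), make_alter(2, "friend")]
    events = [make_event(i, 1 + i % 7, 10, ["a001"]) for i in range(20)] + [
        make_event(100 + i, 1, 12 + i, ["a002"]) for i in range(2)
    ]
    counts = interaction_counts(events, roster, by="partner")
    assert counts == {"a001": 20, "a002": 2}


def test_single_score_has_mean_but_no_interval():
    roster = [make_alter(1)]
    events = [make_event(1, 1, 10, ["a001"], 7.0)]
    (s,) = quality_summary(events, roster, by="partner", indicator="meaningfulness")
    assert s.mean == 7.0 and s.n == 1
    assert s.ci_low is None and s.ci_high is None


def test_t_interval_matches_independent_oracle():
    roster = [make_alter(1)]
    events = [make_event(i, 1, 9 + i, ["a001"], q) for i, q in enumerate([6, 7, 8, 9, 10])]
    (s,) = quality_summary(events, roster, by="partner", indicator="meaningfulness")
    assert s.mean == pytest.approx(8.0, abs=1e-12)
    assert s.ci_low == pytest.approx(CI_5_SCORES[0], abs=1e-9)
    assert s.ci_high == pytest.approx(CI_5_SCORES[1], abs=1e-9)


def test_low_quality_friend_ranks_lowest_among_friends():
    roster = [make_alter(i, "friend") for i in (1, 2, 3)]
    events = (
        [make_event(i, 1, 9, ["a001"], 8 + i % 3) for i in range(6)]
        + [make_event(10 + i, 2, 9, ["a002"], 7 + i % 4) for i in range(6)]
        + [make_event(20 + i, 3, 9, ["a003"], 3 + i % 2) for i in range(6)]
    )
    summaries = quality_summary(events, roster, by="partner", indicator="meaningfulness")
    means = {s.group_key: s.mean for s in summaries}
    assert min(means, key=means.get) == "a003"


def test_summary_ordering_descending_n_then_key():
    roster = [make_alter(1), make_alter(2), make_alter(3)]
    events = [make_event(i, 1, 9, ["a002"], 7) for i in range(3)] + [
        make_event(10 + i, 1, 12, ["a001"], 7) for i in range(3)
    ] + [make_event(20, 2, 9, ["a003"], 7)]
    keys = [s.group_key for s in quality_summary(events, roster, by="partner",
                                                 indicator="meaningfulness")]
    assert keys == ["a001", "a002", "a003"]


def test_mean_invariant_under_event_permutation():
    roster = [make_alter(1)]
    events = [make_event(i, 1, 9, ["a001"], q) for i, q in enumerate([2, 9, 5, 7])]
    fwd = quality_summary(events, roster, by="partner", indicator="meaningfulness")
    rev = quality_summary(list(reversed(events)), roster, by="partner",
                          indicator="meaningfulness")
    assert fwd[0].mean == rev[0].mean
    assert sorted(fwd[0].points) == sorted(rev[0].points)


def test_ci_width_shrinks_with_n():
    rng = np.random.default_rng(0)
    roster = [make_alter(1)]
    widths = []
    for n in (5, 50, 500):
        events = [
            make_event(i, 1 + i // 20, 9, ["a001"],
                       float(np.clip(rng.normal(6, 1.5), 0, 10)))
            for i in range(n)
        ]
        (s,) = quality_summary(events, roster, by="partner", indicator="meaningfulness")
        widths.append(s.ci_high - s.ci_low)
    assert widths[0] > widths[1] > widths[2]


def test_unknown_indicator_raises():
    roster = [make_alter(1)]
    events = [make_event(1, 1, 9, ["a001"])]
    with pytest.raises(KeyError):
        quality_summary(events, roster, indicator="charisma")


def test_timeline_without_events_has_affect_only(tiny_dataset):
    payload = affect_timeline(tiny_dataset.responses, [], affect_item="happiness")
    assert payload.event_points == []
    assert len(payload.affect_series) == 1  # one answered prompt


def test_timeline_partner_filter_semantics(tiny_dataset):
    payload = affect_timeline(
        tiny_dataset.responses, tiny_dataset.events,
        affect_item="happiness", indicator="meaningfulness",
        partner_filter={"a001"}, roster=tiny_dataset.roster,
    )
    assert all("a001" in p.partner_ids for p in payload.event_points)
    # the affect line is unaffected by the filter
    unfiltered = affect_timeline(
        tiny_dataset.responses, tiny_dataset.events,
        affect_item="happiness", indicator="meaningfulness",
        roster=tiny_dataset.roster,
    )
    assert payload.affect_series == unfiltered.affect_series


def test_timeline_merges_prompt_and_event_affect(tiny_dataset):
    payload = affect_timeline(
        tiny_dataset.responses, tiny_dataset.events,
        affect_item="happiness", indicator="meaningfulness",
        roster=tiny_dataset.roster,
    )
    n_prompt_affect = sum(1 for r in tiny_dataset.responses
                          if r.answered and "happiness" in r.affect)
    n_event_affect = sum(1 for e in tiny_dataset.events if "happiness" in e.affect)
    assert len(payload.affect_series) == n_prompt_affect + n_event_affect
    times = [p.time for p in payload.affect_series]
    assert times == sorted(times)


def test_interaction_detail_lookup_and_unknown_id(tiny_dataset):
    detail = interaction_detail(tiny_dataset.events, "e0001", tiny_dataset.roster)
    e = tiny_dataset.events[0]
    assert detail["mode"] == e.mode
    assert detail["quality"] == e.quality
    assert detail["partner_names"] == ["Person 1"]
    with pytest.raises(KeyError):
        interaction_detail(tiny_dataset.events, "nope")


def test_perception_behavior_discrepancy_rule():
    alters = [make_alter(i, "friend", closeness=c) for i, c in
              enumerate([9, 9, 8, 6, 5, 5, 4, 3, 2, 1], start=1)]
    wave = _wave(alters)
    # a001 close but never contacted; a002 close and contacted a lot
    events = [make_event(i, 1 + i % 7, 10, ["a002"]) for i in range(30)]
    table = perception_behavior_table(wave, events)
    flagged = set(table.loc[table["discrepancy"], "alter_id"])
    # hand enumeration: 2/3-quantile of {1..6,8,9,9} ratings is 6.0, so the
    # uncontacted alters rated 9, 8 and 6 are flagged; a002 (9, contacted) is not
    assert flagged == {"a001", "a003", "a004"}
    row = table.set_index("alter_id").loc["a002"]
    assert row["n_interactions"] == 30 and not row["discrepancy"]


def test_no_ties_means_every_alter_isolate():
    wave = _wave([make_alter(i) for i in range(1, 5)])
    res = network_structure(wave)
    assert res.isolates == ["a001", "a002", "a003", "a004"]
    assert all(len(c) == 1 for c in res.components)


def test_family_clique_plus_isolate():
    family = [make_alter(i, "family") for i in range(1, 5)]
    loner = make_alter(41, "acquaintance")
    ties = [(a.alter_id, b.alter_id) for i, a in enumerate(family) for b in family[i + 1:]]
    res = network_structure(_wave(family + [loner], ties))
    assert res.isolates == ["a041"]
    assert res.components[0] == [a.alter_id for a in family]


class UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


@pytest.mark.parametrize("seed", range(10))
def test_structure_matches_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 25))
    alters = [make_alter(i) for i in range(1, n + 1)]
    ids = [a.alter_id for a in alters]
    ties = [
        (ids[i], ids[j])
        for i in range(n) for j in range(i + 1, n)
        if rng.random() < 0.12
    ]
    res = network_structure(_wave(alters, ties))
    uf = UnionFind(ids)
    for a, b in ties:
        uf.union(a, b)
    groups = {}
    for i in ids:
        groups.setdefault(uf.find(i), set()).add(i)
    assert {frozenset(c) for c in res.components} == {frozenset(g) for g in groups.values()}


def test_word_frequencies_hand_tokenised():
    events = [
        make_event(1, 1, 9, ["a001"],
                   content_text="talked about food. made plans for going out. food again")
    ]
    freq = word_frequencies(events, stopwords={"about", "for", "out", "again"},
                            extra_exclusions={"talked"})
    assert freq == [("food", 2), ("going", 1), ("made", 1), ("plans", 1)]


def test_word_frequencies_empty_corpus():
    assert word_frequencies([]) == []


def test_default_exclusions_remove_talking_verbs_and_stopwords():
    events = [make_event(1, 1, 9, ["a001"],
                         content_text="We talked about the food and chatted about plans")]
    terms = dict(word_frequencies(events))
    assert "talked" not in terms and "chatted" not in terms
    assert "the" not in terms and "about" not in terms
    assert terms["food"] == 1 and terms["plans"] == 1


def test_fixture_dominant_topics_lead_table(sim_dataset):
    """Simulated diaries are about food/plans/going most of all."""
    freq = word_frequencies(sim_dataset.events)
    top = [t for t, _ in freq[:6]]
    assert {"food", "plans", "going"} & set(top[:4])
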