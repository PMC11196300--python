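"""Simulator contracts: determinism, clean validation, scenario flags,
ground-truth recovery, and the affect-coupling structure."""

import numpy as np
import pytest

from egolens.core_model import validate_dataset
from egolens.io_formats import write_dataset
from egolens.network_reconciliation import reconcile
from egolens.sampling_schedule import compliance
from egolens.synthetic_cohort import (
    SimulationConfig,
    recovery_report,
    simulate_participant,
    simulate_with_truth,
)


def _esm(dataset):
    return [a for a in dataset.roster if a.origin == "esm"]


def test_simulated_dataset_validates_cleanly(sim_dataset):
    assert [i for i in validate_dataset(sim_dataset) if i.severity == "error"] == []


def test_same_seed_byte_identical_bundles(tmp_path):
    cfg = SimulationConfig(seed=3, n_alters=12, n_days=5)
    write_dataset(simulate_participant(cfg), tmp_path / "x")
    write_dataset(simulate_participant(cfg), tmp_path / "y")
    for f in (tmp_path / "x").iterdir():
        assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes()


def test_different_seeds_differ(tmp_path):
    a = simulate_participant(SimulationConfig(seed=1, n_alters=12, n_days=5))
    b = simulate_participant(SimulationConfig(seed=2, n_alters=12, n_days=5))
    assert a != b


def test_breakup_flag_produces_single_partner_to_friend_change():
    ds = simulate_participant(SimulationConfig(seed=5, n_alters=15, n_days=6, breakup=True))
    res = reconcile(ds.wave("pre"), ds.wave("post"), _esm(ds))
    assert res.role_changes.count(
        next(rc for rc in res.role_changes if rc[1] == "romantic_partner")
    ) == 1
    partner_changes = [rc for rc in res.role_changes if rc[1] == "romantic_partner"]
    assert partner_changes == [(partner_changes[0][0], "romantic_partner", "friend")]


def test_growth_and_removals_reflected_in_reconciliation():
    ds = simulate_participant(
        SimulationConfig(seed=6, n_alters=14, n_days=8, growth=5, removals=2)
    )
    res = reconcile(ds.wave("pre"), ds.wave("post"), _esm(ds))
    counts = res.counts()
    assert counts["added_during_esm"] == 5
    assert counts["removed"] == 2


def test_growth_post_members_classed_added_post():
    ds = simulate_participant(
        SimulationConfig(seed=8, n_alters=12, n_days=5, growth=2, growth_post=3)
    )
    res = reconcile(ds.wave("pre"), ds.wave("post"), _esm(ds))
    assert res.counts()["added_post"] == 3


def test_every_growth_partner_appears_in_events():
    ds = simulate_participant(SimulationConfig(seed=9, n_alters=12, n_days=8, growth=4))
    partner_ids = {pid for e in ds.events for pid in e.partner_ids}
    assert {a.alter_id for a in _esm(ds)} <= partner_ids


def test_sigma_zero_recovers_latent_means_exactly():
    cfg = SimulationConfig(seed=11, n_alters=10, n_days=10, quality_sd=0.0,
                           interactions_per_day=6.0, group_event_prob=0.0)
    ds = simulate_participant(cfg)
    report = recovery_report(ds, cfg)
    assert len(report) > 0
    assert (report["estimated_mean"] == report["latent_mean"]).all()


def test_null_coupling_gives_near_zero_correlation():
    """gamma = 0: affect is independent of same-window quality."""
    affect, quality = _affect_quality_pairs(gamma=0.0, n_seeds=4)
    assert len(affect) >= 300
    r = np.corrcoef(affect, quality)[0, 1]
    assert abs(r) < 0.12


def test_positive_coupling_lifts_affect_after_good_interactions():
    affect_hi, affect_none = [], []
    for seed in range(3):
        cfg = SimulationConfig(seed=seed, n_alters=12, n_days=14,
                               affect_coupling=0.5, interactions_per_day=2.0)
        ds = simulate_participant(cfg)
        hi, none = _split_by_window_quality(ds, cfg)
        affect_hi += hi
        affect_none += none
    assert np.mean(affect_hi) > np.mean(affect_none)


def test_phi_zero_gamma_zero_is_white_noise_around_baseline():
    cfg = SimulationConfig(seed=13, n_alters=10, n_days=28, affect_autocorr=0.0,
                           affect_coupling=0.0, compliance_prob=1.0)
    ds = simulate_participant(cfg)
    vals = [r.affect["happiness"] for r in ds.responses if r.answered]
    n = len(vals)
    sd = np.std(vals, ddof=1)
    assert abs(np.mean(vals) - cfg.affect_baseline) < 3 * sd / np.sqrt(n)


def test_doubling_rate_increases_counts():
    base = SimulationConfig(seed=14, n_alters=12, n_days=10, interactions_per_day=2.0)
    double = SimulationConfig(seed=14, n_alters=12, n_days=10, interactions_per_day=4.0)
    assert len(simulate_participant(double).events) > len(simulate_participant(base).events)


def test_compliance_rate_near_configured_probability():
    cfg = SimulationConfig(seed=15, n_alters=10, n_days=28, compliance_prob=0.85)
    ds = simulate_participant(cfg)
    summary = compliance(ds.schedule, ds.responses, ds.events)
    assert 0.75 <= summary.overall_rate <= 0.95


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_alters=5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(affect_autocorr=1.0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(role_distribution={"friend": 0.5}).validate()


# -- helpers ----------------------------------------------------------------

def _window_quality(ds, cfg):
    """Per answered prompt: (affect, mean coupling-indicator quality in window)."""
    prompts = {p.prompt_id: p for p in ds.schedule}
    ordered = sorted(ds.schedule, key=lambda p: p.scheduled_time)
    prev = {p.prompt_id: (ordered[i - 1].scheduled_time if i else None)
            for i, p in enumerate(ordered)}
    out = []
    for r in ds.responses:
        if not r.answered:
            continue
        p = prompts[r.prompt_ref]
        lo = prev[p.prompt_id]
        window = [
            e.quality[cfg.coupling_indicator] for e in ds.events
            if (lo is None or e.start_time > lo) and e.start_time <= p.scheduled_time
        ]
        out.append((r.affect["happiness"], window))
    return out


def _affect_quality_pairs(gamma, n_seeds):
    affect, quality = [], []
    for seed in range(n_seeds):
        cfg = SimulationConfig(seed=100 + seed, n_alters=12, n_days=28,
                               affect_coupling=gamma, compliance_prob=1.0,
                               interactions_per_day=6.0)
        ds = simulate_participant(cfg)
        for a, window in _window_quality(ds, cfg):
            if window:
                affect.append(a)
                quality.append(float(np.mean(window)))
    return np.asarray(affect), np.asarray(quality)


def _split_by_window_quality(ds, cfg, hi_threshold=7.0):
    hi, none = [], []
    for a, window in _window_quality(ds, cfg):
        if not window:
            none.append(a)
        elif np.mean(window) >= hi_threshold:
            hi.append(a)
    return hi, none


def test_truth_regeneration_is_consistent(sim_config, sim_dataset):
    ds2, truth = simulate_with_truth(sim_config)
    assert ds2 == sim_dataset
    assert set(truth.latent_quality) >= {a.alter_id for a in sim_dataset.roster
                                         if a.origin != "wave2"}
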