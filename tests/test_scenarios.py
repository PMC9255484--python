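"""Scenario comparison and waiting-list dynamics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctflow.scenarios import (
    ScenarioConfig,
    baseline_scenario,
    compare_scenarios,
    op_only_scenario,
    project_waitlist,
    run_scenario,
)


# ---------------------------------------------------------------------------
# Waiting-list projection
# ---------------------------------------------------------------------------

def test_backlog_grows_by_excess_demand_exactly(default_params):
    """demand 110/week against capacity 100/week from an empty list:
    pending after T weeks is 10*T, exactly."""
    p = default_params.with_overrides(
        {"waitlist": {"weekly_referrals": 110.0, "weekly_capacity": 100.0,
                      "initial_backlog": 0.0}})
    state = project_waitlist(p, 20, mode="fast")
    assert np.array_equal(state.pending, 10.0 * np.arange(21))


def test_balanced_demand_stays_flat_at_zero(default_params):
    p = default_params.with_overrides(
        {"waitlist": {"weekly_referrals": 100.0, "weekly_capacity": 100.0,
                      "initial_backlog": 0.0}})
    state = project_waitlist(p, 10, mode="fast")
    assert np.array_equal(state.pending, np.zeros(11))


def test_backlog_drains_but_never_goes_negative(default_params):
    p = default_params.with_overrides(
        {"waitlist": {"weekly_referrals": 50.0, "weekly_capacity": 100.0,
                      "initial_backlog": 120.0}})
    state = project_waitlist(p, 10, mode="fast")
    state.check_conservation()
    assert state.pending.min() == 0.0
    assert (np.diff(state.pending) <= 0).all()


def test_non_positive_horizon_rejected(default_params):
    with pytest.raises(ValueError, match="horizon"):
        project_waitlist(default_params, 0, mode="fast")


def test_micro_mode_matches_fast_mode_without_contention(ample_params):
    """With ample resources every booked slot is completed, so the
    micro-simulation capacity equals the slot template and the two
    projection modes coincide."""
    fast = project_waitlist(ample_params, 4, mode="fast")
    micro = project_waitlist(ample_params, 4, mode="micro", seed=17)
    assert np.array_equal(fast.pending, micro.pending)


def test_default_regime_projects_growing_waitlist(default_params):
    """Demand above the slot template: the three-year trajectory rises
    with a significantly positive weekly slope (micro mode)."""
    state = project_waitlist(default_params, 26, mode="micro", seed=5)
    slope, pval = state.slope()
    assert slope > 0 and pval < 0.05


# ---------------------------------------------------------------------------
# Scenario running and comparison
# ---------------------------------------------------------------------------

def test_zero_replications_rejected(default_params):
    with pytest.raises(ValueError, match="replication"):
        run_scenario(ScenarioConfig("x", n_replications=0),
                     params=default_params)


def test_identical_scenarios_have_zero_paired_differences(default_params):
    cfg = baseline_scenario(horizon_days=20.0, n_replications=2, base_seed=3)
    a = run_scenario(cfg, params=default_params)
    b = run_scenario(cfg, params=default_params)
    table = compare_scenarios([a, b])
    diffs = table[("baseline", "diff_vs_baseline")]
    assert np.allclose(diffs.fillna(0.0), 0.0)
    assert "perturbation/scheduled" in table.index
    assert "utilization/radiographer" in table.index


def test_mismatched_horizons_rejected(default_params):
    a = run_scenario(baseline_scenario(horizon_days=10.0, n_replications=1),
                     params=default_params)
    b = run_scenario(baseline_scenario(horizon_days=20.0, n_replications=1),
                     params=default_params)
    with pytest.raises(ValueError, match="horizon"):
        compare_scenarios([a, b])


def test_removing_unscheduled_stream_does_not_worsen_scheduled_delays(
        default_params):
    """Paired comparison under common random numbers: a scheduled-only
    service never shows larger mean scheduled perturbation than the
    mixed service."""
    kw = dict(horizon_days=60.0, n_replications=5, base_seed=11)
    base = run_scenario(baseline_scenario(**kw), params=default_params)
    oponly = run_scenario(op_only_scenario(**kw), params=default_params)
    d = (oponly.metrics["perturbation/scheduled"]
         - base.metrics["perturbation/scheduled"])
    assert d.mean() <= 1e-9


def test_higher_infection_prevalence_does_not_reduce_scheduled_scanner_waits(
        default_params):
    """Raising the unscheduled infectious proportion (all else equal,
    common random numbers) cannot shorten mean scheduled waits for the
    scanner."""
    from ctflow.metrics import _frame
    from ctflow.synthetic import simulate

    def mean_op_scanner_wait(p, seed):
        df = _frame(simulate(p, 40.0, seed))
        w = df[(df["activity"] == "wait_scanner")
               & df["cohort"].isin(("OP", "GP"))]
        n_sched = df.loc[df["cohort"].isin(("OP", "GP")), "entity_id"].nunique()
        return w["dur"].sum() / max(n_sched, 1)

    hi = default_params.with_overrides(
        {"cohorts": {c: {"p_infectious": 0.5} for c in ("IP", "ED")}})
    for seed in (21, 22, 23):
        assert mean_op_scanner_wait(hi, seed) \
            >= mean_op_scanner_wait(default_params, seed) - 1e-9


def test_added_scanner_capacity_does_not_steepen_waitlist(default_params):
    two = default_params.with_overrides({"scanners": 2})
    s1, _ = project_waitlist(default_params, 12, mode="micro", seed=9).slope()
    s2, _ = project_waitlist(two, 12, mode="micro", seed=9).slope()
    assert s2 <= s1 + 1e-9


def test_common_random_numbers_tighten_paired_comparison(default_params):
    """The paired-difference CI under common random numbers is no wider
    than under independent seeding, for the scheduled perturbation
    metric."""
    from ctflow.scenarios import _ci_halfwidth

    kw = dict(horizon_days=30.0, n_replications=6, base_seed=101)
    variant = {"p_ward_not_ready": min(1.0, default_params.p_ward_not_ready
                                       + 0.2)}
    base = run_scenario(baseline_scenario(**kw), params=default_params)
    crn = run_scenario(ScenarioConfig("variant", overrides=variant, **kw),
                       params=default_params)
    indep = run_scenario(
        ScenarioConfig("variant_indep", overrides=variant,
                       common_random_numbers=False, **kw),
        params=default_params)
    col = "perturbation/unscheduled"
    paired = crn.metrics[col].to_numpy() - base.metrics[col].to_numpy()
    unpaired = indep.metrics[col].to_numpy() - base.metrics[col].to_numpy()
    w_paired = _ci_halfwidth(pd.DataFrame({col: paired}))[col]
    w_unpaired = _ci_halfwidth(pd.DataFrame({col: unpaired}))[col]
    assert w_paired <= w_unpaired
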