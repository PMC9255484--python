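"""Workload metric definitions checked on hand-built logs and on
simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from ctflow.core import EventLog, Record
from ctflow.metrics import (
    UnknownEntityError,
    compute_report,
    consumed_staff_minutes,
    pct_time_scanning,
    perturbation,
    task_breakdown,
    time_in_system,
    utilization,
)


def _log(records) -> EventLog:
    log = EventLog(horizon_min=1440.0)
    for r in records:
        log.append(Record(*r))
    return log


def test_consumed_staff_minutes_is_duration_times_staff():
    # prep 4 min x 1 staff + scan 6 min x 1 + handling 2 min x 2 staff -> 14
    log = _log([
        ("A", "OP", "non_contrast", "prep", 0, 4, ("hca-1",), True),
        ("A", "OP", "non_contrast", "manual_handling_on", 4, 6,
         ("scanner-1", "rad-1", "hca-1"), True),
        ("A", "OP", "non_contrast", "scan", 6, 12, ("scanner-1", "rad-1"), True),
    ])
    assert consumed_staff_minutes(log, "A") == pytest.approx(14.0)


def test_tasks_outside_csm_categories_do_not_count():
    log = _log([
        ("A", "OP", "non_contrast", "paperwork", 0, 9, ("rad-1",), False),
        ("A", "OP", "non_contrast", "wait_scanner", 9, 12, (), False),
    ])
    assert consumed_staff_minutes(log, "A") == 0.0


def test_unknown_entity_raises():
    log = _log([("A", "OP", "non_contrast", "prep", 0, 4, ("hca-1",), True)])
    with pytest.raises(UnknownEntityError):
        consumed_staff_minutes(log, "B")
    with pytest.raises(UnknownEntityError):
        perturbation(log, "B")


def test_porter_minutes_excluded_by_default_but_configurable():
    recs = [("A", "IP", "non_contrast", "scan", 0, 6, ("scanner-1", "rad-1"),
             True)]
    assert consumed_staff_minutes(_log(recs), "A") == 6.0
    log2 = _log(recs + [("A", "IP", "non_contrast", "manual_handling_on",
                         6, 8, ("scanner-1", "rad-1", "porter-1"), True)])
    assert consumed_staff_minutes(log2, "A") == 8.0
    assert consumed_staff_minutes(log2, "A", include_porter=True) == 10.0


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def test_no_wait_records_means_zero_perturbation():
    log = _log([("A", "OP", "non_contrast", "scan", 0, 6,
                 ("scanner-1", "rad-1"), True)])
    assert perturbation(log, "A") == 0.0


def test_decontamination_delay_charged_to_causing_patient():
    """A's 60-min hold delays B's scan start by 12 min: those 12 min are
    A's perturbation, not B's; a later waiter C is not charged."""
    log = _log([
        ("A", "IP", "non_contrast", "scan", 90, 100, ("scanner-1", "rad-1"), True),
        ("A", "IP", "non_contrast", "decontamination", 100, 160, ("scanner-1",), False),
        ("B", "OP", "non_contrast", "wait_scanner", 148, 160, (), False),
        ("B", "OP", "non_contrast", "scan", 160, 166, ("scanner-1", "rad-1"), True),
        ("C", "OP", "non_contrast", "wait_scanner", 150, 190, (), False),
        ("C", "OP", "non_contrast", "scan", 190, 196, ("scanner-1", "rad-1"), True),
    ])
    assert perturbation(log, "A") == pytest.approx(12.0)
    assert perturbation(log, "B") == 0.0
    assert perturbation(log, "C") == 0.0


def test_wait_components_sum_into_perturbation():
    log = _log([
        ("A", "IP", "non_contrast", "wait_porter", 0, 5, (), False),
        ("A", "IP", "non_contrast", "ward_not_ready", 5, 15, (), False),
        ("A", "IP", "non_contrast", "wait_helper", 20, 22, (), False),
        ("A", "IP", "non_contrast", "wait_scanner", 30, 45, (), False),
    ])
    # the scanner queue wait is not attributed to the patient's type
    assert perturbation(log, "A") == pytest.approx(17.0)


# ---------------------------------------------------------------------------
# Time in system
# ---------------------------------------------------------------------------

def test_time_in_system_partition_hand_built():
    log = _log([
        ("A", "OP", "non_contrast", "radiology_arrival", 100, 100, (), False),
        ("A", "OP", "non_contrast", "prep", 100, 107, ("hca-1",), True),
        ("A", "OP", "non_contrast", "wait_scanner", 107, 114, (), False),
        ("A", "OP", "non_contrast", "scan", 114, 120, ("scanner-1", "rad-1"), True),
    ])
    assert time_in_system(log, "A") == pytest.approx((20.0, 13.0, 7.0))


def test_no_waits_means_zero_non_value_time():
    log = _log([
        ("A", "OP", "non_contrast", "radiology_arrival", 0, 0, (), False),
        ("A", "OP", "non_contrast", "scan", 0, 6, ("scanner-1", "rad-1"), True),
    ])
    total, value, non_value = time_in_system(log, "A")
    assert non_value == 0.0 and total == value == 6.0


def test_partition_identity_across_a_simulated_run(default_params):
    from ctflow.metrics import _frame, completed_entities
    from ctflow.synthetic import simulate

    log = simulate(default_params, 30.0, seed=21)
    df = _frame(log)
    for eid in completed_entities(df):
        total, value, non_value = time_in_system(df, eid)
        assert total - value - non_value == pytest.approx(0.0, abs=1e-9)
        assert value >= 0 and non_value >= -1e-9 and total >= value - 1e-9


# ---------------------------------------------------------------------------
# Utilization and scanning share
# ---------------------------------------------------------------------------

def test_utilization_full_and_half_shift(default_params):
    p = default_params.with_overrides({"staffing": {"radiographers_day": 1}})
    horizon = 1440.0  # one Monday
    busy_all = _log([("A", "OP", "non_contrast", "scan", 510, 1020,
                      ("scanner-1", "rad-1"), True)])
    assert utilization(busy_all, "radiographer", p, horizon) == pytest.approx(100.0)
    half = _log([("A", "OP", "non_contrast", "scan", 510, 765,
                  ("scanner-1", "rad-1"), True)])
    assert utilization(half, "radiographer", p, horizon) == pytest.approx(50.0)


def test_zero_roster_raises(default_params):
    log = _log([("A", "OP", "non_contrast", "scan", 0, 6,
                 ("scanner-1", "rad-1"), True)])
    with pytest.raises(ValueError, match="rostered"):
        utilization(log, "radiographer", default_params, 0.0)


def test_cognitive_booking_excluded_from_utilization_but_in_breakdown(default_params):
    p = default_params.with_overrides({"staffing": {"radiographers_day": 1}})
    log = _log([
        ("A", "IP", "non_contrast", "schedule_verify_request", 510, 765,
         ("rad-1",), False),
        ("A", "IP", "non_contrast", "scan", 765, 1020, ("scanner-1", "rad-1"),
         True),
    ])
    assert utilization(log, "radiographer", p, 1440.0) == pytest.approx(50.0)
    bd = task_breakdown(log, "radiographer", p)
    assert bd["schedule_verify_request"] == pytest.approx(255.0)


def test_pct_time_scanning_definitions():
    scan_only = _log([
        ("A", "OP", "non_contrast", "scan", 0, 6, ("scanner-1", "rad-1"), True),
        ("A", "OP", "non_contrast", "paperwork", 6, 8, ("rad-1",), False),
    ])
    assert pct_time_scanning(scan_only, "scheduled", "non_contrast") \
        == pytest.approx(100.0)
    half = _log([
        ("A", "OP", "non_contrast", "prep", 0, 6, ("hca-1",), True),
        ("A", "OP", "non_contrast", "scan", 6, 12, ("scanner-1", "rad-1"), True),
        ("A", "OP", "non_contrast", "paperwork", 12, 13, ("rad-1",), False),
    ])
    assert pct_time_scanning(half, "scheduled", "non_contrast") \
        == pytest.approx(50.0)
    with pytest.raises(ValueError, match="no completed"):
        pct_time_scanning(scan_only, "unscheduled", "non_contrast")


# ---------------------------------------------------------------------------
# Consistency of the two utilization paths
# ---------------------------------------------------------------------------

def test_busy_log_and_task_breakdown_agree_without_contention(ample_params):
    """With ample staff there are no assembly waits, so per-unit hold
    intervals and summed task records must agree exactly, and the
    breakdown totals must equal the busy-log totals."""
    from ctflow.metrics import _busy_minutes_by_unit, _frame
    from ctflow.synthetic import build_model

    model = build_model(ample_params, 7.0, seed=4)
    model.run_until()
    df = _frame(model.log)
    for pool in (model.radiographers, model.hcas):
        hold = {}
        for uid, start, end, _e, _l in pool.busy_log:
            hold[uid] = hold.get(uid, 0.0) + (end - start)
        units = sorted(hold)
        from_records = _busy_minutes_by_unit(df, units, physical_only=False)
        for uid in units:
            assert from_records[uid] == pytest.approx(hold[uid], abs=1e-6), uid


def test_report_contains_cohort_tables_and_valid_ranges(default_params):
    from ctflow.synthetic import simulate

    log = simulate(default_params, 14.0, seed=6)
    rep = compute_report(log, default_params)
    assert set(rep.csm_by_cohort) <= {"OP", "GP", "IP", "ED"}
    for role, u in rep.utilization.items():
        assert 0.0 <= u <= 100.0, role
    for cell, v in rep.pct_scanning.items():
        assert 0.0 < v <= 100.0, cell
    for cell, v in rep.csm.items():
        assert v > 0, cell
    table = rep.table()
    assert list(table.columns) == ["unscheduled", "scheduled"]
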