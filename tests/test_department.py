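"""Pathway composition, same-day scheduling, infection control and
porter logistics."""

from __future__ import annotations

import numpy as np
import pytest

from ctflow.department import (
    CTDepartmentModel,
    ExamRequest,
    PathwayError,
    SCHEDULE_STEP_ACTIVITIES,
    build_pathway,
    decontamination_hold,
    ip_on_day_scheduling,
    op_on_day_scheduling,
)
from ctflow.params import EXAM_CLASSES, MOBILITIES

from conftest import sweepline_check


def _req(cohort="OP", exam_class="non_contrast", mobility="walking",
         infectious=False, **kw):
    scheduled = cohort in ("OP", "GP")
    return ExamRequest(id=kw.pop("id", "x-1"), cohort=cohort,
                       exam_class=exam_class, mobility=mobility,
                       infectious=infectious, urgency=kw.pop("urgency", 2),
                       referral_time=kw.pop("referral_time", 0.0),
                       scheduled_slot=0.0 if scheduled else None)


# ---------------------------------------------------------------------------
# Pathway composition
# ---------------------------------------------------------------------------

def test_minimal_outpatient_pathway(default_params):
    pw = build_pathway(_req(), default_params)
    tasks = [s.task for s in pw.steps]
    assert tasks == ["prep", "scan", "standard_clean", "post_processing",
                     "paperwork"]
    assert not any(t.startswith(("transport", "manual_handling", "schedule"))
                   for t in tasks)


def test_bedbound_infectious_inpatient_pathway(default_params):
    pw = build_pathway(_req("IP", "non_contrast", "bed", True, urgency=1),
                       default_params)
    tasks = [s.task for s in pw.steps]
    assert sum(t in SCHEDULE_STEP_ACTIVITIES for t in tasks) == 6
    assert tasks.count("transport_in") == 1 and tasks.count("transport_out") == 1
    handling = [s for s in pw.steps if s.task.startswith("manual_handling")]
    assert len(handling) == 2
    assert all(s.staff_count == 2 for s in handling)
    assert "decontamination" in tasks and "standard_clean" not in tasks


def test_unknown_exam_class_rejected():
    with pytest.raises(PathwayError, match="exam class"):
        _req(exam_class="fluoroscopy")


def test_pathway_invariants_hold_over_attribute_space(default_params):
    """Attribute -> pathway mapping is total, deterministic, and obeys
    its structural invariants across the whole sampled space."""
    rng = np.random.default_rng(2024)
    cohorts = ("OP", "GP", "IP", "ED")
    for _ in range(10_000):
        req = _req(cohorts[rng.integers(4)],
                   EXAM_CLASSES[rng.integers(3)],
                   MOBILITIES[rng.integers(3)],
                   bool(rng.integers(2)))
        pw = build_pathway(req, default_params)
        pw.check_invariants()
        again = build_pathway(req, default_params)
        assert [s.task for s in again.steps] == [s.task for s in pw.steps]


# ---------------------------------------------------------------------------
# Same-day scheduling steps
# ---------------------------------------------------------------------------

def test_inpatient_same_day_scheduling_has_six_radiographer_steps(default_params):
    steps = ip_on_day_scheduling(_req("IP", mobility="bed"), default_params)
    assert len(steps) == 6
    assert all(s.radiographers == 1 and s.cognitive for s in steps)
    assert all(s.csm_category == "prep" for s in steps)


def test_scheduled_cohorts_have_no_on_day_steps(default_params):
    assert op_on_day_scheduling(_req("OP"), default_params) == []
    with pytest.raises(PathwayError, match="advance"):
        ip_on_day_scheduling(_req("OP"), default_params)
    with pytest.raises(PathwayError):
        op_on_day_scheduling(_req("IP"), default_params)


def test_degenerate_zero_scheduling_steps_add_no_minutes(default_params):
    p = default_params.with_overrides(
        {"tasks": {"schedule_step": {"mean": 0.0, "cv": 0.0}}})
    steps = ip_on_day_scheduling(_req("ED", urgency=0), p)
    assert sum(s.mean for s in steps) == 0.0


# ---------------------------------------------------------------------------
# Infection control
# ---------------------------------------------------------------------------

def test_decontamination_hold_durations(default_params):
    assert decontamination_hold(_req("IP", infectious=True, mobility="bed"),
                                default_params) == 60.0
    p = default_params.with_overrides({"standard_clean_minutes": 0.0})
    assert decontamination_hold(_req(), p) == 0.0


def test_negative_decontamination_config_rejected(default_params):
    with pytest.raises(ValueError):
        default_params.with_overrides({"decon_minutes": -5.0})


def _two_patient_model(params, requests, horizon_days=2.0):
    model = CTDepartmentModel(params, seed=9, horizon_days=horizon_days)
    for req in requests:
        model.sim.schedule(req.referral_time, "arrival", req.id,
                           payload=lambda evt, r=req: model.add_request(r))
    model.run_until()
    return model


def test_consecutive_infectious_patients_block_scanner_sequentially(ample_params):
    """Sweep-line on a hand-built two-patient run: scanner busy + blocked
    intervals never overlap and each hold includes the 60-min
    decontamination."""
    p = ample_params.with_overrides(
        {"tasks": {name: {"cv": 0.0} for name in ample_params.tasks}})
    reqs = [_req("IP", "non_contrast", "walking", True, id="IP-00001",
                 urgency=1, referral_time=600.0),
            _req("IP", "non_contrast", "walking", True, id="IP-00002",
                 urgency=1, referral_time=605.0)]
    model = _two_patient_model(p, reqs)
    decons = [r for r in model.log.records if r.activity == "decontamination"]
    assert len(decons) == 2
    assert all(r.end_min - r.start_min == pytest.approx(60.0) for r in decons)
    sweepline_check(model.scanner.busy_log, capacity=model.scanner.capacity)


# ---------------------------------------------------------------------------
# Porter dispatch
# ---------------------------------------------------------------------------

def test_second_simultaneous_transport_waits_one_leg(default_params):
    p = default_params.with_overrides({
        "staffing": {"porters": 1, "radiographers_day": 6, "hcas_day": 4},
        "p_ward_not_ready": 0.0,
        "tasks": {"transport_leg": {"mean": 10.0, "cv": 0.0},
                  "schedule_step": {"mean": 0.0, "cv": 0.0}},
    })
    reqs = [_req("IP", "non_contrast", "walking", False, id="IP-00001",
                 urgency=1, referral_time=600.0),
            _req("IP", "non_contrast", "walking", False, id="IP-00002",
                 urgency=1, referral_time=600.0)]
    model = _two_patient_model(p, reqs)
    waits = [r for r in model.log.records if r.activity == "wait_porter"]
    assert len(waits) == 1
    assert waits[0].end_min - waits[0].start_min == pytest.approx(10.0)
    t_in = sorted(r.start_min for r in model.log.records
                  if r.activity == "transport_in")
    assert t_in[1] - t_in[0] == pytest.approx(10.0)


def test_ward_never_ready_delays_every_transport(default_params):
    p = default_params.with_overrides({
        "p_ward_not_ready": 1.0,
        "ward_not_ready_delay": {"mean": 10.0, "cv": 0.0},
    })
    reqs = [_req("IP", "non_contrast", "walking", False, id="IP-00001",
                 urgency=1, referral_time=600.0)]
    model = _two_patient_model(p, reqs)
    wnr = [r for r in model.log.records if r.activity == "ward_not_ready"]
    assert len(wnr) == 1
    assert wnr[0].end_min - wnr[0].start_min == pytest.approx(10.0)
    t_in = [r for r in model.log.records if r.activity == "transport_in"]
    assert t_in[0].start_min == pytest.approx(wnr[0].end_min)


def test_walking_outpatients_never_use_porters_or_decontamination(default_params):
    """The dominant OP configuration consumes neither porter time nor
    scanner decontamination downtime."""
    from ctflow.synthetic import simulate

    p = default_params.with_overrides({
        "cohorts": {c: {"p_infectious": 0.0,
                        "mobility_mix": {"walking": 1.0, "wheelchair": 0.0,
                                         "bed": 0.0}}
                    for c in ("OP", "GP")}})
    log = simulate(p, 7.0, seed=5)
    sched = {r.entity_id for r in log.records if r.cohort in ("OP", "GP")}
    for rec in log.records:
        if rec.entity_id in sched:
            assert rec.activity not in ("transport_in", "transport_out",
                                        "wait_porter", "decontamination")
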