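"""The CT department model.

Encodes patient cohorts and attributes, the task network each
examination follows (same-day booking micro-steps for unscheduled
cases, preparation, cannulation, porter transport, manual handling,
scanning, infection-control holds, observation and clerical wrap-up),
the staffing and skill mix, and the resource logic binding them to the
single scanner.

The pathway for a given examination request is a *deterministic* and
*total* function of its attributes (:func:`build_pathway`); the
simulator executes the same pathway against resource pools, so the
expected workload of a patient profile can be computed in closed form
from the pathway alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .core import (
    Calendar,
    EventLog,
    Record,
    ResourcePool,
    Simulator,
    Timeout,
    RandomStreams,
    Unit,
    sample_duration,
)
from .params import (
    N_SCHEDULE_STEPS,
    ParameterSet,
    SCHEDULED_COHORTS,
    UNSCHEDULED_COHORTS,
)

# Claim priorities within staff pools (lower = more urgent).  Transfers at
# an idle scanner outrank everything; booking paperwork yields to patients.
PRI_ATTEND = 0
PRI_CANNULATE = 1
PRI_PHYSICAL = 2
PRI_COGNITIVE = 3

#: Labels of the six same-day booking micro-steps a radiographer must
#: complete before an unscheduled case can be scanned.
SCHEDULE_STEP_LABELS = (
    "verify_request",
    "safety_questions",
    "confirm_infection_status",
    "arrange_ward_preparation",
    "arrange_transport",
    "allocate_slot",
)

SCHEDULE_STEP_ACTIVITIES = frozenset(f"schedule_{lbl}" for lbl in SCHEDULE_STEP_LABELS)


class PathwayError(ValueError):
    pass


@dataclass
class ExamRequest:
    """One patient/examination flowing through the system."""

    id: str
    cohort: str
    exam_class: str
    mobility: str
    infectious: bool
    urgency: int
    referral_time: float
    scheduled_slot: Optional[float] = None
    timestamps: dict = field(default_factory=dict)

    @property
    def is_scheduled(self) -> bool:
        return self.cohort in SCHEDULED_COHORTS

    @property
    def involves_iv(self) -> bool:
        return self.exam_class in ("iv_contrast", "oral_and_iv")

    def __post_init__(self) -> None:
        if self.cohort not in SCHEDULED_COHORTS + UNSCHEDULED_COHORTS:
            raise PathwayError(f"unknown cohort {self.cohort!r}")
        if self.exam_class not in ("non_contrast", "iv_contrast", "oral_and_iv"):
            raise PathwayError(f"unknown exam class {self.exam_class!r}")
        if self.is_scheduled and self.scheduled_slot is None:
            raise PathwayError(f"{self.cohort} request must carry a scheduled slot")
        if not self.is_scheduled and self.scheduled_slot is not None:
            raise PathwayError(f"{self.cohort} request is scheduled on the day; "
                               "scheduled_slot must be null")


@dataclass(frozen=True)
class PathwayStep:
    """One realized task: who it occupies, for how long on average."""

    task: str                       # activity name recorded in the log
    mean: float
    cv: float = 0.0
    dist: str = "fixed"
    radiographers: int = 0
    hcas: int = 0
    porters: int = 0
    uses_scanner: bool = False
    requires_cannulator: bool = False
    value_adding: bool = False
    csm_category: Optional[str] = None   # prep | scan | handling | observation
    cognitive: bool = False

    @property
    def staff_count(self) -> int:
        return self.radiographers + self.hcas

    def sample(self, rng: np.random.Generator) -> float:
        return sample_duration(rng, self.mean, self.cv, self.dist)


@dataclass
class Pathway:
    request: ExamRequest
    steps: list[PathwayStep]

    def check_invariants(self) -> None:
        names = [s.task for s in self.steps]
        if sum(n.startswith("scan") for n in names) != 1:
            raise PathwayError("pathway must contain the scan exactly once")
        has_decon = "decontamination" in names
        if has_decon != self.request.infectious:
            raise PathwayError("decontamination hold present iff infectious")
        has_transport = "transport_in" in names
        if has_transport != (not self.request.is_scheduled):
            raise PathwayError("porter transport present iff unscheduled cohort")
        has_cann = "cannulation" in names
        if has_cann != self.request.involves_iv:
            raise PathwayError("cannulation present iff the exam involves IV")
        n_handling = sum(n.startswith("manual_handling") for n in names)
        expected = 0 if self.request.mobility == "walking" else 2
        if n_handling != expected:
            raise PathwayError("manual handling occurs twice for non-ambulant "
                               "patients and never for walking patients")


def _dist_step(params: ParameterSet, task_key: str, activity: str, **kw) -> PathwayStep:
    d = params.tasks[task_key]
    return PathwayStep(task=activity, mean=d.mean, cv=d.cv, dist=d.dist, **kw)


def ip_on_day_scheduling(request: ExamRequest, params: ParameterSet) -> list[PathwayStep]:
    """The six booking micro-steps radiographers complete on the day of
    scanning for unscheduled (IP/ED) cases.

    Each step occupies one radiographer; the work is cognitive, so it
    counts toward consumed staff minutes but not toward the physical-task
    utilization numerator.  Raises for scheduled cohorts, whose booking is
    completed in advance by clerical staff and is off-model.
    """
    if request.is_scheduled:
        raise PathwayError(
            f"{request.cohort} booking is completed in advance off-model; "
            "same-day scheduling applies to IP/ED only")
    steps = []
    for lbl in SCHEDULE_STEP_LABELS:
        key = f"schedule_step_{lbl}" if f"schedule_step_{lbl}" in params.tasks \
            else "schedule_step"
        steps.append(_dist_step(params, key, f"schedule_{lbl}",
                                radiographers=1, csm_category="prep",
                                cognitive=True))
    assert len(steps) == N_SCHEDULE_STEPS
    return steps


def op_on_day_scheduling(request: ExamRequest, params: ParameterSet) -> list[PathwayStep]:
    """On-day booking work for scheduled cohorts: none (pre-done)."""
    if not request.is_scheduled:
        raise PathwayError("unscheduled cases require same-day scheduling")
    return []


def decontamination_hold(request: ExamRequest, params: ParameterSet) -> float:
    """Scanner-blocking minutes after this patient's scan.

    Infectious patients trigger room decontamination and passive air
    exchange (default 60 min, configurable at most 60); everyone else a
    short standard clean.
    """
    return params.decon_minutes if request.infectious else params.standard_clean_minutes


def build_pathway(request: ExamRequest, params: ParameterSet) -> Pathway:
    """Deterministic mapping from examination attributes to the task list."""
    p = params
    steps: list[PathwayStep] = []
    unsched = not request.is_scheduled
    iv = request.involves_iv
    oral = request.exam_class == "oral_and_iv"

    if unsched:
        steps += ip_on_day_scheduling(request, p)
        if oral:
            steps.append(PathwayStep("oral_drink", mean=p.oral_drink_minutes))
        steps.append(_dist_step(p, "transport_leg", "transport_in", porters=1))

    steps.append(_dist_step(p, "prep", "prep", hcas=1, value_adding=True,
                            csm_category="prep"))
    if oral:
        steps.append(_dist_step(p, "oral_supervision", "oral_supervision", hcas=1,
                                value_adding=True, csm_category="prep"))
    if iv:
        steps.append(_dist_step(p, "cannulation", "cannulation", radiographers=1,
                                requires_cannulator=True, value_adding=True,
                                csm_category="prep"))
        steps.append(_dist_step(p, "injector_setup", "injector_setup",
                                radiographers=1))

    handling = None
    if request.mobility == "wheelchair":
        handling = ("manual_handling_wheelchair", dict(radiographers=1))
    elif request.mobility == "bed":
        handling = ("manual_handling_bed", dict(radiographers=1, hcas=1))
    if handling:
        steps.append(_dist_step(p, handling[0], "manual_handling_on",
                                uses_scanner=True, value_adding=True,
                                csm_category="handling", **handling[1]))

    scan_key = p.scan_task(request.cohort, request.exam_class)
    steps.append(_dist_step(p, scan_key, "scan", radiographers=1,
                            uses_scanner=True, value_adding=True,
                            csm_category="scan"))
    if handling:
        steps.append(_dist_step(p, handling[0], "manual_handling_off",
                                uses_scanner=True, value_adding=True,
                                csm_category="handling", **handling[1]))

    if request.infectious:
        steps.append(PathwayStep("decontamination",
                                 mean=decontamination_hold(request, p),
                                 uses_scanner=True))
    else:
        steps.append(PathwayStep("standard_clean",
                                 mean=decontamination_hold(request, p),
                                 radiographers=1, uses_scanner=True))

    if iv:
        steps.append(_dist_step(p, "cannula_removal", "cannula_removal",
                                radiographers=1, value_adding=True))
        steps.append(_dist_step(p, "observation", "observation", hcas=1,
                                csm_category="observation"))
    if unsched:
        steps.append(_dist_step(p, "transport_coordination",
                                "transport_coordination", hcas=1))
        steps.append(_dist_step(p, "transport_leg", "transport_out", porters=1))

    steps.append(_dist_step(p, "post_processing", "post_processing",
                            radiographers=1))
    steps.append(_dist_step(p, "paperwork", "paperwork", radiographers=1))

    pw = Pathway(request, steps)
    pw.check_invariants()
    return pw


# ---------------------------------------------------------------------------
# Simulation model
# ---------------------------------------------------------------------------

class CTDepartmentModel:
    """Binds the pathway logic to resource pools and an event clock.

    Day staff work the weekday shift; a small on-call complement (whose
    roster is the complement of the day shift plus weekends) covers the
    24/7 emergency service.  The scanner is non-preemptive; urgency acts
    on queue order only.
    """

    def __init__(self, params: ParameterSet, seed: int,
                 horizon_days: float) -> None:
        self.params = params
        self.horizon_min = horizon_days * 1440.0
        self.sim = Simulator()
        self.streams = RandomStreams(seed)
        self.log = EventLog(self.horizon_min)
        self.arrival_counts: dict[str, int] = {}
        self.completed_counts: dict[str, int] = {}
        self._open_entities: set[str] = set()
        self._build_pools()

    # -- pools --------------------------------------------------------------

    def _build_pools(self) -> None:
        p = self.params
        st = p.staffing
        if p.protect_lunch:
            day_cal = Calendar({d: [(st.day_shift_start, p.lunch_start),
                                    (p.lunch_end, st.day_shift_end)]
                                for d in range(5)})
        else:
            day_cal = Calendar.weekdays(st.day_shift_start, st.day_shift_end)
        oncall_week = {d: [(0.0, st.day_shift_start), (st.day_shift_end, 1440.0)]
                       for d in range(5)}
        oncall_week.update({d: [(0.0, 1440.0)] for d in (5, 6)})
        oncall_cal = Calendar(oncall_week)

        n_cann = max(1, round(st.p_cannulate * st.radiographers_day)) \
            if st.radiographers_day else 0
        rad_units = []
        # non-cannulators first so generic claims leave cannulators free
        for i in range(st.radiographers_day - n_cann):
            rad_units.append(Unit(f"rad-{i + 1}", day_cal, frozenset({"day"})))
        for i in range(st.radiographers_day - n_cann, st.radiographers_day):
            rad_units.append(Unit(f"rad-{i + 1}", day_cal,
                                  frozenset({"day", "can_cannulate"})))
        for i in range(st.on_call_radiographers):
            rad_units.append(Unit(f"rad-oc-{i + 1}", oncall_cal,
                                  frozenset({"can_cannulate"})))
        hca_units = [Unit(f"hca-{i + 1}", day_cal, frozenset({"day"}))
                     for i in range(st.hcas_day)]
        hca_units += [Unit(f"hca-oc-{i + 1}", oncall_cal)
                      for i in range(st.on_call_hcas)]
        always = Calendar.always_open()
        self.radiographers = ResourcePool(self.sim, "radiographer", rad_units)
        self.hcas = ResourcePool(self.sim, "hca", hca_units)
        self.porters = ResourcePool(
            self.sim, "porter",
            [Unit(f"porter-{i + 1}", always) for i in range(st.porters)])
        self.scanner = ResourcePool(
            self.sim, "scanner",
            [Unit(f"scanner-{i + 1}", always) for i in range(p.scanners)])

    # -- logging helpers ----------------------------------------------------

    def _rec(self, req: ExamRequest, activity: str, start: float, end: float,
             resources=(), value: bool = False) -> None:
        self.log.append(Record(req.id, req.cohort, req.exam_class, activity,
                               start, end, tuple(resources), value))

    def _task_rng(self, task: str) -> np.random.Generator:
        return self.streams.get(f"task:{task}")

    # -- entity lifecycle ----------------------------------------------------

    def add_request(self, req: ExamRequest) -> None:
        self.arrival_counts[req.cohort] = self.arrival_counts.get(req.cohort, 0) + 1
        self._open_entities.add(req.id)
        self.sim.process(self._patient_process(req), req.id)

    def _exec_step(self, req: ExamRequest, step: PathwayStep,
                   priority: int, held=()) -> Iterator:
        """Acquire the step's staff, run it, release.  ``held`` resources
        are already granted and are listed on the record."""
        acquired = []
        t_req = self.sim.now
        for _ in range(step.radiographers):
            units = yield self.radiographers.acquire(
                req.id, priority,
                require_tag="can_cannulate" if step.requires_cannulator else None,
                label=step.task)
            acquired += units
        for _ in range(step.hcas):
            units = yield self.hcas.acquire(req.id, priority, label=step.task)
            acquired += units
        for _ in range(step.porters):
            units = yield self.porters.acquire(req.id, priority, label=step.task)
            acquired += units
        wait = self.sim.now - t_req
        if wait > 1e-9:
            self._rec(req, "wait_porter" if step.porters else "wait_staff",
                      t_req, self.sim.now)
        dur = step.sample(self._task_rng(step.task))
        t0 = self.sim.now
        yield Timeout(dur)
        res = [u.uid for u in held] + [u.uid for u in acquired]
        self._rec(req, step.task, t0, self.sim.now, res, step.value_adding)
        for u in acquired:
            if u.uid.startswith("porter"):
                self.porters.release([u])
            elif u.uid.startswith("rad"):
                self.radiographers.release([u])
            else:
                self.hcas.release([u])

    def _patient_process(self, req: ExamRequest) -> Iterator:
        p = self.params
        pathway = build_pathway(req, p)
        steps = {s.task: s for s in pathway.steps}
        unsched = not req.is_scheduled

        if unsched:
            # six same-day booking micro-steps, one radiographer sitting
            booking = [s for s in pathway.steps
                       if s.task in SCHEDULE_STEP_ACTIVITIES]
            rad = yield self.radiographers.acquire(req.id, PRI_COGNITIVE,
                                                   label="booking")
            for s in booking:
                dur = s.sample(self._task_rng("schedule_step"))
                t0 = self.sim.now
                yield Timeout(dur)
                self._rec(req, s.task, t0, self.sim.now, [rad[0].uid], False)
            self.radiographers.release(rad)
            if "oral_drink" in steps:
                t0 = self.sim.now
                yield Timeout(steps["oral_drink"].mean)
                self._rec(req, "oral_drink", t0, self.sim.now)
            # porter transport to the department, ward possibly not ready
            t_req = self.sim.now
            porter = yield self.porters.acquire(req.id, req.urgency,
                                                label="transport_in")
            if self.sim.now > t_req + 1e-9:
                self._rec(req, "wait_porter", t_req, self.sim.now)
            if self.streams.get("ward_not_ready").random() < p.p_ward_not_ready:
                d = sample_duration(self.streams.get("ward_not_ready_delay"),
                                    p.ward_not_ready_delay.mean,
                                    p.ward_not_ready_delay.cv,
                                    p.ward_not_ready_delay.dist)
                t0 = self.sim.now
                yield Timeout(d)
                self._rec(req, "ward_not_ready", t0, self.sim.now)
            s = steps["transport_in"]
            dur = s.sample(self._task_rng("transport_leg"))
            t0 = self.sim.now
            yield Timeout(dur)
            self._rec(req, "transport_in", t0, self.sim.now, [porter[0].uid])
            self.porters.release(porter)

        self._rec(req, "radiology_arrival", self.sim.now, self.sim.now)
        req.timestamps["radiology_arrival"] = self.sim.now

        yield from self._exec_step(req, steps["prep"], PRI_PHYSICAL)
        if "oral_supervision" in steps:
            yield from self._exec_step(req, steps["oral_supervision"], PRI_PHYSICAL)
        if req.involves_iv:
            yield from self._exec_step(req, steps["cannulation"], PRI_CANNULATE)
            yield from self._exec_step(req, steps["injector_setup"], PRI_PHYSICAL)

        # --- scanner block: transfer on, scan, transfer off, clean/decon ---
        t_req = self.sim.now
        scanner = yield self.scanner.acquire(req.id, req.urgency, label="scan")
        if self.sim.now > t_req + 1e-9:
            self._rec(req, "wait_scanner", t_req, self.sim.now)
        t_grant = self.sim.now
        rad = yield self.radiographers.acquire(req.id, PRI_ATTEND, label="scan")
        helpers = []
        if req.mobility == "bed":
            helpers = yield self.hcas.acquire(req.id, PRI_ATTEND,
                                              label="manual_handling")
        if self.sim.now > t_grant + 1e-9:
            # staff-assembly delay at an available scanner counts as a
            # manual-handling wait only when a transfer is actually needed
            kind = "wait_staff" if req.mobility == "walking" else "wait_helper"
            self._rec(req, kind, t_grant, self.sim.now)

        staff_ids = [rad[0].uid] + [u.uid for u in helpers]
        handling = next((s for s in pathway.steps
                         if s.task == "manual_handling_on"), None)
        if handling is not None:
            dur = handling.sample(self._task_rng(handling.task))
            t0 = self.sim.now
            yield Timeout(dur)
            self._rec(req, "manual_handling_on", t0, self.sim.now,
                      [scanner[0].uid] + staff_ids, True)
        if helpers:
            # the extra pair of hands leaves during the scan itself
            self.hcas.release(helpers)

        scan_step = next(s for s in pathway.steps if s.task == "scan")
        dur = scan_step.sample(self._task_rng(scan_step.task))
        t0 = self.sim.now
        yield Timeout(dur)
        self._rec(req, "scan", t0, self.sim.now, [scanner[0].uid, rad[0].uid], True)
        req.timestamps["scan_end"] = self.sim.now

        if handling is not None:
            helpers = []
            if req.mobility == "bed":
                t1 = self.sim.now
                helpers = yield self.hcas.acquire(req.id, PRI_ATTEND,
                                                  label="manual_handling")
                if self.sim.now > t1 + 1e-9:
                    self._rec(req, "wait_helper", t1, self.sim.now)
            dur = handling.sample(self._task_rng(handling.task))
            t0 = self.sim.now
            yield Timeout(dur)
            self._rec(req, "manual_handling_off", t0, self.sim.now,
                      [scanner[0].uid] + [rad[0].uid] + [u.uid for u in helpers],
                      True)
            if helpers:
                self.hcas.release(helpers)

        if req.infectious:
            self.radiographers.release(rad)
            t0 = self.sim.now
            yield Timeout(p.decon_minutes)
            self._rec(req, "decontamination", t0, self.sim.now, [scanner[0].uid])
            self.scanner.release(scanner)
        else:
            t0 = self.sim.now
            yield Timeout(p.standard_clean_minutes)
            self._rec(req, "standard_clean", t0, self.sim.now,
                      [scanner[0].uid, rad[0].uid])
            self.radiographers.release(rad)
            self.scanner.release(scanner)

        if req.involves_iv:
            yield from self._exec_step(req, steps["cannula_removal"], PRI_PHYSICAL)
            yield from self._exec_step(req, steps["observation"], PRI_PHYSICAL)
        if unsched:
            yield from self._exec_step(req, steps["transport_coordination"],
                                       PRI_PHYSICAL)
            yield from self._exec_step(req, steps["transport_out"], req.urgency)

        yield from self._exec_step(req, steps["post_processing"], PRI_COGNITIVE)
        yield from self._exec_step(req, steps["paperwork"], PRI_COGNITIVE)

        self._open_entities.discard(req.id)
        self.completed_counts[req.cohort] = \
            self.completed_counts.get(req.cohort, 0) + 1

    # -- run -----------------------------------------------------------------

    def run_until(self, t_end: Optional[float] = None) -> EventLog:
        t_end = self.horizon_min if t_end is None else t_end
        self.sim.run_until(t_end)
        self.log.in_flight = set(self._open_entities)
        self.log.records.sort(key=lambda r: (r.start_min, r.end_min, r.entity_id))
        return self.log
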