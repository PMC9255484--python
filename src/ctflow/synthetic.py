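"""Synthetic demand generation.

The department's historic information-system extracts are not public, so
arrival streams and patient attributes are generated with the structure
the analysis assumes: scheduled OP/GP work fills a weekday slot template
around the lunch closure, unscheduled IP/ED work arrives around the
clock as a nonhomogeneous Poisson process with a daytime-peaked diurnal
profile, and per-cohort attribute mixes make inpatients less mobile and
more often infectious than outpatients.
"""

from __future__ import annotations

from functools import partial

import numpy as np
import pandas as pd

from .core import EventLog, RandomStreams
from .department import CTDepartmentModel, ExamRequest
from .params import ParameterSet

ARRIVAL_COLUMNS = ["arrival_min", "cohort"]


def generate_arrivals(params: ParameterSet, horizon_days: float,
                      streams: RandomStreams) -> pd.DataFrame:
    """Arrival stream over the horizon: (arrival_min, cohort), sorted.

    Scheduled arrivals fill the weekday slot template deterministically
    (minus no-shows); unscheduled arrivals follow a Poisson process whose
    daily intensity integrates to the rate implied by the annual volume
    target, shaped by the hourly weights.
    """
    if horizon_days <= 0:
        raise ValueError(f"horizon_days must be positive, got {horizon_days}")
    n_days = int(np.ceil(horizon_days))
    rows: list[tuple[float, str]] = []

    sched = params.scheduled
    rng_s = streams.get("arrivals:scheduled")
    s_cohorts = sorted(sched.cohort_mix)
    s_probs = [sched.cohort_mix[c] for c in s_cohorts]
    for day in range(n_days):
        if day % 7 not in sched.weekdays:
            continue
        for slot in sched.slot_times:
            t = day * 1440.0 + slot
            if t >= horizon_days * 1440.0:
                continue
            if sched.no_show_prob > 0 and rng_s.random() < sched.no_show_prob:
                continue
            cohort = s_cohorts[rng_s.choice(len(s_cohorts), p=s_probs)]
            rows.append((t, cohort))

    rate = params.unscheduled_daily_rate
    if rate > 0:
        rng_u = streams.get("arrivals:unscheduled")
        w = np.asarray(params.unscheduled.hourly_weights, dtype=float)
        w = w / w.sum()
        u_cohorts = sorted(params.unscheduled.cohort_mix)
        u_probs = [params.unscheduled.cohort_mix[c] for c in u_cohorts]
        for day in range(n_days):
            n = rng_u.poisson(rate)
            if n == 0:
                continue
            hours = rng_u.choice(24, size=n, p=w)
            times = day * 1440.0 + hours * 60.0 + rng_u.random(n) * 60.0
            cohorts = rng_u.choice(len(u_cohorts), size=n, p=u_probs)
            for t, c in zip(times, cohorts):
                if t < horizon_days * 1440.0:
                    rows.append((float(t), u_cohorts[c]))

    rows.sort()
    return pd.DataFrame(rows, columns=ARRIVAL_COLUMNS)


def sample_attributes(cohort: str, params: ParameterSet,
                      rng: np.random.Generator):
    """Draw (exam_class, mobility, infectious, urgency) for one arrival.

    Defaults in the calibrated configuration make P(infectious | IP)
    exceed P(infectious | OP) and inpatients far less likely to walk,
    reflecting the case-mix differences between the cohorts.
    """
    spec = params.cohorts[cohort]
    classes = sorted(spec.exam_class_mix)
    exam_class = classes[rng.choice(len(classes),
                                    p=[spec.exam_class_mix[c] for c in classes])]
    mobilities = sorted(spec.mobility_mix)
    mobility = mobilities[rng.choice(len(mobilities),
                                     p=[spec.mobility_mix[m] for m in mobilities])]
    infectious = bool(rng.random() < spec.p_infectious)
    return exam_class, mobility, infectious, spec.urgency


def build_model(params: ParameterSet, horizon_days: float,
                seed: int) -> CTDepartmentModel:
    """Department model with the full arrival stream scheduled onto it."""
    model = CTDepartmentModel(params, seed, horizon_days)
    arrivals = generate_arrivals(params, horizon_days, model.streams)
    counters: dict[str, int] = {}
    for row in arrivals.itertuples(index=False):
        cohort = row.cohort
        counters[cohort] = counters.get(cohort, 0) + 1
        rng = model.streams.get(f"attrs:{cohort}")
        exam_class, mobility, infectious, urgency = sample_attributes(
            cohort, params, rng)
        scheduled = cohort in ("OP", "GP")
        req = ExamRequest(
            id=f"{cohort}-{counters[cohort]:05d}",
            cohort=cohort, exam_class=exam_class, mobility=mobility,
            infectious=infectious, urgency=urgency,
            referral_time=row.arrival_min,
            scheduled_slot=row.arrival_min if scheduled else None)
        model.sim.schedule(row.arrival_min, "arrival", req.id,
                           payload=partial(_on_arrival, model, req))
    return model


def _on_arrival(model: CTDepartmentModel, req: ExamRequest, _evt) -> None:
    model.add_request(req)


def simulate(params: ParameterSet, horizon_days: float, seed: int) -> EventLog:
    """Run the department for ``horizon_days`` and return the event log."""
    model = build_model(params, horizon_days, seed)
    return model.run_until()


def generate_reference_log(params: ParameterSet, horizon_days: float,
                           seed: int) -> EventLog:
    """Synthetic stand-in for a historic process log.

    Runs the simulator under a designated ground-truth seed; the result
    serves as the reference in mean-error validation experiments.
    """
    return simulate(params, horizon_days, seed)
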