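"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ctflow.calibration import calibrate_defaults
from ctflow.params import ParameterSet


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    """The calibrated default configuration (analytic solve, fast)."""
    return calibrate_defaults()


@pytest.fixture(scope="session")
def ample_params(default_params) -> ParameterSet:
    """Contention-free variant: staff and scanners far exceed demand and
    stochastic delays are switched off, so queue waits are zero and
    hand-computed schedules are exact."""
    over = {
        "staffing": {"radiographers_day": 8, "hcas_day": 6, "porters": 5,
                     "on_call_radiographers": 3, "on_call_hcas": 3},
        "scanners": 3,
        "p_ward_not_ready": 0.0,
    }
    return default_params.with_overrides(over)


def lindley_waits(interarrivals, services):
    """Exact single-server FIFO waiting times.

    ``interarrivals[i]`` is the gap between customer i-1 and i
    (interarrivals[0] is the first arrival time); independent oracle for
    the event kernel: W_1 = 0, W_{n+1} = max(0, W_n + S_n - A_{n+1}).
    """
    w = [0.0]
    for s, a in zip(services[:-1], interarrivals[1:]):
        w.append(max(0.0, w[-1] + s - a))
    return w


def sweepline_check(busy_log, capacity, calendar=None):
    """Assert no unit overlaps itself and concurrency never exceeds
    capacity; with a calendar, every hold must start while it is open."""
    by_unit: dict[str, list[tuple[float, float]]] = {}
    events = []
    for uid, start, end, _entity, _label in busy_log:
        by_unit.setdefault(uid, []).append((start, end))
        events.append((start, 1))
        events.append((end, -1))
        if calendar is not None:
            assert calendar.is_open(start), \
                f"unit {uid} granted at {start} outside its calendar"
    for uid, ivs in by_unit.items():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            assert s1 >= e0 - 1e-9, f"unit {uid} overlaps itself"
    # close-before-open at identical timestamps so back-to-back is fine
    events.sort(key=lambda t: (t[0], t[1]))
    level = 0
    for _t, d in events:
        level += d
        assert level <= capacity, "pool concurrency exceeds capacity"


def conservation_check(model):
    """Arrivals = completions + in-flight, per cohort."""
    in_flight_by_cohort: dict[str, int] = {}
    for eid in model.log.in_flight:
        cohort = eid.split("-")[0]
        in_flight_by_cohort[cohort] = in_flight_by_cohort.get(cohort, 0) + 1
    for cohort, n_arr in model.arrival_counts.items():
        n_done = model.completed_counts.get(cohort, 0)
        n_open = in_flight_by_cohort.get(cohort, 0)
        assert n_arr == n_done + n_open, (
            f"{cohort}: {n_arr} arrivals != {n_done} completed "
            f"+ {n_open} in flight")
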