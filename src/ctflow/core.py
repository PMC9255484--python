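"""Event-driven simulation kernel.

A minimal process-oriented discrete-event engine: a clock, a stable
priority event queue, resource pools with priority-then-FIFO queueing
discipline and per-unit availability calendars, and named seeded random
streams.  Time is in simulation minutes from 00:00 of day 0 (a Monday);
calendars use minutes-from-midnight with half-open ``[start, end)``
intervals.

Processes are Python generators that ``yield`` either a :class:`Timeout`
or the token returned by :meth:`ResourcePool.acquire`; the simulator
resumes them when the delay elapses or the units are granted.
"""

from __future__ import annotations

import heapq
import io
import zlib
from dataclasses import dataclass
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY


class SchedulingInPastError(ValueError):
    """Raised when an event is scheduled before the current clock."""


@dataclass(frozen=True)
class SimEvent:
    """One scheduled occurrence: a time, a tag, and an opaque payload."""

    time: float
    kind: str
    entity_id: Optional[str] = None
    payload: object = None


class EventQueue:
    """Stable time-ordered queue: ties dequeue FIFO by insertion order."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, SimEvent]] = []
        self._seq = 0

    def __len__(self) -> int:
        return len(self._heap)

    def schedule(self, event: SimEvent, clock: float = 0.0) -> None:
        if not np.isfinite(event.time):
            raise ValueError(f"event time must be finite, got {event.time!r}")
        if event.time < clock:
            raise SchedulingInPastError(
                f"cannot schedule {event.kind!r} at t={event.time} "
                f"before current clock t={clock}"
            )
        heapq.heappush(self._heap, (event.time, self._seq, event))
        self._seq += 1

    def next_event(self) -> SimEvent:
        return heapq.heappop(self._heap)[2]

    def peek_time(self) -> float:
        return self._heap[0][0]


class Calendar:
    """Weekly availability pattern of half-open open intervals.

    ``week`` maps weekday index (0 = Monday) to disjoint, sorted
    ``(start, end)`` intervals in minutes-from-midnight.  ``exceptions``
    maps an absolute day index to an interval list overriding the weekly
    pattern for that day.
    """

    def __init__(
        self,
        week: dict[int, list[tuple[float, float]]],
        exceptions: Optional[dict[int, list[tuple[float, float]]]] = None,
    ) -> None:
        self.week = {d: sorted(week.get(d, [])) for d in range(7)}
        self.exceptions = {k: sorted(v) for k, v in (exceptions or {}).items()}
        for d, ivs in list(self.week.items()) + list(self.exceptions.items()):
            last = -1.0
            for s, e in ivs:
                if not (0 <= s < e <= MINUTES_PER_DAY):
                    raise ValueError(f"bad interval ({s}, {e}) on day {d}")
                if s < last:
                    raise ValueError(f"overlapping intervals on day {d}")
                last = e

    @classmethod
    def always_open(cls) -> "Calendar":
        return cls({d: [(0.0, float(MINUTES_PER_DAY))] for d in range(7)})

    @classmethod
    def weekdays(cls, start: float, end: float,
                 days: Sequence[int] = (0, 1, 2, 3, 4)) -> "Calendar":
        return cls({d: [(start, end)] for d in days})

    def _day_intervals(self, day: int) -> list[tuple[float, float]]:
        if day in self.exceptions:
            return self.exceptions[day]
        return self.week[day % 7]

    def is_open(self, t: float) -> bool:
        day, m = int(t // MINUTES_PER_DAY), t % MINUTES_PER_DAY
        return any(s <= m < e for s, e in self._day_intervals(day))

    def next_open(self, t: float) -> Optional[float]:
        """Earliest time >= t at which the calendar is open (14-day lookahead)."""
        day = int(t // MINUTES_PER_DAY)
        for d in range(day, day + 15):
            m = t % MINUTES_PER_DAY if d == day else 0.0
            for s, e in self._day_intervals(d):
                if m < e:
                    return d * MINUTES_PER_DAY + max(s, m)
        return None

    def open_minutes(self, t0: float, t1: float) -> float:
        """Total open minutes in [t0, t1)."""
        total = 0.0
        for d in range(int(t0 // MINUTES_PER_DAY), int(np.ceil(t1 / MINUTES_PER_DAY))):
            base = d * MINUTES_PER_DAY
            for s, e in self._day_intervals(d):
                lo, hi = max(base + s, t0), min(base + e, t1)
                total += max(0.0, hi - lo)
        return total


class RandomStreams:
    """Named, independently seeded substreams off one master seed.

    The substream seed is derived from a stable hash of the name, so the
    same (master seed, name) pair yields the same stream in every run and
    across scenario configurations (common random numbers).
    """

    def __init__(self, master_seed: int) -> None:
        self.master_seed = int(master_seed)
        self._streams: dict[str, np.random.Generator] = {}

    def get(self, name: str) -> np.random.Generator:
        if name not in self._streams:
            key = zlib.crc32(name.encode("utf-8"))
            ss = np.random.SeedSequence([self.master_seed, key])
            self._streams[name] = np.random.Generator(np.random.PCG64(ss))
        return self._streams[name]


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

LOG_COLUMNS = ["entity_id", "cohort", "exam_class", "activity",
               "start_min", "end_min", "resources", "value_adding"]


@dataclass
class Record:
    entity_id: str
    cohort: str
    exam_class: str
    activity: str
    start_min: float
    end_min: float
    resources: tuple[str, ...] = ()
    value_adding: bool = False


class EventLog:
    """Ordered activity records from which every metric is computed."""

    def __init__(self, horizon_min: float = 0.0) -> None:
        self.records: list[Record] = []
        self.horizon_min = horizon_min
        self.in_flight: set[str] = set()

    def append(self, rec: Record) -> None:
        if rec.end_min < rec.start_min:
            raise ValueError(f"record {rec.activity} ends before it starts")
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.entity_id, r.cohort, r.exam_class, r.activity,
              r.start_min, r.end_min, ";".join(r.resources), int(r.value_adding))
             for r in self.records],
            columns=LOG_COLUMNS,
        )

    def to_csv(self, path_or_buf=None):
        df = self.to_dataframe()
        if path_or_buf is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format="%.6f")
            return buf.getvalue()
        df.to_csv(path_or_buf, index=False, float_format="%.6f")
        return None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, horizon_min: float = 0.0) -> "EventLog":
        log = cls(horizon_min)
        for row in df.itertuples(index=False):
            res = tuple(str(row.resources).split(";")) if isinstance(row.resources, str) and row.resources else ()
            log.append(Record(str(row.entity_id), row.cohort, row.exam_class,
                              row.activity, float(row.start_min), float(row.end_min),
                              res, bool(row.value_adding)))
        return log

    @classmethod
    def from_csv(cls, path, horizon_min: float = 0.0) -> "EventLog":
        df = pd.read_csv(path, keep_default_na=False,
                         dtype={"resources": str, "entity_id": str})
        return cls.from_dataframe(df, horizon_min)


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------

@dataclass
class Unit:
    uid: str
    calendar: Calendar
    tags: frozenset = frozenset()
    busy: bool = False
    _grant_time: float = 0.0
    _grant_entity: str = ""
    _grant_label: str = ""


@dataclass
class _Claim:
    priority: int
    seq: int
    entity_id: str
    n_units: int
    require_tag: Optional[str]
    continuation: Callable[[list[Unit]], None]
    time_requested: float
    label: str = ""
    cancelled: bool = False

    def sort_key(self) -> tuple[int, int]:
        return (self.priority, self.seq)


class CapacityError(ValueError):
    """A request asks for more units than the pool owns."""


class ResourcePool:
    """Units with calendars, granted priority-then-FIFO.

    Lower ``priority`` numbers are more urgent.  Among equal priorities
    claims are served in request order.  An in-queue claim's priority may
    be updated in place without losing queue membership.  Grants occur
    only at instants when the unit's calendar is open; an in-progress
    hold is never preempted (it may run past a calendar close).
    """

    def __init__(self, sim: "Simulator", name: str, units: Sequence[Unit]) -> None:
        self.sim = sim
        self.name = name
        self.units = list(units)
        self.claims: list[_Claim] = []
        self._claim_seq = 0
        self.busy_log: list[tuple[str, float, float, str, str]] = []
        self._wake_scheduled_at: Optional[float] = None

    @property
    def capacity(self) -> int:
        return len(self.units)

    # -- claim management ---------------------------------------------------

    def acquire(self, entity_id: str, priority: int = 0, n_units: int = 1,
                require_tag: Optional[str] = None, label: str = "") -> "_AcquireToken":
        if n_units > self.capacity:
            raise CapacityError(
                f"pool {self.name!r}: requested {n_units} units, capacity {self.capacity}")
        eligible = [u for u in self.units
                    if require_tag is None or require_tag in u.tags]
        if n_units > len(eligible):
            raise CapacityError(
                f"pool {self.name!r}: no {n_units} units with tag {require_tag!r}")
        return _AcquireToken(self, entity_id, priority, n_units, require_tag, label)

    def _enqueue(self, claim: _Claim) -> None:
        self.claims.append(claim)
        self.try_grant()

    def update_priority(self, entity_id: str, new_priority: int) -> None:
        """Re-prioritize waiting claims of an entity in place."""
        changed = False
        for c in self.claims:
            if c.entity_id == entity_id and not c.cancelled:
                c.priority = new_priority
                changed = True
        if changed:
            self.try_grant()

    def release(self, units: Sequence[Unit]) -> None:
        now = self.sim.now
        for u in units:
            if not u.busy:
                raise RuntimeError(f"double release of unit {u.uid}")
            u.busy = False
            self.busy_log.append((u.uid, u._grant_time, now,
                                  u._grant_entity, u._grant_label))
        self.try_grant()

    # -- granting -----------------------------------------------------------

    def _available(self, require_tag: Optional[str]) -> list[Unit]:
        now = self.sim.now
        return [u for u in self.units
                if not u.busy and u.calendar.is_open(now)
                and (require_tag is None or require_tag in u.tags)]

    def try_grant(self) -> None:
        now = self.sim.now
        while True:
            live = [c for c in self.claims if not c.cancelled]
            if not live:
                self.claims = []
                return
            best = min(live, key=_Claim.sort_key)
            avail = self._available(best.require_tag)
            if len(avail) < best.n_units:
                self._schedule_wake(best)
                return
            grant = avail[:best.n_units]
            for u in grant:
                u.busy = True
                u._grant_time = now
                u._grant_entity = best.entity_id
                u._grant_label = best.label
            self.claims.remove(best)
            best.continuation(grant)

    def _schedule_wake(self, claim: _Claim) -> None:
        """Wake when a closed-but-free unit's calendar next opens."""
        now = self.sim.now
        cands = []
        for u in self.units:
            if u.busy:
                continue
            if claim.require_tag is not None and claim.require_tag not in u.tags:
                continue
            t = u.calendar.next_open(now)
            if t is not None and t > now:
                cands.append(t)
        if not cands:
            return
        t = min(cands)
        if self._wake_scheduled_at is not None and self._wake_scheduled_at <= t:
            return
        self._wake_scheduled_at = t
        self.sim.schedule(t, "pool_wake", payload=self._on_wake)

    def _on_wake(self, _evt: SimEvent) -> None:
        self._wake_scheduled_at = None
        self.try_grant()


@dataclass
class Timeout:
    delay: float


class _AcquireToken:
    def __init__(self, pool: ResourcePool, entity_id: str, priority: int,
                 n_units: int, require_tag: Optional[str], label: str) -> None:
        self.pool = pool
        self.entity_id = entity_id
        self.priority = priority
        self.n_units = n_units
        self.require_tag = require_tag
        self.label = label


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

class Simulator:
    """Clock + event loop driving generator processes."""

    def __init__(self) -> None:
        self.now = 0.0
        self.queue = EventQueue()
        self._live_processes = 0

    def schedule(self, time: float, kind: str, entity_id: Optional[str] = None,
                 payload: object = None) -> None:
        self.queue.schedule(SimEvent(time, kind, entity_id, payload), clock=self.now)

    def process(self, gen: Iterator, entity_id: Optional[str] = None) -> None:
        """Register a generator process; it starts at the current clock."""
        self._live_processes += 1
        self.schedule(self.now, "process_start", entity_id,
                      payload=lambda evt: self._step(gen, None))

    def _step(self, gen: Iterator, send_value) -> None:
        try:
            cmd = gen.send(send_value)
        except StopIteration:
            self._live_processes -= 1
            return
        if isinstance(cmd, Timeout):
            if cmd.delay < 0:
                raise ValueError(f"negative timeout {cmd.delay}")
            self.schedule(self.now + cmd.delay, "timeout",
                          payload=lambda evt: self._step(gen, None))
        elif isinstance(cmd, _AcquireToken):
            claim = _Claim(cmd.priority, cmd.pool._claim_seq, cmd.entity_id,
                           cmd.n_units, cmd.require_tag,
                           lambda units: self._step(gen, units), self.now,
                           label=cmd.label)
            cmd.pool._claim_seq += 1
            cmd.pool._enqueue(claim)
        else:
            raise TypeError(f"process yielded unsupported command {cmd!r}")

    def run_until(self, t_end: float) -> None:
        if not np.isfinite(t_end):
            raise ValueError(f"t_end must be finite, got {t_end!r}")
        while len(self.queue) and self.queue.peek_time() <= t_end:
            evt = self.queue.next_event()
            self.now = evt.time
            if callable(evt.payload):
                evt.payload(evt)
        self.now = max(self.now, t_end)


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

def sample_duration(rng: np.random.Generator, mean: float, cv: float = 0.0,
                    dist: str = "lognormal") -> float:
    """Sample a non-negative task duration with the given mean.

    ``lognormal`` is parameterized by (mean, coefficient of variation) so
    the sample mean is exact; ``cv == 0`` or ``dist == 'fixed'`` degenerates
    to the mean; ``exponential`` ignores ``cv``.
    """
    if mean < 0:
        raise ValueError(f"negative mean duration {mean}")
    if mean == 0 or cv == 0 or dist == "fixed":
        return float(mean)
    if dist == "lognormal":
        sigma2 = np.log1p(cv * cv)
        mu = np.log(mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    if dist == "exponential":
        return float(rng.exponential(mean))
    raise ValueError(f"unknown distribution {dist!r}")
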