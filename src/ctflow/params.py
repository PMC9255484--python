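"""Model configuration: validated parameter sets, read and written as YAML.

A :class:`ParameterSet` holds everything the simulator needs — cohort
mixes, task-duration distributions, staffing and shift calendars,
arrival profiles, infection-control durations and the waiting-list
regime.  Proportions are validated to sum to one (tolerance 1e-9) and
all rates and durations to be non-negative, with precise error messages
on load.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

SCHEDULED_COHORTS = ("OP", "GP")
UNSCHEDULED_COHORTS = ("IP", "ED")
COHORTS = SCHEDULED_COHORTS + UNSCHEDULED_COHORTS

EXAM_CLASSES = ("non_contrast", "iv_contrast", "oral_and_iv")
MOBILITIES = ("walking", "wheelchair", "bed")

#: Exam-class groups used for workload reporting.
NON_CONTRAST_GROUP = ("non_contrast",)
IV_GROUP = ("iv_contrast", "oral_and_iv")

WEEKDAYS_PER_365 = 261  # day 0 is a Monday


def _check_mix(mix: dict, keys: tuple, what: str) -> dict:
    if set(mix) != set(keys):
        raise ValueError(f"{what}: expected keys {sorted(keys)}, got {sorted(mix)}")
    for k, v in mix.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{what}[{k}] = {v} is not a proportion in [0, 1]")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} sums to {total!r}, expected 1.0")
    return mix


class Dist(BaseModel):
    """A named duration distribution in minutes: (mean, cv) parameterized."""

    model_config = ConfigDict(extra="forbid")
    mean: float = Field(ge=0)
    cv: float = Field(default=0.25, ge=0)
    dist: str = "lognormal"

    @field_validator("dist")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in ("lognormal", "fixed", "exponential"):
            raise ValueError(f"unknown distribution family {v!r}")
        return v


class CohortSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    exam_class_mix: dict[str, float]
    mobility_mix: dict[str, float]
    p_infectious: float = Field(ge=0, le=1)
    urgency: int = 2

    @field_validator("exam_class_mix")
    @classmethod
    def _ecm(cls, v):
        return _check_mix(v, EXAM_CLASSES, "exam_class_mix")

    @field_validator("mobility_mix")
    @classmethod
    def _mm(cls, v):
        return _check_mix(v, MOBILITIES, "mobility_mix")


class ScheduledArrivals(BaseModel):
    """Bookable slot template for OP/GP work, weekday service only."""

    model_config = ConfigDict(extra="forbid")
    slot_times: list[float] = Field(default_factory=list)
    weekdays: list[int] = Field(default_factory=lambda: [0, 1, 2, 3, 4])
    no_show_prob: float = Field(default=0.0, ge=0, le=1)
    cohort_mix: dict[str, float] = Field(
        default_factory=lambda: {"OP": 0.75, "GP": 0.25})

    @field_validator("cohort_mix")
    @classmethod
    def _cm(cls, v):
        return _check_mix(v, SCHEDULED_COHORTS, "scheduled cohort_mix")

    @field_validator("slot_times")
    @classmethod
    def _slots(cls, v):
        if any(not (0 <= s < 1440) for s in v):
            raise ValueError("slot_times must be minutes-from-midnight in [0, 1440)")
        return sorted(v)

    @field_validator("weekdays")
    @classmethod
    def _wd(cls, v):
        if any(d not in range(7) for d in v):
            raise ValueError("weekdays must be in 0..6 (0 = Monday)")
        return sorted(set(v))


class UnscheduledArrivals(BaseModel):
    """24/7 IP/ED demand as a nonhomogeneous Poisson process."""

    model_config = ConfigDict(extra="forbid")
    hourly_weights: list[float]
    cohort_mix: dict[str, float] = Field(
        default_factory=lambda: {"IP": 0.75, "ED": 0.25})
    rate_multiplier: float = Field(default=1.0, ge=0)

    @field_validator("hourly_weights")
    @classmethod
    def _hw(cls, v):
        if len(v) != 24:
            raise ValueError(f"hourly_weights needs 24 entries, got {len(v)}")
        if any(w < 0 for w in v):
            raise ValueError("hourly_weights must be non-negative")
        if sum(v) <= 0:
            raise ValueError("hourly_weights must not all be zero")
        return v

    @field_validator("cohort_mix")
    @classmethod
    def _cm(cls, v):
        return _check_mix(v, UNSCHEDULED_COHORTS, "unscheduled cohort_mix")


class Staffing(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radiographers_day: int = Field(default=2, ge=1)
    hcas_day: int = Field(default=1, ge=0)
    porters: int = Field(default=1, ge=1)
    on_call_radiographers: int = Field(default=1, ge=0)
    on_call_hcas: int = Field(default=1, ge=0)
    p_cannulate: float = Field(default=0.5, ge=0, le=1)
    day_shift_start: float = Field(default=510.0, ge=0, lt=1440)   # 08:30
    day_shift_end: float = Field(default=1020.0, gt=0, le=1440)    # 17:00

    @model_validator(mode="after")
    def _shift(self):
        if self.day_shift_end <= self.day_shift_start:
            raise ValueError("day_shift_end must be after day_shift_start")
        return self


class WaitlistConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weekly_referrals: float = Field(default=70.0, ge=0)
    initial_backlog: float = Field(default=120.0, ge=0)
    weekly_capacity: Optional[float] = Field(default=None, ge=0)


class ParameterSet(BaseModel):
    """The full model configuration.

    ``tasks`` maps task names to duration distributions; the scan-table
    occupancy is keyed per cohort group × exam-class group because the
    workload profile of bed-bound, often infectious unscheduled patients
    differs from ambulant scheduled ones.
    """

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    schema_version: int = Field(default=1, alias="schema")
    seed: int = 0
    annual_exam_total: float = Field(default=5958.0, gt=0)
    scheduled: ScheduledArrivals
    unscheduled: UnscheduledArrivals
    cohorts: dict[str, CohortSpec]
    staffing: Staffing = Field(default_factory=Staffing)
    tasks: dict[str, Dist]
    scanners: int = Field(default=1, ge=1)
    decon_minutes: float = Field(default=60.0, ge=0, le=60)
    standard_clean_minutes: float = Field(default=5.0, ge=0)
    p_ward_not_ready: float = Field(default=0.4, ge=0, le=1)
    ward_not_ready_delay: Dist = Field(default_factory=lambda: Dist(mean=15.0))
    oral_drink_minutes: float = Field(default=30.0, ge=0)
    protect_lunch: bool = False
    lunch_start: float = Field(default=780.0)   # 13:00
    lunch_end: float = Field(default=840.0)     # 14:00
    csm_include_porter: bool = False
    csm_include_decon: bool = False
    waitlist: WaitlistConfig = Field(default_factory=WaitlistConfig)

    @field_validator("cohorts")
    @classmethod
    def _cohorts(cls, v):
        missing = set(COHORTS) - set(v)
        if missing:
            raise ValueError(f"cohorts missing entries for {sorted(missing)}")
        return v

    @model_validator(mode="after")
    def _tasks_present(self):
        missing = set(REQUIRED_TASKS) - set(self.tasks)
        if missing:
            raise ValueError(f"tasks missing entries for {sorted(missing)}")
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def scheduled_exams_per_year(self) -> float:
        per_week = len(self.scheduled.slot_times) * len(self.scheduled.weekdays)
        expected = per_week / 7.0 * 365.0
        return expected * (1.0 - self.scheduled.no_show_prob)

    @property
    def unscheduled_daily_rate(self) -> float:
        """Mean IP/ED arrivals per day so annual volumes hit the target."""
        base = max(0.0, self.annual_exam_total - self.scheduled_exams_per_year) / 365.0
        return base * self.unscheduled.rate_multiplier

    def scan_task(self, cohort: str, exam_class: str) -> str:
        group = "scheduled" if cohort in SCHEDULED_COHORTS else "unscheduled"
        cls = "non_contrast" if exam_class == "non_contrast" else "iv"
        return f"scan_{group}_{cls}"

    # -- IO -----------------------------------------------------------------

    def to_dict(self) -> dict:
        return self.model_dump(by_alias=True)

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls.model_validate(d)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, overrides: dict) -> "ParameterSet":
        """Deep-merged copy; override keys follow the YAML schema."""
        d = self.to_dict()
        _deep_merge(d, overrides)
        return ParameterSet.from_dict(d)


REQUIRED_TASKS = (
    "prep",
    "oral_supervision",
    "cannulation",
    "injector_setup",
    "schedule_step",
    "manual_handling_wheelchair",
    "manual_handling_bed",
    "scan_scheduled_non_contrast",
    "scan_scheduled_iv",
    "scan_unscheduled_non_contrast",
    "scan_unscheduled_iv",
    "cannula_removal",
    "observation",
    "transport_leg",
    "transport_coordination",
    "post_processing",
    "paperwork",
)

N_SCHEDULE_STEPS = 6  # same-day booking micro-steps for unscheduled cases


def _deep_merge(base: dict, override: dict) -> None:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_merge(base[k], v)
        else:
            base[k] = v


def default_parameters() -> "ParameterSet":
    """The repository's calibrated default configuration.

    Loaded from the packaged ``params_default.yaml``, which is the output
    of :func:`ctflow.calibration.calibrate_defaults`.
    """
    from importlib.resources import files

    text = files("ctflow").joinpath("params_default.yaml").read_text()
    return ParameterSet.from_dict(yaml.safe_load(text))
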