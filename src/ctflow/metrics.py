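"""Workload and process metrics computed from an event log.

Everything here is derived from the serialized activity records alone:
consumed staff minutes (CSM), perturbation delays, staff utilization,
percentage of time scanning, throughput and the value / non-value
decomposition of patient time in the system.

Definitions
-----------
CSM
    Staff-minutes a patient consumes across preparation (including the
    same-day booking micro-steps, cannulation and oral-prep
    supervision), scanning, manual handling and observation: the task
    duration times the number of staff engaged.  Porter minutes and
    scanner decontamination downtime are excluded by default (both
    configurable).
Perturbation
    Delay to the process attributable to a patient's type: porter
    waits, ward-not-ready delays, waits for manual-handling helpers
    once the scanner is available, and the successor's scanner wait
    induced by this patient's decontamination hold (charged to the
    *causing* patient).
Utilization
    Busy minutes on modeled physical tasks over rostered minutes,
    averaged over the day staff of a role.  Cognitive booking time is
    excluded from the numerator but appears in the task breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Calendar, EventLog
from .department import SCHEDULE_STEP_ACTIVITIES
from .params import (
    IV_GROUP,
    NON_CONTRAST_GROUP,
    ParameterSet,
    SCHEDULED_COHORTS,
    UNSCHEDULED_COHORTS,
)

CSM_ACTIVITIES = frozenset(
    {"prep", "oral_supervision", "cannulation", "scan",
     "manual_handling_on", "manual_handling_off", "observation"}
    | SCHEDULE_STEP_ACTIVITIES)

#: Perturbation wait components read directly from the log.
PERTURBATION_WAITS = frozenset({"wait_porter", "ward_not_ready", "wait_helper"})

GROUPS = {"scheduled": SCHEDULED_COHORTS, "unscheduled": UNSCHEDULED_COHORTS}
CLASS_GROUPS = {"non_contrast": NON_CONTRAST_GROUP, "iv": IV_GROUP}


class UnknownEntityError(KeyError):
    pass


def _frame(log) -> pd.DataFrame:
    df = log.to_dataframe() if isinstance(log, EventLog) else log.copy()
    df["dur"] = df["end_min"] - df["start_min"]
    res = df["resources"].fillna("").astype(str)
    df["n_rad"] = res.str.count("rad-")
    df["n_hca"] = res.str.count("hca-")
    df["n_porter"] = res.str.count("porter-")
    df["n_staff"] = df["n_rad"] + df["n_hca"]
    return df


def completed_entities(df: pd.DataFrame) -> pd.Index:
    """Entities whose pathway finished (clerical wrap-up present)."""
    return pd.Index(df.loc[df["activity"] == "paperwork", "entity_id"].unique())


# ---------------------------------------------------------------------------
# Per-entity metrics
# ---------------------------------------------------------------------------

def consumed_staff_minutes(log, entity_id: str,
                           include_porter: bool = False,
                           include_decon: bool = False) -> float:
    df = _frame(log)
    sub = df[df["entity_id"] == entity_id]
    if sub.empty:
        raise UnknownEntityError(entity_id)
    return float(_csm_series(sub, include_porter, include_decon).get(entity_id, 0.0))


def _csm_series(df: pd.DataFrame, include_porter: bool = False,
                include_decon: bool = False) -> pd.Series:
    """CSM per entity over all entities present in the frame."""
    m = df["activity"].isin(CSM_ACTIVITIES)
    staff = df["n_staff"] + (df["n_porter"] if include_porter else 0)
    contrib = (df["dur"] * staff).where(m, 0.0)
    if include_decon:
        contrib = contrib + df["dur"].where(df["activity"] == "decontamination", 0.0)
    out = contrib.groupby(df["entity_id"]).sum()
    return out


def _decon_charges(df: pd.DataFrame) -> pd.Series:
    """Scanner-wait minutes induced by each decontamination hold,
    charged to the infectious patient who caused it.

    For each hold, the successor is the waiting patient first granted
    the scanner after the hold ends (the overlapping scanner-wait record
    with the earliest end); the charge is the overlap of that wait with
    the hold interval.
    """
    charges: dict[str, float] = {}
    decons = df[df["activity"] == "decontamination"]
    waits = df[df["activity"] == "wait_scanner"]
    if decons.empty or waits.empty:
        return pd.Series(charges, dtype=float)
    w_start = waits["start_min"].to_numpy()
    w_end = waits["end_min"].to_numpy()
    w_ent = waits["entity_id"].to_numpy()
    for row in decons.itertuples(index=False):
        ov = np.minimum(w_end, row.end_min) - np.maximum(w_start, row.start_min)
        mask = (ov > 1e-9) & (w_ent != row.entity_id)
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        successor = idx[np.argmin(w_end[idx])]
        charges[row.entity_id] = charges.get(row.entity_id, 0.0) \
            + float(ov[successor])
    return pd.Series(charges, dtype=float)


def perturbation(log, entity_id: str) -> float:
    df = _frame(log)
    if not (df["entity_id"] == entity_id).any():
        raise UnknownEntityError(entity_id)
    return float(_perturbation_series(df).get(entity_id, 0.0))


def _perturbation_series(df: pd.DataFrame) -> pd.Series:
    waits = df[df["activity"].isin(PERTURBATION_WAITS)]
    per = waits.groupby("entity_id")["dur"].sum()
    charges = _decon_charges(df)
    return per.add(charges, fill_value=0.0)


def time_in_system(log, entity_id: str) -> tuple[float, float, float]:
    """(total, value-adding, non-value) minutes from arrival in
    radiology to scan finish."""
    df = _frame(log)
    sub = df[df["entity_id"] == entity_id]
    if sub.empty:
        raise UnknownEntityError(entity_id)
    arr = sub.loc[sub["activity"] == "radiology_arrival", "start_min"]
    scan = sub.loc[sub["activity"] == "scan", "end_min"]
    if arr.empty or scan.empty:
        raise UnknownEntityError(f"{entity_id}: not scanned within the horizon")
    t0, t1 = float(arr.iloc[0]), float(scan.iloc[0])
    total = t1 - t0
    inwin = sub[(sub["value_adding"] == 1)
                & (sub["start_min"] >= t0 - 1e-9) & (sub["end_min"] <= t1 + 1e-9)]
    value = float(inwin["dur"].sum())
    return total, value, total - value


def arrival_to_scan_durations(log) -> pd.Series:
    """Per-entity arrival-to-scan-finish durations for completed scans."""
    df = _frame(log)
    arr = df[df["activity"] == "radiology_arrival"].set_index("entity_id")["start_min"]
    scan = df[df["activity"] == "scan"].set_index("entity_id")["end_min"]
    common = arr.index.intersection(scan.index)
    return (scan.loc[common] - arr.loc[common]).astype(float)


# ---------------------------------------------------------------------------
# Role utilization
# ---------------------------------------------------------------------------

def day_units(params: ParameterSet, role: str) -> list[str]:
    st = params.staffing
    if role == "radiographer":
        return [f"rad-{i + 1}" for i in range(st.radiographers_day)]
    if role == "hca":
        return [f"hca-{i + 1}" for i in range(st.hcas_day)]
    raise ValueError(f"unknown staff role {role!r}")


def rostered_minutes(params: ParameterSet, horizon_min: float) -> float:
    """Rostered minutes per day-shift staff member over the horizon."""
    st = params.staffing
    if params.protect_lunch:
        cal = Calendar({d: [(st.day_shift_start, params.lunch_start),
                            (params.lunch_end, st.day_shift_end)]
                        for d in range(5)})
    else:
        cal = Calendar.weekdays(st.day_shift_start, st.day_shift_end)
    return cal.open_minutes(0.0, horizon_min)


def _busy_minutes_by_unit(df: pd.DataFrame, units: list[str],
                          physical_only: bool = True) -> dict[str, float]:
    busy = {u: 0.0 for u in units}
    work = df[~df["activity"].str.startswith("wait")]
    if physical_only:
        work = work[~work["activity"].isin(SCHEDULE_STEP_ACTIVITIES)]
    res = work["resources"].astype(str)
    for u in units:
        m = res.str.contains(u, regex=False)
        busy[u] = float(work.loc[m, "dur"].sum())
    return busy


def utilization(log, role: str, params: ParameterSet,
                horizon_min: float) -> float:
    """Percent busy on physical tasks, averaged over day staff of the role."""
    units = day_units(params, role)
    roster = rostered_minutes(params, horizon_min)
    if roster <= 0 or not units:
        raise ValueError(f"zero rostered minutes for role {role!r}")
    df = _frame(log)
    busy = _busy_minutes_by_unit(df, units)
    return float(100.0 * np.mean([busy[u] / roster for u in units]))


def task_breakdown(log, role: str, params: ParameterSet) -> pd.Series:
    """Minutes per activity performed by the role's day staff, including
    cognitive booking work."""
    units = day_units(params, role)
    df = _frame(log)
    work = df[~df["activity"].str.startswith("wait")]
    res = work["resources"].astype(str)
    mask = pd.Series(False, index=work.index)
    for u in units:
        mask |= res.str.contains(u, regex=False)
    return work.loc[mask].groupby("activity")["dur"].sum().sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Grouped report
# ---------------------------------------------------------------------------

def pct_time_scanning(log, cohort_group: str, exam_class_group: str) -> float:
    """100 x mean scan duration / mean CSM for the completed entities of
    a cohort group ('scheduled'/'unscheduled') x exam-class group
    ('non_contrast'/'iv')."""
    df = _frame(log)
    cell = _cell_frame(df, cohort_group, exam_class_group)
    if cell is None:
        raise ValueError(f"no completed entities in "
                         f"{cohort_group}/{exam_class_group}")
    scan_mean, csm_mean = cell
    return float(100.0 * scan_mean / csm_mean)


def _cell_frame(df: pd.DataFrame, cohort_group: str, exam_class_group: str):
    cohorts = GROUPS[cohort_group]
    classes = CLASS_GROUPS[exam_class_group]
    done = completed_entities(df)
    sub = df[df["cohort"].isin(cohorts) & df["exam_class"].isin(classes)
             & df["entity_id"].isin(done)]
    if sub.empty:
        return None
    csm = _csm_series(sub)
    scan = sub[sub["activity"] == "scan"].groupby("entity_id")["dur"].sum()
    if csm.empty or scan.empty:
        return None
    return float(scan.mean()), float(csm.mean())


@dataclass
class MetricsReport:
    """Replication-level metric block in the layout of the workload table."""

    horizon_min: float
    completed: int
    csm: dict = field(default_factory=dict)           # (group, class) -> mean min
    perturbation: dict = field(default_factory=dict)  # group -> mean min
    pct_scanning: dict = field(default_factory=dict)  # (group, class) -> %
    utilization: dict = field(default_factory=dict)   # role -> %
    csm_by_cohort: dict = field(default_factory=dict)
    breakdown: dict = field(default_factory=dict)     # role -> {activity: min}
    mean_time_in_system: float = float("nan")
    value_adding_share: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "horizon_min": self.horizon_min,
            "completed": self.completed,
            "csm": {f"{g}/{c}": v for (g, c), v in self.csm.items()},
            "perturbation": dict(self.perturbation),
            "pct_scanning": {f"{g}/{c}": v for (g, c), v in self.pct_scanning.items()},
            "utilization": dict(self.utilization),
            "csm_by_cohort": dict(self.csm_by_cohort),
            "breakdown": {r: dict(b) for r, b in self.breakdown.items()},
            "mean_time_in_system": self.mean_time_in_system,
            "value_adding_share": self.value_adding_share,
        }

    def table(self) -> pd.DataFrame:
        """Workload-table mirror: rows metrics, columns cohort groups."""
        rows = {
            "mean_perturbation_min": {g: self.perturbation.get(g)
                                      for g in GROUPS},
            "csm_iv_min": {g: self.csm.get((g, "iv")) for g in GROUPS},
            "csm_non_contrast_min": {g: self.csm.get((g, "non_contrast"))
                                     for g in GROUPS},
            "pct_time_scanning_non_contrast": {
                g: self.pct_scanning.get((g, "non_contrast")) for g in GROUPS},
        }
        return pd.DataFrame(rows).T[["unscheduled", "scheduled"]]


def compute_report(log, params: ParameterSet,
                   horizon_min: float | None = None) -> MetricsReport:
    df = _frame(log)
    horizon = horizon_min if horizon_min is not None else getattr(
        log, "horizon_min", 0.0)
    if not horizon:  # e.g. a log deserialized from CSV
        horizon = float(np.ceil(df["end_min"].max() / 1440.0)) * 1440.0
    done = completed_entities(df)
    dfc = df[df["entity_id"].isin(done)]
    rep = MetricsReport(horizon_min=horizon, completed=len(done))

    csm = _csm_series(dfc, params.csm_include_porter, params.csm_include_decon)
    pert = _perturbation_series(df).reindex(done, fill_value=0.0)
    ent_meta = dfc.groupby("entity_id")[["cohort", "exam_class"]].first()

    for g, cohorts in GROUPS.items():
        in_g = ent_meta.index[ent_meta["cohort"].isin(cohorts)]
        if len(in_g):
            rep.perturbation[g] = float(pert.reindex(in_g, fill_value=0.0).mean())
        for c, classes in CLASS_GROUPS.items():
            in_cell = ent_meta.index[ent_meta["cohort"].isin(cohorts)
                                     & ent_meta["exam_class"].isin(classes)]
            if len(in_cell):
                rep.csm[(g, c)] = float(csm.reindex(in_cell, fill_value=0.0).mean())
                cell = _cell_frame(df, g, c)
                if cell:
                    rep.pct_scanning[(g, c)] = float(100.0 * cell[0] / cell[1])

    for cohort in ent_meta["cohort"].unique():
        in_c = ent_meta.index[ent_meta["cohort"] == cohort]
        rep.csm_by_cohort[cohort] = float(csm.reindex(in_c, fill_value=0.0).mean())

    for role in ("radiographer", "hca"):
        if day_units(params, role):
            rep.utilization[role] = utilization(df, role, params, horizon)
            rep.breakdown[role] = task_breakdown(df, role, params).to_dict()

    tis = arrival_to_scan_durations(dfc)
    if len(tis):
        rep.mean_time_in_system = float(tis.mean())
        value = dfc[(dfc["value_adding"] == 1)]["dur"].sum()
        allmin = dfc[~dfc["activity"].str.startswith("wait")]["dur"].sum()
        rep.value_adding_share = float(100.0 * value / allmin) if allmin else np.nan
    return rep
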