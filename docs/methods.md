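# Methods

## The model

`ctflow` is a discrete-event simulation of a small hospital radiology
department operating a single CT scanner.  Demand is of two kinds:

* **Scheduled** work — outpatients (OP) and GP referrals — booked in
  advance into a weekday slot template between 08:30 and 17:00 with a
  one-hour lunch closure (no slots 13:00–14:00).
* **Unscheduled** work — inpatients (IP) and emergency-department (ED)
  patients — requested around the clock and scheduled on the day of
  scanning.

Each examination request carries four attributes drawn from
cohort-specific mixes: exam class (non-contrast, IV contrast, oral+IV),
mobility (walking, wheelchair, bed), an infectious flag, and an urgency
used for scanner queue ordering (ED before IP before scheduled).
Unscheduled patients are less mobile and more often infectious than
scheduled ones.

A request's **pathway** is a deterministic, total function of its
attributes:

1. six same-day booking micro-steps (unscheduled only), occupying a
   radiographer — verify the request and its justification, safety
   questions, infection-status confirmation, arranging ward
   preparation, arranging transport, allocating and communicating a
   slot; these labels are an interpretation of the workflow-mapping
   narrative, since only their count is documented;
2. oral contrast drink on the ward (oral+IV, unscheduled) — a pure
   delay;
3. porter transport to the department (unscheduled), preceded by a
   possible *ward-not-ready* delay with probability
   `p_ward_not_ready`;
4. preparation by a healthcare assistant (HCA), oral-prep supervision,
   cannulation (IV exams; requires a radiographer with the cannulation
   skill) and injector set-up;
5. the scanner block: queue for the scanner by urgency, assemble the
   transfer staff, manual handling onto the table (wheelchair: the
   attending radiographer; bed: radiographer + one HCA, who leaves
   during the scan and is recalled for the off-transfer), the scan,
   manual handling off;
6. infection control: a 60-minute decontamination hold of the scanner
   (passive air exchange, no staff) after infectious patients, a
   5-minute radiographer standard clean otherwise;
7. cannula removal and a post-contrast observation period (IV exams),
   transport coordination and porter transport back (unscheduled),
   image post-processing and paperwork.

The engine is a minimal process-oriented kernel: a stable time-ordered
event queue (FIFO within simultaneous events), resource pools with
priority-then-FIFO discipline and per-unit availability calendars, and
named random substreams hashed off one master seed so that identical
(seed, configuration) pairs give bit-identical event logs and scenario
comparisons can share common random numbers.  The scanner is
non-preemptive: urgency reorders the queue but never interrupts a scan.

Day staff (default two radiographers, one of whom cannulates, and one
HCA) work Monday–Friday 08:30–17:00; a small on-call complement (one
radiographer, one HCA) whose calendar is the complement of the day
shift covers the 24/7 emergency service, and one porter is available
around the clock.  Lunch closure applies to the booking template, not
to staff availability (staggered lunches are abstracted away); a
`protect_lunch` flag instead removes the lunch hour from day-staff
calendars for sensitivity analyses.

## Metrics

All metrics are computed from the serialized event log.

* **Consumed staff minutes (CSM)** — per patient, the sum over
  preparation (booking micro-steps, prep, oral supervision,
  cannulation), scanning, manual handling and observation of task
  duration × staff engaged.  Porter minutes and decontamination
  downtime are excluded by default (both configurable).
* **Perturbation** — delay attributable to the patient's type: porter
  waits, ward-not-ready delays, waits for manual-handling helpers at
  an available scanner, plus the successor's scanner wait induced by
  the patient's decontamination hold.  The decontamination charge goes
  to the *causing* patient (the first patient granted the scanner
  after the hold is identified and the overlap of their wait with the
  hold is charged back); infectious patients therefore carry their
  induced cost.  Routine 5-minute cleans are not charged.
* **Utilization** — busy minutes on physical tasks over rostered
  minutes, averaged across the day staff of a role.  Cognitive booking
  time is excluded from the numerator (it appears in the task
  breakdown); the on-call complement is outside the average.
* **% time scanning** — 100 × mean scan duration / mean CSM within a
  reporting cell.
* **Time in system** — arrival in radiology (slot time for scheduled
  patients, end of inbound transport for unscheduled) to scan finish,
  partitioned exactly into value-adding task time and non-value time
  (waits, holds).

Reporting cells group OP+GP ("scheduled") vs IP+ED ("unscheduled") and
non-contrast vs IV-involving exams; per-cohort tables are also
emitted.  Replication summaries report per-replication means averaged
across replications with 95% t confidence intervals.

## Calibration

Task times were not published, so the defaults are reconstructed by
expected-value matching (`ctflow.calibration`):

* The % -time-scanning definition forces the scan-table occupancy per
  cell: scan = pct/100 × CSM (3.835 min scheduled, 6.420 min
  unscheduled, non-contrast).  The two published percentages are
  incompatible with a single cross-cohort scan time, so scan
  durations are per cohort group × exam class; the longer unscheduled
  occupancy reflects positioning and supervision of less mobile
  patients.
* Scheduled non-contrast CSM then pins the preparation time, and
  unscheduled non-contrast CSM pins the total booking micro-step time,
  given fixed conventions for handling (wheelchair 2 min × 1 staff,
  bed 3 min × 2 staff, two transfers), cannulation (5 min),
  observation (15 min) and oral supervision (2 min).
* The IV-involving CSM targets pin the IV scan occupancies.
* The utilization targets pin the per-exam clerical overhead
  (post-processing + paperwork, radiographer) and the per-patient
  transport-coordination time (HCA) through a closed-form utilization
  expression, inflated by a frozen shift-boundary factor (≈5%)
  measured once by simulation: pathways that straddle 17:00 hand work
  to the on-call complement, which the closed form cannot see.
* Contention-driven behavior cannot be solved in closed form.  A
  seeded coarse grid search over porter count, ward-not-ready
  probability and delay, and infection prevalence (3 replications ×
  365 days per point) selects the combination whose simulated mean
  perturbations land nearest the published 11.9 / 0.15 min; the chosen
  values are frozen into `params_default.yaml`.

Every closed-form expectation is computed by enumerating attribute
profiles through the *same* pathway builder the simulator executes, so
the calibration round trip (expected CSM reproduces all four targets
to 1e-6) is a genuine consistency check, not a tautology.

Durations are lognormal, parameterized by (mean, cv) so the mean is
exact; the family is configurable per task and cv = 0 degenerates to a
deterministic time.  Lognormal was chosen for the positive skew
typical of service times; cv defaults (0.20 scans, 0.25–0.30
otherwise) are conventions, as dispersion was not published.

## Synthetic demand

The generator emulates roughly 5958 examinations/year: 13 slots per
weekday (8 before lunch, 5 after) for the scheduled stream, with the
remainder as a nonhomogeneous Poisson process (per-day Poisson count,
daytime-peaked hourly profile) for the unscheduled stream, giving an
unscheduled share of ≈43%.  The diurnal profile, the slot count and
the cohort splits (OP:GP = 3:1, IP:ED = 3:1) are assumptions: the
historic arrival records behind the original analysis are not public.
What passing tests show is therefore internal consistency — that the
method recovers the published metrics under demand with the *assumed*
statistical structure — not agreement with any particular hospital's
data.  Real arrival streams can be supplied through the CLI and the
`EventLog`/`ParameterSet` interfaces.

## Validation

`validate(sim_log, reference_log)` computes the mean absolute error of
per-patient arrival-to-scan-finish durations, entity-matched when
identifiers align and quantile-paired otherwise; the signed mean error
is reported alongside (the published "mean error difference" of
3.36 min is ambiguous between the two).  The historic comparison is
not reproducible without the 2015 records; the repository instead runs
a self-consistency experiment against a synthetic reference log under
a held-out seed and checks the error stays small relative to mean time
in system, and that parameter distortion strictly worsens it.

## Scenarios and waiting list

Scenarios are parameter overrides run for `n` seeded replications;
common random numbers reuse the same master seeds across scenarios for
paired comparison.  "Separate services" is modeled as two independent
single-scanner departments (`op_only`: unscheduled rate multiplier 0;
`ip_only`: empty slot template).  The waiting list evolves weekly as
`pending_{t+1} = max(0, pending_t + demand_t − served_t)` with demand
70 referrals/week against a slot capacity of 65/week (the published
backlog level and referral rate are not printed; only the growth
regime is reproduced).  `fast` mode uses the analytic capacity;
`micro` mode reads weekly completed scheduled examinations from a full
simulation run.

## Problem sizes and numerical choices

The shipped experiments use 10 replications × 365 days for the
headline reproduction (seeds 1..10), 200 generator replications for
the annual-volume check, and 3–6 replications at 30–90 days for
paired-scenario and validation properties; these sizes keep each check
to seconds while leaving Monte-Carlo error well inside the stated
tolerances.  Ties in the event queue and in every resource queue break
FIFO by insertion order.  Grants occur only at instants when a unit's
calendar is open; an in-progress task may run past a closing edge
(non-preemptive overrun).  Degenerate inputs (zero demand, zero-length
tasks, empty logs, zero rosters) either produce exact trivial results
or raise precise configuration errors.

## Known limitations

* No radiologist reporting workflow, no clerical pre-booking of
  scheduled work, no wheelchair inventory, no multi-scanner site
  logic beyond a scanner-count parameter.
* Phone-call interruptions and dynamic in-queue re-prioritization are
  structural hooks (priority updates are supported by the resource
  pools) but are off by default, as no rates were published.
* The on-call arrangement and the shift-boundary correction are
  simplifications; utilization of the on-call complement is not
  reported.
* The waiting-list projection treats referral demand as exogenous and
  constant; supplier-induced demand is out of scope.
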