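schema: 1
seed: 0
annual_exam_total: 5958.0
scheduled:
  slot_times:
  - 510.0
  - 543.0
  - 576.0
  - 609.0
  - 642.0
  - 675.0
  - 708.0
  - 741.0
  - 840.0
  - 873.0
  - 906.0
  - 939.0
  - 972.0
  weekdays:
  - 0
  - 1
  - 2
  - 3
  - 4
  no_show_prob: 0.0
  cohort_mix:
    OP: 0.75
    GP: 0.25
unscheduled:
  hourly_weights:
  - 0.4
  - 0.4
  - 0.4
  - 0.4
  - 0.4
  - 0.4
  - 0.4
  - 0.8
  - 1.8
  - 1.8
  - 1.8
  - 1.8
  - 1.8
  - 1.8
  - 1.8
  - 1.8
  - 1.8
  - 1.2
  - 1.2
  - 1.2
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  cohort_mix:
    IP: 0.75
    ED: 0.25
  rate_multiplier: 1.0
cohorts:
  OP:
    exam_class_mix:
      non_contrast: 0.45
      iv_contrast: 0.35
      oral_and_iv: 0.2
    mobility_mix:
      walking: 0.9
      wheelchair: 0.09
      bed: 0.01
    p_infectious: 0.002
    urgency: 2
  GP:
    exam_class_mix:
      non_contrast: 0.45
      iv_contrast: 0.35
      oral_and_iv: 0.2
    mobility_mix:
      walking: 0.9
      wheelchair: 0.09
      bed: 0.01
    p_infectious: 0.002
    urgency: 2
  IP:
    exam_class_mix:
      non_contrast: 0.5
      iv_contrast: 0.3
      oral_and_iv: 0.2
    mobility_mix:
      walking: 0.3
      wheelchair: 0.3
      bed: 0.4
    p_infectious: 0.15
    urgency: 1
  ED:
    exam_class_mix:
      non_contrast: 0.5
      iv_contrast: 0.3
      oral_and_iv: 0.2
    mobility_mix:
      walking: 0.3
      wheelchair: 0.3
      bed: 0.4
    p_infectious: 0.15
    urgency: 0
staffing:
  radiographers_day: 2
  hcas_day: 1
  porters: 1
  on_call_radiographers: 1
  on_call_hcas: 1
  p_cannulate: 0.5
  day_shift_start: 510.0
  day_shift_end: 1020.0
tasks:
  prep:
    mean: 1.8853
    cv: 0.25
    dist: lognormal
  oral_supervision:
    mean: 2.0
    cv: 0.25
    dist: lognormal
  cannulation:
    mean: 5.0
    cv: 0.25
    dist: lognormal
  injector_setup:
    mean: 2.0
    cv: 0.25
    dist: lognormal
  schedule_step:
    mean: 0.36575833333333313
    cv: 0.3
    dist: lognormal
  manual_handling_wheelchair:
    mean: 2.0
    cv: 0.25
    dist: lognormal
  manual_handling_bed:
    mean: 3.0
    cv: 0.25
    dist: lognormal
  scan_scheduled_non_contrast:
    mean: 3.8347
    cv: 0.2
    dist: lognormal
  scan_scheduled_iv:
    mean: 13.407427272727276
    cv: 0.2
    dist: lognormal
  scan_unscheduled_non_contrast:
    mean: 6.420149999999999
    cv: 0.2
    dist: lognormal
  scan_unscheduled_iv:
    mean: 16.170149999999996
    cv: 0.2
    dist: lognormal
  cannula_removal:
    mean: 2.0
    cv: 0.25
    dist: lognormal
  observation:
    mean: 15.0
    cv: 0.25
    dist: lognormal
  transport_leg:
    mean: 10.0
    cv: 0.3
    dist: lognormal
  transport_coordination:
    mean: 3.7430441335721913
    cv: 0.3
    dist: lognormal
  post_processing:
    mean: 9.49379317250447
    cv: 0.25
    dist: lognormal
  paperwork:
    mean: 6.329195448336314
    cv: 0.25
    dist: lognormal
scanners: 1
decon_minutes: 60.0
standard_clean_minutes: 5.0
p_ward_not_ready: 0.45
ward_not_ready_delay:
  mean: 10.0
  cv: 0.3
  dist: lognormal
oral_drink_minutes: 30.0
protect_lunch: false
lunch_start: 780.0
lunch_end: 840.0
csm_include_porter: false
csm_include_decon: false
waitlist:
  weekly_referrals: 70.0
  initial_backlog: 120.0
  weekly_capacity: null
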