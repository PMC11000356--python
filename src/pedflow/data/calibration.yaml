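# Calibration constants for the pediatric ED simulator, version 1.
# All durations are minutes; probabilities are printed percentages (they are
# renormalized to sum to 1 at load time).

version: 1

arrivals:
  annual_visits: 28500
  per_day: 78
  overnight_fraction: 0.23      # share of arrivals in [00:00, 10:00)
  overnight_end_minute: 600

transfer_latency:
  p_within_5: 0.83
  p_within_10: 0.94

age_months:
  median: 34
  q1: 12
  q3: 100

case_mix:
  reason:                       # fever, respiratory, digestive, trauma, other
    fever: 14.2
    respiratory: 16.3
    digestive: 15.0
    trauma: 13.0
    other: 41.5
  priority:                     # simplified 3-level acuity
    high: 13.1
    moderate: 57.3
    low: 29.6
  blood_tests:
    0: 83.7
    1: 15.6
    2: 0.8
  imaging:
    0: 72.5
    1: 25.1
    2: 2.1
    3: 0.3
  specialist:
    0: 77.2
    1: 19.6
    2: 2.9
    3: 0.4
  treatment_lines:
    0: 86.9
    1: 12.6
    2: 0.6
  senior_evals:
    0: 33.6
    1: 51.0
    2: 15.3
  disposition:                  # home, short-stay, ward, LWBS, PICU
    home: 77.4
    short_stay: 10.9
    ward: 9.9
    lwbs: 1.3
    picu: 0.5

# Per-stage interval summaries as median [q1, q3], one block per arm.
stage_specs:
  control:
    admission_to_triage: [15, 8, 23]
    triage_to_first_eval: [23, 11, 45]
    first_eval_to_junior_eval: [29, 19, 45]
    admission_to_senior_eval: [71, 47, 102]
    blood_presc_to_draw: [40, 25, 60]
    blood_draw_to_result: [122, 73, 171]
    imaging_presc_to_result: [63, 35, 118]
    specialist_presc_to_eval: [39, 10, 110]
    treatment_presc_to_admin: [25, 12, 48]
    final_senior_to_end_of_care: [0, 0, 97]
    end_of_care_to_discharge: [33, 16, 73]
  optimum:
    admission_to_triage: [15, 8, 27]
    triage_to_first_eval: [21, 10, 50]
    first_eval_to_junior_eval: [30, 19, 47]
    admission_to_senior_eval: [76, 49, 118]
    blood_presc_to_draw: [41, 20, 75]
    blood_draw_to_result: [129, 81, 180]
    imaging_presc_to_result: [59, 35, 100]
    specialist_presc_to_eval: [45, 8, 106]
    treatment_presc_to_admin: [21, 9, 43]
    final_senior_to_end_of_care: [0, 0, 88]
    end_of_care_to_discharge: [29, 14, 62]
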