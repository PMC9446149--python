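population:
  n_agents: 10000
  ward_shares:
  - 0.11341889943194945
  - 0.11341889943194945
  - 0.11341889943194945
  - 0.11341889943194945
  - 0.11341889943194945
  - 0.12392146083797415
  - 0.19556514257032911
  - 0.11341889943194945
  smartphone_ownership: 0.8
  car_ownership:
  - 0.62
  - 0.62
  - 0.62
  - 0.62
  - 0.62
  - 0.68
  - 0.45
  - 0.55
  age_range:
  - 18.0
  - 65.0
  height_mean: 1.63
  height_sd: 0.07
  bmi_median: 30.2
  bmi_sigma: 0.23
  bmi_range:
  - 16.0
  - 55.0
  income_median: 45000.0
  income_sigma: 0.6
  seed: 1
environment:
  centers_per_ward:
  - 4
  - 3
  - 4
  - 4
  - 3
  - 8
  - 1
  - 3
  geofence_miles: 0.5
  walk_reach_km: 1.0
  drive_reach_km: 8.0
  ward_size_km: 4.0
  class_days:
  - 0
  - 1
  - 2
  - 3
  - 4
  class_duration: 50.0
  class_intensity: 6.5
gates:
  p_perceived_access: 0.6
  p_class_awareness: 0.5
  p_prepared: 0.5
  p_perceived_access_app: 0.85
  p_class_awareness_app: 0.8
  p_prepared_app: 0.8
  habit_sd: 0.0
metabolic:
  rho_fat: 9440.0
  rho_lean: 1807.0
  forbes_c: 10.4
  rmr_slope: 19.7
  rmr_intercept: 413.0
  pal: 1.5
  met_resting_subtracted: true
  lean_floor: 25.0
  fat_floor: 2.0
engagement:
  p_aware: 0.5
  p_download: 0.5823
  p_notify: 0.55
engagement_mode: sampled
attrition:
  r_inf: 0.3
  window_days: 90
app_intro_day: 0
baseline_exercise_prob: 0.25
horizon_years: 5
replicates: 10
seed: 1
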