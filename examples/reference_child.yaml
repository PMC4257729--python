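# A reference boy from birth to age 18 on the on-trajectory (demand-matching)
# intake.  All parameter blocks are shown with their defaults; delete any
# block to use the built-in values.
curves:
  source: synthetic      # or "lms" with height_path/bmi_path CSV tables
  sex: male
  race: nh_white
subject:
  height_factor: 1.0     # individual potential-height multiplier
  bmi_factor: 1.0        # predisposition to higher BMI
  fmi_offset: 0.0        # kg/m^2 of fat beyond the BMI/race expectation
  pa_factor: 1.0         # physical-activity multiplier
  bioage_multiplier: 1.0 # <1 slow developer, >1 fast developer
composition:
  lambda_bmi: 0.5        # weight on current BMI in the indicated-BMI blend
  gamma: 2.0             # elasticity of indicated FMI with respect to BMI
  age_slope: 0.0         # extra post-adult FMI slope (curve already has one)
  rho_fm: 39.5           # MJ/kg fat
  rho_ffm_adult: 5.0     # MJ/kg fat-free mass at adult saturation
  rho_ffm_intercept: 1.5
  rho_ffm_slope: 0.0875
metabolic:
  tef_fraction: 0.10
  at_coefficient: 0.25
  at_includes_growth: true
  deposition_efficiency_fm: 0.98
  deposition_efficiency_ffm: 0.85
  sigma_fm: 0.0187       # MJ/kg/day adipose
  sigma_residual: 0.10   # MJ/kg/day residual FFM at childhood cellularity
  turnover_rate: 0.0
  pa_scales_with_weight: true
simulation:
  dt: 1.0
  tau_height: 180.0
  tau_mass_gap: 60.0
  tau_correction: 60.0
  catchup_cap: 4.0
  stunting_threshold: 0.85
  stunting_floor: 0.60
  starvation_fraction: 0.20
scenario:
  t_start_years: 0.0
  t_end_years: 18.0
  dt_days: 1.0
  intake:
    mode: reference
  initial:
    kind: reference
output:
  directory: out/reference_child
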