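# Severe under/overfeeding of a 30-year-old, 80 kg white male.
# He holds his 11.74 MJ/day equilibrium intake for 100 days, switches to a
# 1500 kcal/day (6.28 MJ/day) deficit on day 100, and to a 1500 kcal/day
# surplus on day 250 for another 450 days.  (11.74 MJ/day is the equilibrium
# intake the package computes for this subject; see the README example.)
curves:
  source: synthetic
  sex: male
  race: nh_white
scenario:
  t_start_years: 30.0
  t_end_years: 31.917   # 700 days
  dt_days: 1.0
  intake:
    mode: piecewise
    segments:
      - {from_years: 30.0, to_years: 30.274, mj_per_day: 11.74}
      - {from_years: 30.274, to_years: 30.684, mj_per_day: 5.46}
      - {from_years: 30.684, to_years: 31.917, mj_per_day: 18.02}
  initial:
    kind: explicit
    age_years: 30.0
    weight_kg: 80.0
output:
  directory: out/adult_overfeeding
  ledger: true
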