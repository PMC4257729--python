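# Data dictionary — `result.csv`

One row per integration step (daily by default).  State columns describe the
start of the step; flow columns describe the step that begins at that row
(the final row has no flows and holds NaN there).

Units: age in days, masses in kg, height in m, energies in MJ/day unless
noted.

## State columns

| column         | meaning                                                   |
|----------------|-----------------------------------------------------------|
| `age`          | calendar age, days                                        |
| `fm`, `ffm`    | fat mass, fat-free mass                                   |
| `h`            | height                                                    |
| `bw`           | body weight = fm + ffm                                    |
| `bmi`          | body mass index, kg/m²                                    |
| `fat_fraction` | fm / bw                                                   |
| `bmi_star`     | indicated BMI (blend of current and reference BMI)        |
| `bw_star`      | indicated body weight                                     |
| `fm_star`, `ffm_star` | indicated fat / fat-free mass                      |

## Flow columns (per step)

| column              | meaning                                              |
|---------------------|------------------------------------------------------|
| `ei`                | energy intake                                        |
| `bmr`               | organ-based basal metabolic rate                     |
| `pa`                | physical-activity energy                             |
| `tef`               | thermic effect of feeding                            |
| `at`                | adaptive-thermogenesis adjustment (signed)           |
| `turnover`          | mass-turnover energy                                 |
| `growth_fm_demand`, `growth_ffm_demand` | essential-deposition energy demand (trajectory motion plus catch-up) |
| `growth_fraction`   | funded share of the trajectory-motion growth demand (throttles height growth) |
| `v_height`          | realized height velocity, m/day                      |
| `stunting`          | BMI-threshold growth throttle in [0, 1]              |
| `losses`            | deposition-efficiency losses                         |
| `catabolized`       | energy released from body stores                     |
| `stored`            | energy deposited into body stores                    |
| `expended`          | total expenditure = bmr+pa+tef+at+turnover+losses    |
| `net_dfm`, `net_dffm` | net mass change rates, kg/day                      |
| `extra_fm`, `extra_ffm` | mass above the indicated trajectory, kg          |

First-law check for any window: `sum((ei - expended) * dt)` equals the
change in metabolizable body energy (`growthsim.body_energy`) over the same
window to machine precision.
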