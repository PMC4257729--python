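# growthsim

Mechanistic simulation of an individual human's body weight, body
composition (fat mass / fat-free mass) and height from birth to old age,
driven by energy intake and canalized reference growth curves.

The model integrates three states — FM, FFM and H — with a daily explicit
Euler step.  Exogenous age-indexed reference curves (median height, BMI,
fat-mass index and physical activity, per sex and race) define an
*indicated* trajectory the body is drawn toward; an energy-allocation
priority ladder reconciles intake with itemized demands

    D = BMR + PA + TEF + growth + turnover + AT,

where BMR is organ-based (liver, brain, heart, kidneys plus adipose and
residual fat-free tissue, adjusted for age-dependent cellularity), AT is
adaptive thermogenesis applied to BMR, and growth demand prices the motion
of the indicated trajectory plus catch-up.  Body composition follows an
indicated fat-mass-index family FMI*(BMI) = A·(BMI/BMI_ref)^γ whose
derivative gives the marginal partition fraction
p_FFM = 1 − γ·FMI*/BMI of weight change deposited as fat-free mass.
Height growth is canalized with catch-up capped at four times the
age-specific reference velocity and throttled below 85% of BMI-for-age —
so chronic malnutrition stunts, refeeding before adulthood catches up, and
a deficit maintained to adulthood leaves a permanent height deficit.

It is intended for researchers and modellers studying growth, malnutrition
and obesity interventions: it answers questions like "what intake tracks the
97th BMI percentile?", "what energy gap returns a subject one BMI unit above
the reference to it within a year?", or "how much surplus intake is embedded
in an elevated population BMI curve?".  A bundled parametric generator
emulates chart-like reference curves so everything runs without downloads;
real CDC-style LMS tables (`age_days,L,M,S` or `age_days,P50`) can be
dropped in.

## Worked example

A 30-year-old white male at 80 kg equilibrium switches to a 1500 kcal/day
deficit on day 100 and to a 1500 kcal/day surplus on day 250 for another
450 days:

```python
import growthsim as gs
from growthsim import DAYS_PER_YEAR as Y

curves = gs.synthetic_reference(sex="male")
subject = gs.Subject(sex="male", race="nh_white")
t0 = 30 * Y
state = gs.reference_state(subject, curves, t0, bmi=80.0 / 1.77**2)
ei0 = gs.equilibrium_intake(state, subject, curves)
print(f"equilibrium intake: {ei0:.2f} MJ/day  fat fraction: {state.fat_fraction:.1%}")

delta = 1500 * 0.004184  # kcal/day -> MJ/day
scenario = gs.Scenario.piecewise(
    ei0, [(t0 + 100, t0 + 250, ei0 - delta), (t0 + 250, t0 + 700, ei0 + delta)],
    t0, t0 + 700, initial_state=state)
result = gs.simulate(subject, curves, scenario)
bw = result.series["bw"]
print(f"weight at day 250: {bw[250]:.1f} kg   final weight: {bw[-1]:.1f} kg")
lhs, rhs, rel = result.energy_audit()
print(f"energy audit residual: {rel:.1e} (relative)")
```

prints

```
equilibrium intake: 11.74 MJ/day  fat fraction: 20.5%
weight at day 250: 51.8 kg   final weight: 119.5 kg
energy audit residual: 5.6e-17 (relative)
```

He maintains 80 kg at 11.74 MJ/day with 20.5% body fat; the 150-day deficit
strips him to 51.8 kg (extra mass is catabolized first, adaptive
thermogenesis spares energy, activity cost falls with the mass moved), the
450-day surplus carries him to 119.5 kg, and the whole run conserves energy
to machine precision.

The same scenario as a config file: `examples/adult_overfeeding.yaml`, run
with the CLI:

```bash
growthsim simulate examples/adult_overfeeding.yaml
growthsim validate-config examples/reference_child.yaml
growthsim make-curves --sex female --out curves/
growthsim analyze examples/reference_child.yaml --kind maintenance_gap
```

Each run writes `result.csv` (columns documented in
`docs/data_dictionary.md`), a resolved-config snapshot, a log and a hashed
manifest, and is byte-reproducible from the snapshot alone.

Higher-level analyses live in `growthsim.analyses`: calibration of intake
multipliers and individual height factors to observed targets,
BMI-percentile tracking (the daily intake that makes BMI follow an arbitrary
curve, exposing stunting at low percentiles), and the weight-loss and
maintenance energy-gap computations.

See `docs/methods.md` for the model description, parameter defaults and
known limitations.

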