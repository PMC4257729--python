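# Methods

`growthsim` integrates three state variables — fat mass FM (kg), fat-free
mass FFM (kg) and height H (m) — with a one-day explicit Euler step from
birth to old age.  Two ideas organize the model: *canalization* (exogenous
age-indexed reference curves define an indicated trajectory that height, and
to a lesser degree body composition, are drawn back toward) and *energy
allocation* (a strict priority ladder reconciles intake with itemized
demands and converts the imbalance into mass change, catch-up growth or
stunting).  The core is fully deterministic: there is no random number
generator anywhere in the model.

## Canalized targets

Reference curves (per sex; race enters as an additive height offset and an
additive term in the fat-mass-index anchor) supply, as functions of
biological age: median height H_ref, BMI_ref, FMI_ref, reference physical
activity PA_ref, organ mass fractions and relative cellularity.  Biological
age is `bioage_multiplier × calendar age`, so slow or fast developers can be
simulated with a single factor.

The potential height is `H* = height_factor · (H_ref + race offset)`.  The
indicated BMI blends the subject's current state with the chart,

    BMI* = λ·BMI + (1−λ)·bmi_factor·BMI_ref ,        λ = 0.5 by default,

reflecting that BMI is only partially canalized while height is tightly
regulated.  The indicated fat-mass index follows a power-law family anchored
on the reference FMI:

    FMI*(B) = A · (B / BMI_ref)^γ ,   A = FMI_ref + race term + fmi_offset ,

with elasticity γ = 2 by default.  Differentiating FFM = (BMI − FMI)·H² at
fixed height yields the marginal partition fraction

    p_FFM = 1 − dFMI*/dBMI = 1 − γ·FMI*(BMI)/BMI ,

the share of a marginal weight change deposited as (or drawn from) fat-free
mass.  `p_FFM` is clipped to [0.01, 0.99] with a logged warning at
pathological BMIs so flows stay defined in extreme scenarios.  The classical
Forbes partition `10.4/(10.4+FM)` is provided for comparison only.

Body energy: fat has constant metabolizable density ρ_FM = 39.5 MJ/kg.  The
*marginal* FFM density rises linearly, `min(5, 1.5 + 0.0875·FFM)` MJ/kg,
saturating at the adult 5 MJ/kg at 40 kg FFM.  All mass↔energy conversions
invert the exact piecewise-quadratic cumulative energy curve, which is why
whole-life energy audits close at machine precision (~1e-16 relative) rather
than drifting with the step count.

## Energy demand

    D = BMR + PA + TEF + growth_FM + growth_FFM + turnover + AT.

**BMR** sums liver, brain, heart and kidneys — mass = age-dependent fraction
of the *indicated* body weight, scaled by a per-organ response (0.6; brain
0) to the relative deviation of actual from indicated weight — times
literature specific metabolic rates (liver 0.84, brain 1.00, heart/kidneys
1.84 MJ/kg/day), plus adipose tissue at 0.0187 and residual FFM at
0.10 MJ/kg/day.  A relative-cellularity curve (1.0 through age 10, 0.72 at
20, 0.66 at 30, 0.53 at 100) multiplies the organ and residual terms,
capturing the decline of mass-specific tissue metabolism from childhood
through old age; a config switch restores the organs-only convention.  With
these defaults per-kg basal rates are ~51/46/39 kcal/kg/day at 0.75/5/10
years and the reference 30-year-old male at 80 kg spends ≈ 11.7 MJ/day at
equilibrium with a 20.5% fat fraction — the adult calibration anchors used
to fix the residual rate and adult activity level once.

**PA** is the age-referenced activity energy (Torun-style childhood values
rising to 3.2 MJ/day in adolescence, declining in old age) scaled by
`BW / BW_ref(age)`: moving more mass costs proportionally more energy.
Without this scaling the model has no weight-dependent activity brake and
over/underfeeding trajectories diverge qualitatively from the adult models
this component follows.  **TEF** is 10% of intake.  **Turnover** is a per-kg
rate, zero by default (folded into the residual BMR).

**Growth demand** prices the desired deposition velocity of essential mass:
the motion of the indicated trajectory — evaluated at constant offset from
the canalized curve, so an on-trajectory child demands exactly the chart's
motion — plus a gap-closing catch-up term `max(0, X*−X)/τ_mass` (τ_mass =
60 d), each divided by the deposition efficiency (FFM 0.85, FM 0.98).  When
the indicated trajectory itself falls (the post-infancy BMI decline, aging),
the shed mass releases its energy into the ladder as supply rather than
creating negative demand.

**Adaptive thermogenesis** applies to BMR only:
`AT = c·(EI/D_pre − 1)·BMR` with c = 0.25, where D_pre is the demand for all
other components and, by default, includes catch-up growth needs (config
switch `at_includes_growth`).  It is negative under deficit (energy
sparing), positive under surplus, instantaneous by construction.

## Allocation ladder

Each step, after a composition-correction exchange (below), sources serve
demands in strict priority.  Sources: intake first; then *extra* FM/FFM
(mass beyond the indicated trajectory), consumed with the same p_FFM split
used for deposition; essential mass is catabolized last and only for
maintenance.  Demands: maintenance (BMR+PA+TEF+turnover+AT) first, then
essential deposition (trajectory motion before catch-up), and only then does
surplus intake deposit extra mass split p_FFM : (1−p_FFM).  If maintenance
cannot be met even from essential stores, or essential FM/FFM falls below
20% of indicated, the run halts with a starvation-collapse flag (the model
does not represent death; this marks the edge of its validity).

**Composition correction.**  Deviations of FM from the FMI indicated by the
*current* BMI decay with τ_corr = 60 d via an FM↔FFM exchange at fixed body
weight; the energy released by the shrinking compartment funds the growing
one and the surplus or deficit enters the ladder.  This homeostatic channel
is what returns the fat fraction to the reference curve after an episode of
weight gain and loss — the architecture's distinguishing prediction against
pure-partitioning models, which retain a permanent composition shift.

## Height growth, catch-up and stunting

Desired velocity: `v = min(v_ref + max(0, H*−H)/τ_H, 4·v_ref)` with τ_H =
180 d — catch-up growth up to four times the age-specific reference rate,
impossible after the adult stop (v_ref = 0 beyond age 20), so unrepaired
deficits become permanent.  The velocity is multiplied by a stunting factor:
1 at or above 85% of BMI-for-age, ramping linearly to 0 at 60%.  Finally the
realized velocity is scaled by the funded fraction of the trajectory-motion
growth demand, so true energy crises (intake short of maintenance plus
normal growth) stall height even above the BMI threshold.  Throttling by the
*total* growth funding (including mass catch-up) was rejected: it makes a
child merely held at 85% of BMI-for-age grow at a quarter speed, which
contradicts the threshold semantics.

Under these rules, severe chronic restriction (60% of reference intake from
age 2) yields a permanent ~6% height deficit if maintained to adulthood,
while refeeding at age 10 recovers the full potential height with the 4×
cap binding during catch-up.

## Reference intake, equilibrium and inversions

`equilibrium_intake` returns the intake at which deviation flows vanish (no
catabolism, no extra deposition, growth exactly funded); for a growing child
this is the reference intake, and feeding it daily reproduces the height and
BMI charts to within 0.05% over 0–18 y.  `percentile_tracking_intake`
inverts the energy balance day by day so BMI tracks an arbitrary curve; it
prefers the largest intake consistent with the target (growth funded before
catabolism), because BMI alone under-determines intake while growth funding
modulates.  Days where exact tracking would need negative intake are clipped
to zero and flagged — the stunting regime of low percentile curves.
Calibrations (intake multiplier to a target weight, height factor to an
observed height) are plain bisections over full simulations; tolerances
0.05 kg and 1 mm, verified by round-trip in the tests.

The two policy analyses: the *weight-loss energy gap* is the difference
between the constant intake holding a subject `ΔBMI` above the reference
curve for one year and the constant intake reaching the reference curve in
exactly that year (also expressed as a fraction of the former); the
*maintenance energy gap* is the per-age difference between the
demand-matching intakes at an observed (elevated) BMI curve and at the
reference curve.

## Synthetic reference curves

The bundled parametric generator replaces chart tables so everything runs
without downloads.  Height integrates a velocity profile (decaying infancy
term, childhood plateau tapering to zero at the adult stop, single Gaussian
adolescent spurt — male peak 13 y, female 11 y), rescaled so the adult
height is exact (male 1.77 m, female 1.63 m).  BMI and FMI use a common
shape — floor + infancy decay + infancy bump + logistic adolescent rise —
giving the infancy peak, the childhood minimum (between ages 3 and 8) and
the rise to adult levels (BMI 22.0/21.7; FMI anchor 3.8 male / 6.5 female at
age 20 with +0.008/+0.010 kg/m² per year of adult aging).  PA uses
monotone-Hermite knots.  All curves are shape-preserving piecewise cubics
(PCHIP): no overshoot between knots, which matters because the height
curve's derivative feeds the growth demand.  Evaluation outside a curve's
tabulated span raises rather than extrapolating.  Real chart tables can be
substituted via the LMS CSV loader (`age_days,L,M,S` or `age_days,P50`; the
median is the M column), with an explicit opt-in plateau extension for
tables that end at age 20.

What the synthetic curves do not emulate: chart-vintage detail, percentile
shapes other than scaled/shifted medians, secular trends, and
population-fitted race offsets (defaults are plausible placeholders).
Passing tests therefore demonstrate the mechanics and internal consistency
of the model, not agreement with any particular survey population.

## Numerical choices and limitations

* Explicit Euler, dt = 1 day; halving the step changes the severe adult
  scenario's weight by < 0.03 kg.  Flows are linear in dt; per-step
  exchanges are capped (a quarter of the shrinking compartment) to keep the
  explicit step well behaved.
* Root finds are bisection/Brent only — the step map is piecewise linear in
  intake, and gradient methods would chatter at the ladder's regime
  boundaries.  Equilibrium intake has a closed-form fixed point (AT vanishes
  at balance) used as the solver's starting point.
* Tie-breaks: at exactly 85% of BMI-for-age growth is unthrottled (the
  boundary is inclusive); extra stores are consumed with the deposition
  p-split, switching to single-compartment draws when one side empties.
* The childhood-overfeeding experiment (120% intake, ages 12–15) peaks near
  13 kg of weight excess with the default expenditure responses; the
  magnitude is sensitive to the per-kg activity and organ-mass responses,
  for which the literature gives a range rather than a value.  Composition
  homeostasis after the episode is insensitive to this choice.
* Not modelled: macronutrient composition, sub-daily dynamics, pregnancy,
  disease, mortality; hormonal regulation is summarized by the time
  constants τ_H, τ_mass, τ_corr.
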