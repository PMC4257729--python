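"""Shared fixtures: synthetic curve sets, default parameters, and the
expensive reference-intake simulations reused across test modules."""

import numpy as np
import pytest

import growthsim as gs
from growthsim import DAYS_PER_YEAR as Y


@pytest.fixture(scope="session")
def male_curves():
    return gs.synthetic_reference(sex="male")


@pytest.fixture(scope="session")
def female_curves():
    return gs.synthetic_reference(sex="female")


@pytest.fixture(scope="session")
def male_subject():
    return gs.Subject(sex="male")


@pytest.fixture(scope="session")
def female_subject():
    return gs.Subject(sex="female")


@pytest.fixture(scope="session")
def params():
    return gs.ModelParams()


@pytest.fixture(scope="session")
def adult80(male_curves, male_subject, params):
    """30-year-old white male at 80 kg equilibrium: (state, equilibrium EI)."""
    state = gs.reference_state(male_subject, male_curves, 30 * Y, params,
                               bmi=80.0 / 1.77 ** 2)
    ei0 = gs.equilibrium_intake(state, male_subject, male_curves, params)
    return state, ei0


@pytest.fixture(scope="session")
def adult_feeding_result(male_curves, male_subject, params, adult80):
    """The two-phase severe under/overfeeding scenario for the 80 kg adult:
    -1500 kcal/day on days 100-250, +1500 kcal/day on days 250-700."""
    state, ei0 = adult80
    t0 = state.age
    delta = 1500 * 0.004184
    scn = gs.Scenario.piecewise(
        ei0, [(t0 + 100, t0 + 250, ei0 - delta), (t0 + 250, t0 + 700, ei0 + delta)],
        t0, t0 + 700, initial_state=state)
    return gs.simulate(male_subject, male_curves, scn, params)


@pytest.fixture(scope="session")
def male_reference_intake(male_curves, male_subject, params):
    """Reference (on-trajectory) intake series, birth to age 20."""
    return gs.reference_intake(male_subject, male_curves, params,
                               t_start=0.0, t_end=20 * Y)
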