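"""Daily integration: height canalization, stunting/catch-up, composition
homeostasis, equilibrium intake and the whole-run energy audit."""

import dataclasses

import numpy as np
import pytest

import growthsim as gs
from growthsim import DAYS_PER_YEAR as Y
from growthsim.errors import ParameterError
from growthsim.simulator import desired_height_velocity, stunting_factor


class TestHeightVelocityRules:
    def test_on_trajectory_reference_rate(self):
        assert desired_height_velocity(1.0, 1.0, 2e-4, 180.0) == pytest.approx(2e-4)

    def test_large_deficit_hits_four_fold_cap(self):
        v = desired_height_velocity(0.8, 1.2, 2e-4, 180.0, cap=4.0)
        assert v == pytest.approx(4 * 2e-4)

    def test_adult_stop_makes_stunting_permanent(self):
        assert desired_height_velocity(1.5, 1.77, 0.0, 180.0) == 0.0

    def test_increment_cap_mode(self):
        v = desired_height_velocity(0.8, 1.2, 2e-4, 180.0, cap=4.0, cap_total=False)
        assert v == pytest.approx(4 * 2e-4)

    @pytest.mark.parametrize("ratio,expected", [
        (1.00, 1.0), (0.85, 1.0), (0.90, 1.0),
        (0.725, 0.5), (0.60, 0.0), (0.50, 0.0),
    ])
    def test_stunting_ramp(self, ratio, expected):
        assert stunting_factor(20.0 * ratio, 20.0) == pytest.approx(expected)


class TestStepAndEquilibrium:
    def test_equilibrium_adult_state_unchanged(self, male_curves, male_subject):
        # with the composition aging term silenced, the demand-matching
        # intake leaves the adult state unchanged to solver precision
        curves = dataclasses.replace(
            male_curves,
            fmi_ref=gs.curves.AgeCurve(male_curves.fmi_ref.ages,
                                       np.full_like(male_curves.fmi_ref.values, 3.8),
                                       name="fmi_ref"),
            bmi_ref=gs.curves.AgeCurve(male_curves.bmi_ref.ages,
                                       np.full_like(male_curves.bmi_ref.values, 22.0),
                                       name="bmi_ref"))
        st = gs.reference_state(male_subject, curves, 30 * Y)
        ei = gs.equilibrium_intake(st, male_subject, curves)
        st2 = gs.step(st, male_subject, curves, ei)
        assert abs(st2.bw - st.bw) < 1e-6

    def test_equilibrium_intake_monotone_in_activity(self, male_curves):
        vals = []
        for pa in (0.5, 1.0, 1.5):
            subj = gs.Subject(pa_factor=pa)
            st = gs.reference_state(subj, male_curves, 30 * Y)
            vals.append(gs.equilibrium_intake(st, subj, male_curves))
        assert vals[0] < vals[1] < vals[2]

    def test_negative_intake_rejected(self, male_curves, male_subject):
        st = gs.reference_state(male_subject, male_curves, 30 * Y)
        with pytest.raises(ParameterError):
            gs.step(st, male_subject, male_curves, -1.0)


class TestCanalization:
    def test_child_on_reference_intake_tracks_charts(self, male_reference_intake,
                                                     male_curves):
        """Feeding the demand-matching intake from birth reproduces the
        reference height and BMI charts — the defining property of the
        reference trajectory."""
        sim = male_reference_intake.sim
        ages = sim.series["age"]
        sel = ages <= 18 * Y
        bmi_dev = np.abs(sim.series["bmi"][sel] - male_curves.bmi_ref(ages[sel]))
        h_dev = np.abs(sim.series["h"][sel] - male_curves.height_ref(ages[sel]))
        assert np.nanmax(bmi_dev / male_curves.bmi_ref(ages[sel])) < 0.01
        assert np.nanmax(h_dev / male_curves.height_ref(ages[sel])) < 0.01

    def test_final_height_matches_potential(self, male_reference_intake, male_curves):
        sim = male_reference_intake.sim
        assert sim.series["h"][-1] == pytest.approx(
            male_curves.height_ref(20 * Y), rel=0.005)

    def test_height_never_decreases(self, adult_feeding_result, male_reference_intake):
        for res in (adult_feeding_result, male_reference_intake.sim):
            assert np.all(np.diff(res.series["h"]) >= -1e-15)

    def test_catchup_after_early_deficit_permanent_if_sustained(
            self, male_curves, male_subject, params, male_reference_intake):
        """Severe restriction from age 2: refeeding at 10 restores height to
        within 2% of potential; the same deficit to adulthood leaves a
        permanent deficit (directional canalization test)."""
        ref = male_reference_intake
        recover = gs.simulate(male_subject, male_curves, gs.Scenario.multiplier_of_reference(
            ref, [(2 * Y, 10 * Y, 0.60)], 0.0, 20 * Y), params)
        chronic = gs.simulate(male_subject, male_curves, gs.Scenario.multiplier_of_reference(
            ref, [(2 * Y, 20 * Y, 0.60)], 0.0, 20 * Y), params)
        h_star = male_curves.height_ref(20 * Y)
        assert not recover.collapsed and not chronic.collapsed
        assert recover.series["h"][-1] >= 0.98 * h_star
        assert chronic.series["h"][-1] < 0.97 * h_star

    def test_perturbed_height_recovers_with_adequate_feeding(
            self, male_curves, male_subject, params):
        st = gs.reference_state(male_subject, male_curves, 2 * Y, params)
        stunted = gs.BodyState(fm=st.fm, ffm=st.ffm, h=0.9 * st.h, age=st.age)
        scn = gs.Scenario(2 * Y, 19 * Y, None, 1.0, initial_state=stunted)
        res = gs.simulate(male_subject, male_curves, scn, params)
        assert res.series["h"][-1] >= 0.98 * male_curves.height_ref(19 * Y)


class TestCompositionHomeostasis:
    def test_fat_perturbation_decays_to_indicated(self, male_curves, male_subject,
                                                  params):
        """+3 kg FM / -3 kg FFM at constant body weight: the FM/FFM exchange
        restores the composition indicated by the current BMI — the
        architecture's distinguishing homeostatic feature."""
        st = gs.reference_state(male_subject, male_curves, 30 * Y, params)
        # feed the unperturbed maintenance intake throughout: the exchange
        # itself, not an intake adjustment, must restore composition
        ei = gs.equilibrium_intake(st, male_subject, male_curves, params)
        for sign in (+1.0, -1.0):
            pert = gs.BodyState(fm=st.fm + 3.0 * sign, ffm=st.ffm - 3.0 * sign,
                                h=st.h, age=st.age)
            scn = gs.Scenario.constant(ei, pert.age, pert.age + 400,
                                       initial_state=pert)
            res = gs.simulate(male_subject, male_curves, scn, params)
            age_end = res.series["age"][-1]
            fmi_end = res.series["fm"][-1] / res.series["h"][-1] ** 2
            fmi_ind = gs.indicated_fmi(res.series["bmi"][-1],
                                       male_curves.bmi_ref(age_end),
                                       male_curves.fmi_ref(age_end),
                                       male_subject, age_end,
                                       params.composition)
            assert abs(fmi_end - fmi_ind) / fmi_ind < 0.01


class TestEnergyAudit:
    def test_whole_run_first_law(self, adult_feeding_result, male_reference_intake):
        for res in (adult_feeding_result, male_reference_intake.sim):
            lhs, rhs, rel = res.energy_audit()
            assert rel < 1e-6

    def test_series_contract(self, adult_feeding_result):
        res = adult_feeding_result
        n = res.n_steps
        assert len(res.series["age"]) == n + 1
        assert np.all(np.diff(res.series["age"]) > 0)
        df = res.to_dataframe()
        assert len(df) == n + 1


class TestScenario:
    def test_validation(self):
        with pytest.raises(ParameterError):
            gs.Scenario(100.0, 50.0, lambda a: 5.0)
        with pytest.raises(ParameterError):
            gs.Scenario(0.0, 100.0, lambda a: 5.0, dt=-1.0)

    def test_piecewise_schedule(self):
        scn = gs.Scenario.piecewise(10.0, [(5.0, 8.0, 2.0)], 0.0, 20.0)
        assert scn.ei_schedule(4.9) == 10.0
        assert scn.ei_schedule(5.0) == 2.0
        assert scn.ei_schedule(8.0) == 10.0

    def test_reference_intake_interpolates_and_guards(self, male_reference_intake):
        ri = male_reference_intake
        mid = 0.5 * (ri.ages[10] + ri.ages[11])
        lo, hi = sorted((ri.ei[10], ri.ei[11]))
        assert lo <= ri(mid) <= hi
        with pytest.raises(ParameterError):
            ri(25 * Y)
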