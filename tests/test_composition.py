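"""Indicated BMI/FMI equations, the partition fraction and body-energy
accounting, including the exact deposition/catabolism solvers."""

import numpy as np
import pytest

import growthsim as gs
from growthsim import DAYS_PER_YEAR as Y
from growthsim.composition import (CompositionParams, ffm_energy, ffm_energy_delta,
                                   solve_consume, solve_deposit)
from growthsim.errors import CompositionError, ParameterError

NEUTRAL = gs.Subject()
ADULT = 25 * Y


def comp(**kw):
    return CompositionParams(**kw)


class TestIndicatedBmi:
    def test_fixed_point_at_reference(self):
        for lam in (0.0, 0.3, 1.0):
            assert gs.indicated_bmi(22.0, 22.0, NEUTRAL, comp(lambda_bmi=lam)) == 22.0

    def test_degenerate_weights(self):
        assert gs.indicated_bmi(30.0, 22.0, NEUTRAL, comp(lambda_bmi=1.0)) == 30.0
        assert gs.indicated_bmi(30.0, 22.0, NEUTRAL, comp(lambda_bmi=0.0)) == 22.0

    def test_midpoint(self):
        assert gs.indicated_bmi(30.0, 22.0, NEUTRAL, comp(lambda_bmi=0.5)) == pytest.approx(26.0)

    def test_between_inputs_for_neutral_subject(self):
        v = gs.indicated_bmi(28.0, 21.0, NEUTRAL, comp(lambda_bmi=0.4))
        assert 21.0 < v < 28.0


class TestIndicatedFmi:
    def test_anchor_at_reference_bmi(self):
        for race in ("nh_white", "nh_black", "mexican_american"):
            subj = gs.Subject(race=race, fmi_offset=0.4)
            p = comp()
            got = gs.indicated_fmi(22.0, 22.0, 5.0, subj, 10 * Y, p)
            assert got == pytest.approx(5.0 + p.race_terms[race] + 0.4)

    def test_zero_elasticity_constant(self):
        p = comp(gamma=0.0)
        assert gs.indicated_fmi(35.0, 22.0, 5.0, NEUTRAL, ADULT, p) == pytest.approx(
            gs.indicated_fmi(15.0, 22.0, 5.0, NEUTRAL, ADULT, p))

    def test_strictly_increasing_in_bmi(self):
        p = comp()
        vals = [gs.indicated_fmi(b, 22.0, 4.0, NEUTRAL, ADULT, p)
                for b in np.linspace(13, 55, 40)]
        assert np.all(np.diff(vals) > 0)

    def test_fat_cannot_exceed_total(self):
        # absurd anchor forces FMI* >= BMI
        with pytest.raises(CompositionError):
            gs.indicated_fmi(20.0, 22.0, 21.0, gs.Subject(fmi_offset=8.0), ADULT, comp())

    def test_ratio_bounded_over_supported_range(self):
        p = comp()
        for bmi in np.linspace(12, 60, 60):
            f = gs.indicated_fmi(bmi, 22.0, 3.8, NEUTRAL, ADULT, p)
            assert 0.0 < f / bmi < 1.0


class TestPartitionFraction:
    def test_hand_value(self):
        # FMI* = 5 at BMI 22 with gamma 2 -> p_FFM = 1 - 2*5/22
        p = comp(gamma=2.0)
        got = gs.partition_fraction(22.0, 22.0, 5.0, NEUTRAL, ADULT, p)
        assert got == pytest.approx(1 - 2 * 5 / 22, abs=1e-12)

    def test_zero_elasticity_all_ffm(self):
        got = gs.partition_fraction(22.0, 22.0, 5.0, NEUTRAL, ADULT, comp(gamma=0.0))
        assert got == pytest.approx(0.99)  # clipped from 1.0

    @pytest.mark.parametrize("bmi", np.linspace(14.0, 50.0, 8))
    @pytest.mark.parametrize("gamma", [0.8, 1.5, 2.0, 2.7])
    def test_matches_finite_difference_of_indicated_ffm(self, bmi, gamma):
        """p_FFM must equal 1 - dFMI*/dBMI = d(FFM*)/d(BW*) at fixed height,
        measured by central finite difference (the defining derivation)."""
        p = comp(gamma=gamma)
        h = 1.7
        eps = 1e-4

        def ffm_star(b):
            f = gs.indicated_fmi(b, 22.0, 4.0, NEUTRAL, ADULT, p)
            return (b - f) * h * h

        dffm_dbw = (ffm_star(bmi + eps) - ffm_star(bmi - eps)) / (2 * eps * h * h)
        got = gs.partition_fraction(bmi, 22.0, 4.0, NEUTRAL, ADULT, p)
        expected = min(0.99, max(0.01, dffm_dbw))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_decreasing_in_bmi_for_gamma_above_one(self):
        p = comp(gamma=2.0)
        vals = [gs.partition_fraction(b, 22.0, 4.0, NEUTRAL, ADULT, p)
                for b in np.linspace(15, 45, 31)]
        assert np.all(np.diff(vals) < 0)

    def test_clipping_logged(self, caplog):
        import logging
        # near-zero elasticity: derivative ~0, p -> 1, clipped to 0.99
        with caplog.at_level(logging.WARNING, logger="growthsim.composition"):
            got = gs.partition_fraction(22.0, 22.0, 5.0, NEUTRAL, ADULT,
                                        comp(gamma=0.01))
        assert got == pytest.approx(0.99)
        assert any("clipped" in r.getMessage() for r in caplog.records)


class TestSplitIndicated:
    def test_hand_split(self):
        p = comp(gamma=2.0)
        st = gs.split_indicated(22.0, 1.0, 22.0, 5.0, NEUTRAL, ADULT, p)
        assert st.bw_star == pytest.approx(22.0)
        assert st.fm_star == pytest.approx(5.0)
        assert st.ffm_star == pytest.approx(17.0)

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(1)
        p = comp()
        for _ in range(1000):
            bmi = rng.uniform(13, 45)
            h = rng.uniform(0.5, 2.0)
            st = gs.split_indicated(bmi, h, 22.0, 4.0, NEUTRAL, ADULT, p)
            assert abs(st.fm_star + st.ffm_star - st.bw_star) < 1e-12

    def test_height_squared_scaling(self):
        p = comp()
        a = gs.split_indicated(22.0, 0.8, 22.0, 4.0, NEUTRAL, ADULT, p)
        b = gs.split_indicated(22.0, 1.6, 22.0, 4.0, NEUTRAL, ADULT, p)
        assert b.bw_star == pytest.approx(4 * a.bw_star)
        assert b.fm_star == pytest.approx(4 * a.fm_star)
        assert b.ffm_star == pytest.approx(4 * a.ffm_star)


class TestForbes:
    def test_half_at_constant(self):
        assert gs.forbes_partition(70.0, 10.4) == pytest.approx(0.5)

    def test_lean_limit_all_ffm(self):
        assert gs.forbes_partition(60.0, 1e-9) == pytest.approx(1.0, abs=1e-9)

    def test_decreasing_in_fat(self):
        vals = [gs.forbes_partition(90.0, fm) for fm in np.linspace(1, 60, 30)]
        assert np.all(np.diff(vals) < 0)

    def test_domain(self):
        with pytest.raises(ParameterError):
            gs.forbes_partition(50.0, 50.0)


class TestFfmEnergy:
    def test_adult_saturation_value(self):
        assert gs.ffm_energy_density(60.0, comp()) == pytest.approx(5.0)

    def test_continuity_at_saturation(self):
        p = comp()
        fs = p.ffm_saturation
        assert gs.ffm_energy_density(fs - 1e-9, p) == pytest.approx(
            gs.ffm_energy_density(fs + 1e-9, p), abs=1e-6)

    def test_nondecreasing(self):
        p = comp()
        vals = [gs.ffm_energy_density(f, p) for f in np.linspace(0, 80, 400)]
        assert np.all(np.diff(vals) >= 0)

    def test_body_energy_zero_at_zero_mass(self):
        assert gs.body_energy(0.0, 0.0, comp()) == 0.0

    def test_body_energy_saturated_closed_form(self):
        p = comp()
        fs = p.ffm_saturation
        e_ramp = p.rho_ffm_intercept * fs + 0.5 * p.rho_ffm_slope * fs ** 2
        ffm = 70.0
        expected = 10 * p.rho_fm + e_ramp + 5.0 * (ffm - fs)
        assert gs.body_energy(10.0, ffm, p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_each_mass(self):
        p = comp()
        grid = np.linspace(0.1, 80, 50)
        e_fm = [gs.body_energy(m, 30.0, p) for m in grid]
        e_ffm = [gs.body_energy(10.0, m, p) for m in grid]
        assert np.all(np.diff(e_fm) > 0) and np.all(np.diff(e_ffm) > 0)


class TestMassEnergySolvers:
    """The deposition/catabolism solvers must invert the cumulative energy
    curve exactly, including across the saturation breakpoint."""

    @pytest.mark.parametrize("f0", [5.0, 25.0, 39.0, 41.0, 60.0])
    @pytest.mark.parametrize("p_ffm", [0.0, 0.3, 0.85, 1.0])
    def test_deposit_energy_roundtrip(self, f0, p_ffm):
        p = comp()
        eff_ffm, eff_fm, S = 0.85, 0.98, 12.0
        m = solve_deposit(f0, p_ffm, S, eff_ffm, eff_fm, p)
        cost = (ffm_energy_delta(f0, f0 + p_ffm * m, p) / eff_ffm
                + (1 - p_ffm) * m * p.rho_fm / eff_fm)
        assert cost == pytest.approx(S, rel=1e-10)

    @pytest.mark.parametrize("f0", [8.0, 39.5, 41.0, 70.0])
    @pytest.mark.parametrize("p_ffm", [0.0, 0.5, 1.0])
    def test_consume_energy_roundtrip(self, f0, p_ffm):
        p = comp()
        S = 6.0
        m = solve_consume(f0, p_ffm, S, p)
        got = (ffm_energy_delta(f0 - p_ffm * m, f0, p)
               + (1 - p_ffm) * m * p.rho_fm)
        assert got == pytest.approx(S, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            comp(lambda_bmi=1.5)
        with pytest.raises(ParameterError):
            comp(rho_fm=4.0, rho_ffm_adult=5.0)
        with pytest.raises(ParameterError):
            comp(rho_ffm_intercept=-1.0)
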