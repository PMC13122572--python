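"""Nernst/GHK engine: frozen hand-computed values and structural properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gilltep.electrochem import (
    GHKPermeabilitySet,
    PlasmaComposition,
    driving_force_shift,
    ghk_fit_permeability_ratio,
    ghk_voltage,
    nernst_potential,
    nernst_slope,
    partition_gradient,
)
from gilltep.exceptions import (
    DegenerateSolutionError,
    InfeasiblePotentialError,
    InvalidInputError,
    UnsupportedModelError,
)

CONC = st.floats(min_value=1e-3, max_value=1e3)


class TestNernstSlope:
    def test_natural_slope_at_27C(self):
        # 1000 * 8.314 * 300.15 / 96485
        assert nernst_slope(27.0) == pytest.approx(25.8636, abs=5e-4)

    def test_decadic_slope_at_27C(self):
        assert nernst_slope(27.0, "decadic") == pytest.approx(59.553, abs=5e-3)

    def test_strictly_increasing_in_temperature(self):
        assert nernst_slope(33.0) > nernst_slope(27.0) > nernst_slope(21.0)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -300.0])
    def test_invalid_temperature_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            nernst_slope(bad)


class TestNernstPotential:
    def test_gill_na_gradient_at_27C(self):
        # 63 umol/L water vs 158 mmol/L plasma, monovalent cation
        assert nernst_potential(0.063, 158.0, 1, 27.0) == pytest.approx(-202.5, abs=0.1)

    def test_typical_freshwater_gradient_at_27C(self):
        # 1 vs 140 mmol/L: first-principles value, ~128 mV
        assert nernst_potential(1.0, 140.0, 1, 27.0) == pytest.approx(-127.8, abs=0.1)

    @given(c=CONC, t=st.floats(min_value=0.0, max_value=40.0))
    @settings(derandomize=True, max_examples=30)
    def test_equal_concentrations_give_zero(self, c, t):
        assert nernst_potential(c, c, 1, t) == 0.0

    @given(c_out=CONC, c_in=CONC, z=st.sampled_from([-2, -1, 1, 2]))
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetric_under_side_swap(self, c_out, c_in, z):
        forward = nernst_potential(c_out, c_in, z, 27.0)
        backward = nernst_potential(c_in, c_out, z, 27.0)
        assert forward == pytest.approx(-backward, abs=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            nernst_potential(0.0, 1.0, 1, 27.0)
        with pytest.raises(InvalidInputError):
            nernst_potential(1.0, -2.0, 1, 27.0)
        with pytest.raises(InvalidInputError):
            nernst_potential(1.0, 1.0, 0, 27.0)


class TestGradientPartition:
    def test_control_tep_at_27C(self):
        part = partition_gradient(-22.3, 0.063, 158.0, 1, 27.0)
        assert part.driving_force == pytest.approx(180.2, abs=0.1)
        assert part.electrical_fraction == pytest.approx(0.110, abs=0.001)
        assert part.equivalent_internal_concentration == pytest.approx(66.8, abs=0.2)
        assert part.driving_force == part.tep - part.nernst_potential  # exact

    def test_hyperpolarized_tep_at_21C(self):
        part = partition_gradient(-37.8, 0.063, 158.0, 1, 21.0)
        assert part.equivalent_internal_concentration == pytest.approx(35.6, abs=0.2)

    def test_zero_tep_is_the_identity(self):
        part = partition_gradient(0.0, 0.063, 158.0, 1, 27.0)
        assert part.driving_force == -part.nernst_potential
        assert part.electrical_fraction == 0.0
        assert part.equivalent_internal_concentration == pytest.approx(158.0, rel=1e-12)

    @given(c_out=CONC, c_in=CONC)
    @settings(derandomize=True, max_examples=50)
    def test_equivalent_concentration_inverts_nernst_at_zero_tep(self, c_out, c_in):
        """At TEP = 0 the equivalent-concentration transform recovers c_in exactly."""
        part = partition_gradient(0.0, c_out, c_in, 1, 27.0)
        assert part.equivalent_internal_concentration == pytest.approx(c_in, rel=1e-9)

    def test_zero_nernst_with_nonzero_tep_gives_nan_fraction(self):
        part = partition_gradient(-10.0, 5.0, 5.0, 1, 27.0)
        assert math.isnan(part.electrical_fraction)

    def test_percent_reporting(self):
        part = partition_gradient(-22.3, 0.063, 158.0, 1, 27.0)
        assert part.electrical_fraction_percent == pytest.approx(11.0, abs=0.1)
        assert part.electrical_fraction_percent_rounded == 11


class TestDrivingForceShift:
    def test_25mV_hyperpolarization_of_120mV_gradient(self):
        shift = driving_force_shift(120.0, -25.0)
        assert shift.new_driving == pytest.approx(95.0)
        assert shift.percent_reduction == pytest.approx(20.833, abs=1e-3)
        assert shift.percent_reduction_rounded == 21
        assert not shift.sign_reversal

    def test_zero_shift(self):
        shift = driving_force_shift(100.0, 0.0)
        assert shift.new_driving == 100.0
        assert shift.percent_reduction == 0.0

    def test_halving(self):
        shift = driving_force_shift(100.0, -50.0)
        assert (shift.new_driving, shift.percent_reduction) == (50.0, 50.0)

    def test_overshoot_flags_sign_reversal_without_raising(self):
        shift = driving_force_shift(20.0, -30.0)
        assert shift.sign_reversal
        assert shift.new_driving == pytest.approx(-10.0)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(InvalidInputError):
            driving_force_shift(0.0, -5.0)


class TestGHKVoltage:
    def test_reproduces_control_tep(self, plasma_mmol):
        """P_Na/P_Cl = 1.95 over the measured gradients gives the -22.3 mV control TEP."""
        v = ghk_voltage({"Na": 1.95, "Cl": 1.0}, {"Na": 0.063, "Cl": 0.011}, plasma_mmol, 27.0)
        assert v == pytest.approx(-22.3, abs=0.05)

    @given(p_na=st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=30)
    def test_symmetric_solutions_give_exactly_zero(self, p_na):
        """Isotonic-saline abolition: identical solutions -> 0 mV for any permeabilities."""
        sol = {"Na": 140.0, "Cl": 140.0}
        assert ghk_voltage({"Na": p_na, "Cl": 1.0}, sol, sol, 27.0) == 0.0

    @given(c_out=CONC, c_in=CONC, p=st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=60)
    def test_single_permeant_cation_reduces_to_nernst(self, c_out, c_in, p):
        v = ghk_voltage({"Na": p, "Cl": 0.0}, {"Na": c_out}, {"Na": c_in}, 27.0)
        assert abs(v - nernst_potential(c_out, c_in, 1, 27.0)) < 1e-9

    @given(c_out=CONC, c_in=CONC)
    @settings(derandomize=True, max_examples=30)
    def test_single_permeant_anion_reduces_to_nernst(self, c_out, c_in):
        v = ghk_voltage({"Cl": 1.0}, {"Cl": c_out}, {"Cl": c_in}, 27.0)
        assert abs(v - nernst_potential(c_out, c_in, -1, 27.0)) < 1e-9

    def test_strictly_increasing_in_external_na(self, plasma_mmol):
        """Raising water NaCl depolarizes the potential when P_Na/P_Cl > 1."""
        perm = {"Na": 1.95, "Cl": 1.0}
        voltages = [
            ghk_voltage(perm, {"Na": na, "Cl": na - 0.052}, plasma_mmol, 27.0)
            for na in (0.063, 0.25, 2.5, 140.0)
        ]
        assert voltages == sorted(voltages)

    def test_divalent_permeability_is_unsupported(self, plasma_mmol):
        with pytest.raises(UnsupportedModelError):
            ghk_voltage({"Ca": 0.5, "Cl": 1.0}, {"Ca": 5.0, "Cl": 11.0}, plasma_mmol, 27.0)

    def test_all_zero_concentrations_rejected(self):
        with pytest.raises(InvalidInputError):
            ghk_voltage({"Na": 1.0, "Cl": 0.0}, {"Na": 0.0}, {"K": 3.0}, 27.0)

    def test_accepts_typed_compositions(self, inpa_water, plasma_mmol):
        """WaterComposition (umol/L) and PlasmaComposition (mmol/L) interoperate."""
        plasma = PlasmaComposition({"Na": 158.0, "Cl": 130.0})
        v_typed = ghk_voltage(
            GHKPermeabilitySet({"Na": 1.95, "Cl": 1.0}), inpa_water, plasma, 27.0
        )
        v_plain = ghk_voltage({"Na": 1.95, "Cl": 1.0}, {"Na": 0.063, "Cl": 0.011}, plasma_mmol, 27.0)
        assert v_typed == pytest.approx(v_plain, abs=1e-12)


class TestGHKFit:
    def test_recovers_permeability_ratio_from_control_tep(self, plasma_mmol):
        water = {"Na": 0.063, "Cl": 0.011}
        ratio = ghk_fit_permeability_ratio(-22.3, water, plasma_mmol, 27.0)
        assert ratio == pytest.approx(1.95, abs=0.01)
        # and the forward model reproduces the fitted TEP to numerical precision
        v = ghk_voltage({"Na": ratio, "Cl": 1.0}, water, plasma_mmol, 27.0)
        assert abs(v - (-22.3)) < 1e-9

    def test_symmetric_solutions_are_degenerate(self):
        sol = {"Na": 140.0, "Cl": 140.0}
        with pytest.raises(DegenerateSolutionError):
            ghk_fit_permeability_ratio(0.0, sol, sol, 27.0)

    def test_infeasible_tep_raises_with_value_in_message(self, plasma_mmol):
        # Feasible potentials lie strictly between the Na and Cl Nernst
        # potentials (~-202 and ~+243 mV here); -300 mV is unreachable.
        water = {"Na": 0.063, "Cl": 0.011}
        with pytest.raises(InfeasiblePotentialError, match="-300"):
            ghk_fit_permeability_ratio(-300.0, water, plasma_mmol, 27.0)

    @given(
        p_na=st.floats(min_value=0.05, max_value=20.0),
        na_out=CONC, cl_out=CONC, na_in=CONC, cl_in=CONC,
        t=st.floats(min_value=5.0, max_value=40.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_fit_inverts_forward_model(self, p_na, na_out, cl_out, na_in, cl_in, t):
        """ghk_fit o ghk_voltage is the identity on feasible ratios (<= 1e-9 mV)."""
        water = {"Na": na_out, "Cl": cl_out}
        plasma = {"Na": na_in, "Cl": cl_in}
        v = ghk_voltage({"Na": p_na, "Cl": 1.0}, water, plasma, t)
        try:
            ratio = ghk_fit_permeability_ratio(v, water, plasma, t)
        except DegenerateSolutionError:
            return  # symmetric draw
        v_back = ghk_voltage({"Na": ratio, "Cl": 1.0}, water, plasma, t)
        assert abs(v_back - v) < 1e-9
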