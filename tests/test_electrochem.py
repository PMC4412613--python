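"""Electrochemistry: ionic strength, activities, Nernst/GHK, junction potentials."""

import math

import numpy as np
import pytest

from vactrace.electrochem import (
    FARADAY,
    GAS_CONSTANT,
    activity_coefficient,
    fit_permeability_ratio,
    ghk_reversal_potential,
    henderson_junction_potential,
    ion_activity,
    ionic_strength,
    nernst_potential,
)
from vactrace.errors import (
    ConfigurationError,
    InvalidInputError,
    NoSolutionError,
    UndefinedPotentialError,
)
from vactrace.solutions import IonSpecies, SolutionSpec, simple_salt_solution

from conftest import random_anion_pair


def _solution(*species, pH=7.0):
    return SolutionSpec(species=species, pH=pH)


class TestIonicStrength:
    def test_pure_water_is_zero(self):
        assert ionic_strength(_solution()) == 0.0

    def test_mixed_salt_hand_sum(self):
        # 200 NaNO3 + 2 CaCl2 + 2 MgCl2, fully dissociated:
        # I = 1/2 (0.2 + 0.2 + 4*0.002 + 4*0.002 + 0.008) = 0.212 M
        sol = _solution(
            IonSpecies("Na", +1, 200), IonSpecies("NO3", -1, 200),
            IonSpecies("Ca", +2, 2), IonSpecies("Mg", +2, 2),
            IonSpecies("Cl", -1, 8),
        )
        assert ionic_strength(sol) == pytest.approx(0.212, abs=1e-12)

    def test_one_to_one_salt_equals_concentration(self):
        sol = simple_salt_solution("KCl", "K", "Cl", 100.0)
        assert ionic_strength(sol) == pytest.approx(0.100, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            IonSpecies("Cl", -1, -5.0)


class TestActivityCoefficient:
    def test_infinite_dilution_gamma_is_one(self):
        for model in ("limiting", "guntelberg", "davies", "ideal"):
            assert activity_coefficient(1, 0.0, model=model) == pytest.approx(1.0)

    def test_davies_monovalent_value(self):
        # direct evaluation of the Davies closed form at I = 0.1 M, 295 K
        gamma = activity_coefficient(1, 0.1, 295.0, model="davies")
        assert gamma == pytest.approx(0.78, abs=0.01)

    def test_z_squared_scaling(self):
        g1 = activity_coefficient(1, 0.1, 295.0, model="davies")
        g2 = activity_coefficient(2, 0.1, 295.0, model="davies")
        assert g2 == pytest.approx(g1**4, rel=1e-12)

    @pytest.mark.parametrize("model", ["limiting", "guntelberg"])
    def test_monotone_decreasing_in_ionic_strength(self, model):
        grid = np.linspace(0.0, 0.5, 200)
        gammas = [activity_coefficient(1, i, model=model) for i in grid]
        assert all(a > b for a, b in zip(gammas, gammas[1:]))
        assert all(0 < g <= 1 for g in gammas)

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            activity_coefficient(1, 0.8)


class TestNernst:
    def test_symmetric_solutions_give_zero(self):
        sol = _solution(IonSpecies("NO3", -1, 200), IonSpecies("BTP", +1, 160))
        assert nernst_potential("NO3", sol, sol) == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_nitrate_gradient_with_activities(self, nitrate_gradient):
        cyt, vac = nitrate_gradient
        assert nernst_potential("NO3", cyt, vac) == pytest.approx(-51.6, abs=3.0)

    def test_tenfold_gradient_ideal_closed_form(self, nitrate_gradient):
        # with unit activity coefficients: E = -(RT/F) ln 10 at 295.15 K
        cyt, vac = nitrate_gradient
        expected = -1000.0 * GAS_CONSTANT * 295.15 / FARADAY * math.log(10.0)
        assert nernst_potential("NO3", cyt, vac, model="ideal") == pytest.approx(
            expected, abs=1e-9)
        assert expected == pytest.approx(-58.6, abs=0.1)

    def test_antisymmetric_under_side_swap(self, rng):
        for _ in range(20):
            cyt, vac = random_anion_pair(rng)
            e1 = nernst_potential("NO3", cyt, vac)
            e2 = nernst_potential("NO3", vac, cyt)
            assert e1 == pytest.approx(-e2, abs=1e-12)

    def test_zero_concentration_errors(self):
        a = _solution(IonSpecies("NO3", -1, 200))
        b = _solution(IonSpecies("Cl", -1, 200))
        with pytest.raises(UndefinedPotentialError):
            nernst_potential("NO3", a, b)


class TestGHK:
    def test_single_permeant_symmetric_is_zero(self):
        sol = _solution(IonSpecies("NO3", -1, 200))
        assert ghk_reversal_potential([("NO3", 1.0)], sol, sol) == pytest.approx(0.0)

    def test_reduces_to_nernst_for_one_species(self, rng):
        for _ in range(100):
            cyt, vac = random_anion_pair(rng)
            e_ghk = ghk_reversal_potential([("NO3", 2.7)], cyt, vac)
            e_nernst = nernst_potential("NO3", cyt, vac)
            assert abs(e_ghk - e_nernst) < 1e-9

    def test_printed_ratio_reproduces_reversal(self, selectivity_pair):
        cyt, vac = selectivity_pair
        e = ghk_reversal_potential([("NO3", 3.08), ("Cl", 1.0)], cyt, vac)
        assert e == pytest.approx(26.6, abs=1.0)

    def test_all_zero_permeabilities_error(self, selectivity_pair):
        cyt, vac = selectivity_pair
        with pytest.raises(InvalidInputError):
            ghk_reversal_potential([("NO3", 0.0), ("Cl", 0.0)], cyt, vac)

    def test_divalent_rejected(self):
        sol = _solution(IonSpecies("Ca", +2, 2), IonSpecies("Cl", -1, 4))
        with pytest.raises(InvalidInputError):
            ghk_reversal_potential([("Ca", 1.0)], sol, sol)


class TestPermeabilityRatioFit:
    def test_measured_reversal_gives_printed_ratio(self, selectivity_pair):
        cyt, vac = selectivity_pair
        res = fit_permeability_ratio(26.6, "NO3", "Cl", cyt, vac)
        assert res.permeability_ratio == pytest.approx(3.08, abs=0.15)

    def test_unit_activities_algebraic_inversion(self, selectivity_pair):
        # closed-form two-anion GHK inversion with concentrations only:
        # r = (exp(E F / RT) * c_Cl,vac - c_Cl,cyt) / c_NO3,cyt
        cyt, vac = selectivity_pair
        vt = 1000.0 * GAS_CONSTANT * cyt.temperature_K / FARADAY
        expected = (math.exp(26.6 / vt) * vac.concentration_mM("Cl")
                    - cyt.concentration_mM("Cl")) / cyt.concentration_mM("NO3")
        res = fit_permeability_ratio(26.6, "NO3", "Cl", cyt, vac, model="ideal")
        assert res.permeability_ratio == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(2.9, abs=0.05)

    def test_mirror_symmetric_compositions_give_unity(self):
        # anion compositions swapped between the two sides: only r = 1
        # makes the GHK reversal vanish
        a = _solution(IonSpecies("NO3", -1, 150), IonSpecies("Cl", -1, 50))
        b = _solution(IonSpecies("NO3", -1, 50), IonSpecies("Cl", -1, 150))
        res = fit_permeability_ratio(0.0, "NO3", "Cl", a, b)
        assert res.permeability_ratio == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("r_true", [0.1, 1.0, 3.08, 10.0])
    def test_round_trip_through_ghk(self, r_true, selectivity_pair):
        cyt, vac = selectivity_pair
        e = ghk_reversal_potential([("NO3", r_true), ("Cl", 1.0)], cyt, vac)
        res = fit_permeability_ratio(e, "NO3", "Cl", cyt, vac)
        assert res.permeability_ratio == pytest.approx(r_true, rel=1e-4)

    def test_unreachable_reversal_errors(self, selectivity_pair):
        cyt, vac = selectivity_pair
        with pytest.raises(NoSolutionError):
            fit_permeability_ratio(500.0, "NO3", "Cl", cyt, vac)


class TestHendersonJunction:
    def test_identical_solutions_zero(self):
        sol = simple_salt_solution("KCl", "K", "Cl", 100.0)
        assert henderson_junction_potential(sol, sol) == 0.0

    def test_kcl_dilution_junction_is_small(self):
        # K+ and Cl- mobilities nearly match, so a tenfold KCl junction
        # produces under 2 mV
        a = simple_salt_solution("KCl100", "K", "Cl", 100.0)
        b = simple_salt_solution("KCl10", "K", "Cl", 10.0)
        assert abs(henderson_junction_potential(a, b)) < 2.0

    def test_hcl_dilution_sign_and_magnitude(self):
        # H+ is ~4.6x more mobile than Cl-: the dilute side goes positive
        a = SolutionSpec((IonSpecies("H", +1, 100), IonSpecies("Cl", -1, 100)), pH=4)
        b = SolutionSpec((IonSpecies("H", +1, 10), IonSpecies("Cl", -1, 10)), pH=5)
        e = henderson_junction_potential(a, b)
        assert 20.0 < e < 45.0

    def test_exact_antisymmetry(self, nitrate_gradient):
        cyt, vac = nitrate_gradient
        assert henderson_junction_potential(cyt, vac) == -henderson_junction_potential(vac, cyt)

    def test_missing_mobility_names_species(self):
        sol = _solution(IonSpecies("EGTA", -2, 2), IonSpecies("BTP", +1, 4))
        other = simple_salt_solution("KCl", "K", "Cl", 100.0)
        with pytest.raises(ConfigurationError, match="EGTA"):
            henderson_junction_potential(sol, other)


def test_ion_activity_requires_presence():
    sol = _solution(IonSpecies("NO3", -1, 200))
    with pytest.raises(UndefinedPotentialError):
        ion_activity(sol, "Cl")
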