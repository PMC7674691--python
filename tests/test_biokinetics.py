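"""Model parameters, scenario rules and compartment-system assembly."""

import dataclasses
import math

import numpy as np
import pytest

import thyret as th
from thyret.biokinetics import (
    CompartmentSystem,
    HATMParameters,
    IntakeScenario,
    RadionuclideSpec,
    Route,
    build_system,
    reference_parameters,
    sampled_parameters,
)
from thyret.errors import InvalidParameterError, InvalidScenarioError


class TestScenario:
    def test_route_absorption_pairings(self):
        assert IntakeScenario.from_route("aerosol-5um").absorption_type == "F"
        assert IntakeScenario.from_route("vapor-organic").absorption_type == "V"
        assert IntakeScenario.from_route("ingestion").absorption_type is None
        with pytest.raises(InvalidScenarioError):
            IntakeScenario(route=Route.VAPOR_ORGANIC, absorption_type="F")
        with pytest.raises(InvalidScenarioError):
            IntakeScenario.from_route("injection")


class TestReferenceParameters:
    def test_ingestion_uses_central_transit_rates_and_full_absorption(self):
        _, hatm, _ = reference_parameters("ingestion")
        assert hatm.f1 == 1.0
        assert hatm.rates_per_d["stomach_to_si"] == pytest.approx(20.57)
        assert hatm.rates_per_d["si_to_rc"] == pytest.approx(6.0)

    def test_organic_vapor_deposits_70_percent(self):
        hrtm, _, _ = reference_parameters("vapor-organic")
        assert hrtm.total_deposition == pytest.approx(0.70)

    def test_aerosol_5um_et1_central_deposition(self):
        hrtm, _, _ = reference_parameters("aerosol-5um")
        assert hrtm.deposition["ET1"] == pytest.approx(0.33)

    def test_systemic_reference_is_icrp_defaults(self):
        _, _, systemic = reference_parameters("ingestion")
        assert systemic.f_blt == pytest.approx(0.3)
        assert systemic.k_t_d == pytest.approx(80.0)
        assert systemic.k_bl_d == pytest.approx(0.25)


class TestSampledParameters:
    def test_sampled_uptake_fraction_gm(self):
        triples = sampled_parameters("ingestion", 1000, seed=2)
        fblt = np.array([s.f_blt for _, _, s in triples])
        gm = math.exp(np.log(fblt).mean())
        assert gm == pytest.approx(0.267, rel=0.03)

    def test_aerosol_deposition_totals_never_exceed_one(self):
        triples = sampled_parameters("aerosol-5um", 1000, seed=4)
        totals = np.array([sum(h.deposition.values()) for h, _, _ in triples])
        assert np.all(totals <= 1.0)
        assert np.all(totals > 0.0)

    def test_vapor_regional_fractions_renormalized(self):
        triples = sampled_parameters("vapor-elemental", 200, seed=6)
        for hrtm, _, _ in triples:
            assert sum(hrtm.deposition.values()) == pytest.approx(hrtm.total_deposition)
            assert hrtm.total_deposition == pytest.approx(1.0)
            assert hrtm.deposition["AI"] == 0.0

    def test_deterministic_from_seed(self):
        a = sampled_parameters("ingestion", 20, seed=9)
        b = sampled_parameters("ingestion", 20, seed=9)
        assert a == b

    def test_uptake_fraction_always_below_one(self):
        triples = sampled_parameters("ingestion", 2000, seed=11)
        assert max(s.f_blt for _, _, s in triples) < 1.0


class TestBuildSystem:
    def test_column_sums_balance_diagonal(self, ingestion_reference_system):
        A = ingestion_reference_system.matrix
        lam = ingestion_reference_system.decay_const_per_d
        np.testing.assert_allclose(A.sum(axis=0), -lam, atol=1e-12)

    def test_organic_vapor_initial_condition(self):
        params = reference_parameters("vapor-organic")
        system = build_system("vapor-organic", params)
        q0 = system.initial
        assert q0[system.index("blood")] == pytest.approx(0.7)
        assert q0[system.index("exhaled")] == pytest.approx(0.3)

    def test_si_absorption_rate_identity(self):
        hrtm, hatm, systemic = reference_parameters("ingestion")
        hatm = dataclasses.replace(hatm, f1=0.5)
        system = build_system("ingestion", (hrtm, hatm, systemic))
        rate = system.matrix[system.index("blood"), system.index("SI")]
        # f1 * lambda_SI / (1 - f1) with lambda_SI = 6/d
        assert rate == pytest.approx(6.0)

    @pytest.mark.parametrize("f1", [0.3, 0.8, 0.97])
    def test_fraction_reaching_blood_equals_f1(self, f1):
        """Long-time integration with decay off and blood made absorbing."""
        hrtm, hatm, systemic = reference_parameters("ingestion")
        hatm = dataclasses.replace(hatm, f1=f1)
        stable = RadionuclideSpec(name="stable", half_life_d=math.inf)
        system = build_system("ingestion", (hrtm, hatm, systemic), stable)
        A = system.matrix.copy()
        blood = system.index("blood")
        A[:, blood] = 0.0  # blood becomes a sink
        trapped = CompartmentSystem(
            names=system.names, matrix=A, initial=system.initial,
            decay_const_per_d=0.0, scenario=system.scenario,
        )
        q = th.solve_activities(trapped, np.array([500.0]))
        assert q[blood, 0] == pytest.approx(f1, abs=1e-6)

    def test_mass_balance_all_routes(self):
        for route in Route:
            system = build_system(route, reference_parameters(route))
            for t in (0.1, 1.0, 10.0, 100.0):
                assert th.activity_balance(system, t) < 1e-8

    def test_slow_fraction_insensitive_under_fast_absorption(self):
        """With s_p = 100/d, dissolution dwarfs the BB/bb fast/slow split."""
        hrtm, hatm, systemic = reference_parameters("aerosol-5um")
        values = []
        for f_s in (0.1, 0.9):
            h = dataclasses.replace(hrtm, slow_fraction=f_s)
            system = build_system("aerosol-5um", (h, hatm, systemic))
            values.append(th.thyroid_retention(system, np.array([24.0])).values[0])
        assert abs(values[1] / values[0] - 1.0) < 0.01

    def test_zero_uptake_fraction_keeps_thyroid_empty(self):
        hrtm, hatm, systemic = reference_parameters("ingestion")
        systemic = dataclasses.replace(systemic, f_blt=1e-300)
        system = build_system("ingestion", (hrtm, hatm, systemic))
        curve = th.thyroid_retention(system, np.arange(1.0, 200.0, 5.0))
        assert np.all(curve.values < 1e-250)

    def test_invalid_parameters_rejected(self):
        hrtm, hatm, systemic = reference_parameters("ingestion")
        bad = dataclasses.replace(systemic, k_t_d=-1.0)
        with pytest.raises(InvalidParameterError):
            build_system("ingestion", (hrtm, hatm, bad))
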