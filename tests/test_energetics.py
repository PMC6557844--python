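import math

import numpy as np
import pytest

from endoepi.energetics import (
    EnergeticsParams,
    actin_bond_energy_density,
    breech_energy_per_cycle,
    case1_strain,
    case2_strain,
    deformation_energy_density,
    elongation_to_inverse_circularity,
    factin_fraction,
    monomer_binding_free_energy,
    neo_hookean_uniaxial,
    total_energy_profile,
)
from endoepi.geometry import aspect_from_circularity


class TestParams:
    def test_shear_modulus_incompressible(self, params):
        assert params.G == pytest.approx(params.E / 3.0)

    def test_gamma_derived_from_benchmark(self, params):
        # slope anchored so f_act = 0.8 at circularity 0.7
        assert params.gamma == pytest.approx(0.496, abs=2e-3)

    def test_from_config_micromolar_conversion(self):
        p = EnergeticsParams.from_config({"C_act_uM": 50})
        assert p.C_act == pytest.approx(0.05)

    def test_from_config_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            EnergeticsParams.from_config({"elastic": 1.0})

    @pytest.mark.parametrize(
        "kwargs", [{"E": -1.0}, {"eta_act": 0.0}, {"eta_br": 1.5}, {"T": 0.0},
                   {"prefactor_mode": "verbatim"}, {"log_base": "2"}]
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            EnergeticsParams(**kwargs)


class TestStrains:
    def test_case1_published_dimensions(self):
        """(d/2)/l with d = 10.62 um, l = 30.97 um gives 0.1715 to 4 s.f."""
        assert round(case1_strain(10.62, 30.97), 4) == 0.1715

    def test_case1_arithmetic(self):
        assert case1_strain(10.0, 100.0) == pytest.approx(0.05)
        assert case1_strain(1e-9, 30.97) == pytest.approx(0.0, abs=1e-10)

    def test_case1_rejects_full_compression(self):
        with pytest.raises(ValueError, match="fully compressed"):
            case1_strain(80.0, 30.0)
        with pytest.raises(ValueError):
            case1_strain(-1.0, 30.0)

    def test_case2_recovers_case1_for_sphere(self):
        assert case2_strain(0.1715, 1.0) == pytest.approx(0.1715)

    def test_case2_scaling(self):
        x = aspect_from_circularity(1.0 / 1.68)
        eps1 = case1_strain(10.62, 30.97)
        assert case2_strain(eps1, x) == pytest.approx(0.11303, abs=1e-4)

    def test_case2_vanishes_for_extreme_elongation(self):
        assert case2_strain(0.1715, 1e6) < 1e-6

    def test_case2_never_exceeds_case1(self):
        for x in np.linspace(1.0, 10.0, 20):
            assert case2_strain(0.1715, x) <= 0.1715


class TestNeoHookean:
    def test_undeformed_is_zero(self):
        assert neo_hookean_uniaxial(1.0, 3333.33) == 0.0

    def test_value(self):
        assert neo_hookean_uniaxial(1.1715, 10_000 / 3.0) == pytest.approx(132.7, abs=0.2)

    def test_two_algebraic_forms_agree(self):
        G = 3333.3333
        for lam in np.linspace(0.2, 3.0, 50):
            direct = neo_hookean_uniaxial(lam, G)
            factored = (G / (2 * lam)) * (lam - 1) ** 2 * (lam + 2)
            assert direct == pytest.approx(factored, rel=1e-12, abs=1e-12)

    def test_strain_form_identity(self):
        """eps^2*(eps+3)/(eps+1) equals lam^2 + 2/lam - 3 at lam = 1 + eps."""
        for eps in np.linspace(0.0, 0.9, 40):
            lam = 1.0 + eps
            lhs = eps**2 * (eps + 3) / (eps + 1)
            rhs = lam**2 + 2 / lam - 3
            assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            neo_hookean_uniaxial(0.0, 1.0)


class TestBreechEnergy:
    def test_zero_strain_costs_nothing(self, params):
        assert breech_energy_per_cycle(0.0, params) == 0.0

    def test_round_cell_cycle_cost(self, params):
        """Undeformed cell: ~530 Pa for the full intravasation+extravasation cycle."""
        eps = case1_strain(params.d_epi, params.l_endo)
        assert breech_energy_per_cycle(eps, params) == pytest.approx(530.9, rel=5e-3)

    def test_elongated_cell_cycle_cost(self, params):
        eps = case2_strain(case1_strain(10.62, 30.97), aspect_from_circularity(1 / 1.68))
        assert breech_energy_per_cycle(eps, params) == pytest.approx(238.2, rel=5e-3)

    def test_strictly_increasing_in_strain(self, params):
        eps = np.linspace(0.0, 0.95, 100)
        w = breech_energy_per_cycle(eps, params)
        assert np.all(np.diff(w) > 0)

    def test_linear_in_modulus(self, params):
        doubled = params.replace(E=2 * params.E)
        for eps in (0.05, 0.1715, 0.5):
            assert breech_energy_per_cycle(eps, doubled) == pytest.approx(
                2 * breech_energy_per_cycle(eps, params)
            )

    def test_as_written_half_efficiency_matches_as_printed(self, params):
        """The verbatim prefactor E/(6*eta_br) coincides with the printed
        numbers exactly when eta_br = 0.5."""
        written = params.replace(prefactor_mode="as_written", eta_br=0.5)
        for eps in (0.05, 0.1715, 0.4):
            assert breech_energy_per_cycle(eps, written) == pytest.approx(
                breech_energy_per_cycle(eps, params), rel=1e-12
            )

    def test_as_written_default_efficiency_scales(self, params):
        """With eta_br = 0.15 the verbatim form is (0.5/0.15)x the printed one."""
        written = params.replace(prefactor_mode="as_written")
        assert breech_energy_per_cycle(0.1715, written) == pytest.approx(
            (0.5 / 0.15) * breech_energy_per_cycle(0.1715, params), rel=1e-12
        )

    def test_rejects_out_of_range_strain(self, params):
        with pytest.raises(ValueError):
            breech_energy_per_cycle(1.0, params)
        with pytest.raises(ValueError):
            breech_energy_per_cycle(-0.1, params)


class TestActinEnergetics:
    def test_binding_free_energy_value(self, params):
        # k_B * 310 * ln(11.6 * 10 / 1)
        assert monomer_binding_free_energy(params) == pytest.approx(2.035e-20, rel=1e-3)

    def test_binding_energy_zero_at_unit_ratio(self):
        p = EnergeticsParams(k_on=1.0, M=1.0, k_off=1.0)
        with pytest.warns(UserWarning, match="outside the model scope"):
            assert monomer_binding_free_energy(p) == 0.0

    def test_binding_energy_linear_in_temperature(self, params):
        hot = params.replace(T=2 * params.T)
        assert monomer_binding_free_energy(hot) == pytest.approx(
            2 * monomer_binding_free_energy(params)
        )

    def test_log10_option(self, params):
        p10 = params.replace(log_base="10")
        assert monomer_binding_free_energy(p10) == pytest.approx(
            monomer_binding_free_energy(params) / math.log(10), rel=1e-12
        )

    def test_factin_at_rest(self, params):
        assert factin_fraction(1.0, params) == 1.0

    def test_factin_benchmark_anchor(self, params):
        x = aspect_from_circularity(0.7)
        assert factin_fraction(x, params) == pytest.approx(0.8, abs=1e-9)

    def test_factin_clipped_at_zero(self, params):
        assert factin_fraction(1.0 + 1.0 / params.gamma + 1.0, params) == 0.0

    def test_bond_energy_density_values(self, params):
        assert actin_bond_energy_density(1.0, params) == 0.0
        assert actin_bond_energy_density(0.8, params) == pytest.approx(122.5, rel=1e-3)
        assert actin_bond_energy_density(0.6, params) == pytest.approx(
            2 * actin_bond_energy_density(0.8, params)
        )

    def test_deformation_cost(self, params):
        assert deformation_energy_density(122.5, 1.0) == 0.0
        assert deformation_energy_density(122.5, 0.15) == pytest.approx(694.4, abs=0.5)
        assert deformation_energy_density(0.0, 0.15) == 0.0
        with pytest.raises(ValueError):
            deformation_energy_density(1.0, 0.0)


class TestEnergyProfile:
    def test_round_cell_point(self, params):
        prof = total_energy_profile([1.0], params)
        assert prof.W_br_total[0] == pytest.approx(530.9, rel=5e-3)
        assert prof.W_def[0] == 0.0
        assert prof.W_total[0] == prof.W_br_total[0]

    def test_median_metastatic_point(self, params):
        prof = total_energy_profile([1.68], params)
        assert prof.W_br_total[0] == pytest.approx(238.2, rel=5e-3)

    def test_energy_saving_fraction(self, params):
        prof = total_energy_profile([1.0, 1.68], params)
        saving = 1.0 - prof.W_br_total[1] / prof.W_br_total[0]
        assert saving == pytest.approx(0.551, abs=0.005)

    def test_breech_energy_strictly_decreasing(self, params):
        grid = np.linspace(1.0, 10.0, 200)
        prof = total_energy_profile(grid, params)
        assert np.all(np.diff(prof.W_br_total) < 0)

    def test_total_is_componentwise_sum(self, params):
        grid = np.linspace(1.0, 5.0, 30)
        prof = total_energy_profile(grid, params)
        np.testing.assert_allclose(prof.W_total, prof.W_br_total + prof.W_def)
        assert np.all(prof.W_br_total >= 0) and np.all(prof.W_def >= 0)

    def test_rejects_bad_grids(self, params):
        with pytest.raises(ValueError):
            total_energy_profile([2.0, 1.5], params)
        with pytest.raises(ValueError):
            total_energy_profile([0.5, 1.5], params)
        with pytest.raises(ValueError):
            total_energy_profile([], params)

    def test_dataframe_columns(self, params):
        df = total_energy_profile([1.0, 2.0], params).to_dataframe()
        assert list(df.columns) == [
            "inverse_circularity", "W_br_total_Pa", "W_def_Pa", "W_total_Pa",
        ]


class TestElongationMapping:
    def test_identity_at_zero(self):
        assert elongation_to_inverse_circularity(0.0, 1.0) == 1.0

    def test_median_consistency(self):
        """Median elongation 0.66 over a baseline of ~1.012 lands on C^-1 = 1.68."""
        assert elongation_to_inverse_circularity(0.66, 1.012) == pytest.approx(1.68, abs=0.01)

    def test_clamped_at_physical_floor(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="endoepi.energetics"):
            assert elongation_to_inverse_circularity(-0.05, 1.0) == 1.0
        assert "clamped" in caplog.text

    def test_rejects_invalid_baseline(self):
        with pytest.raises(ValueError):
            elongation_to_inverse_circularity(0.1, 0.9)
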