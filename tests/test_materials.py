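"""Constitutive laws: closed-form examples, oracles and invariants."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from blasthead.materials import (
    EOSDomainError,
    IdealGasAir,
    JWLProducts,
    LinearElastic,
    ShockEOS,
    ViscoelasticBrain,
    brain_relaxation_modulus,
    ideal_gas_pressure,
    jwl_pressure,
    load_materials,
    shock_eos_pressure,
)


def hugoniot_oracle(rho0, c0, s, rho):
    """Independent root-find of the shock jump relations.

    Solves mass conservation rho0*Us = rho*(Us - Up) with the linear
    Hugoniot Us = c0 + s*Up for the particle velocity, then evaluates
    the momentum jump P = rho0*Us*Up.
    """

    def mass_residual(up):
        us = c0 + s * up
        return rho0 * us - rho * (us - up)

    up = brentq(mass_residual, 0.0, 1.0e5, xtol=1e-12, rtol=8.9e-16)
    us = c0 + s * up
    return rho0 * us * up


class TestShockEOS:
    skull = ShockEOS(1412.0, 1850.0, 0.94, shear_modulus=2.664e9, name="skull")
    csf = ShockEOS(998.0, 1647.0, 1.921, shear_modulus=500.0, name="csf")

    def test_reference_state_is_stress_free(self):
        assert shock_eos_pressure(self.skull, self.skull.ref_density) == 0.0

    def test_matches_jump_relation_root_find(self):
        mu = 0.05
        rho = self.skull.ref_density * (1.0 + mu)
        expected = hugoniot_oracle(1412.0, 1850.0, 0.94, rho)
        assert shock_eos_pressure(self.skull, rho) == pytest.approx(expected, rel=1e-10)

    def test_acoustic_limit(self):
        mu = 1e-6
        p = shock_eos_pressure(self.csf, self.csf.ref_density * (1.0 + mu))
        assert p == pytest.approx(self.csf.bulk_modulus * mu, rel=1e-3)

    def test_differentiable_at_zero_with_bulk_modulus_slope(self):
        eps = 1e-8
        rho0 = self.csf.ref_density
        p_plus = shock_eos_pressure(self.csf, rho0 * (1.0 + eps))
        p_minus = shock_eos_pressure(self.csf, rho0 * (1.0 - eps))
        slope = (p_plus - p_minus) / (2.0 * eps)
        assert slope == pytest.approx(self.csf.bulk_modulus, rel=1e-5)

    def test_tension_is_linear(self):
        mu = -0.01
        p = shock_eos_pressure(self.skull, self.skull.ref_density * (1.0 + mu))
        assert p == pytest.approx(self.skull.bulk_modulus * mu, rel=1e-12)

    def test_pole_raises_named_error(self):
        rho_pole = self.csf.ref_density * (1.0 + 1.0 / (1.921 - 1.0))
        with pytest.raises(EOSDomainError, match="csf"):
            shock_eos_pressure(self.csf, rho_pole * 1.01)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(EOSDomainError):
            shock_eos_pressure(self.skull, 0.0)


class TestBrainRelaxation:
    brain = ViscoelasticBrain(2.19e9, 1040.0, 41.0e3, 7.8e3, 700.0)

    def test_short_and_long_term_moduli(self):
        assert brain_relaxation_modulus(self.brain, 0.0) == pytest.approx(41.0e3)
        assert brain_relaxation_modulus(self.brain, 10.0) == pytest.approx(7.8e3, rel=1e-9)

    def test_one_decay_time(self):
        expected = 7.8e3 + 33.2e3 * math.exp(-1.0)
        assert brain_relaxation_modulus(self.brain, 1.0 / 700.0) == pytest.approx(expected)

    def test_strictly_decreasing_within_bounds(self):
        t = np.linspace(0.0, 0.02, 400)
        g = brain_relaxation_modulus(self.brain, t)
        assert np.all(np.diff(g) < 0)
        assert np.all(g <= 41.0e3) and np.all(g >= 7.8e3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            brain_relaxation_modulus(self.brain, -1e-6)

    def test_modulus_ordering_enforced(self):
        with pytest.raises(ValueError):
            ViscoelasticBrain(2.19e9, 1040.0, 7.8e3, 41.0e3, 700.0)


class TestJWL:
    tnt = JWLProducts(371.2e9, 3.231e9, 4.15, 0.95, 0.30, 1630.0, 4.29e6)

    def test_three_term_sum_independent_evaluation(self):
        v, E = 1.0, 1630.0 * 4.29e6
        expected = (
            371.2e9 * (1.0 - 0.30 / 4.15) * math.exp(-4.15)
            + 3.231e9 * (1.0 - 0.30 / 0.95) * math.exp(-0.95)
            + 0.30 * E
        )
        assert jwl_pressure(self.tnt, v, E) == pytest.approx(expected, rel=1e-12)

    def test_large_volume_gas_limit(self):
        v = 25.0  # R2*v ~ 24 >> 1: exponential terms negligible
        E = 1.0e8
        assert jwl_pressure(self.tnt, v, E) == pytest.approx(0.30 * E / v, rel=1e-2)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(EOSDomainError):
            jwl_pressure(self.tnt, 0.0, 1.0)

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            JWLProducts(3.231e9, 371.2e9, 4.15, 0.95, 0.30, 1630.0, 4.29e6)


class TestIdealGas:
    air = IdealGasAir()

    def test_ambient_state_closes_to_one_atmosphere(self):
        p = ideal_gas_pressure(self.air, 1.225, self.air.ref_internal_energy_per_mass)
        assert p == pytest.approx(101_325.0, rel=1e-12)

    def test_zero_energy_zero_pressure(self):
        assert ideal_gas_pressure(self.air, 1.225, 0.0) == 0.0

    def test_bilinear_in_density_and_energy(self):
        e = self.air.ref_internal_energy_per_mass
        assert ideal_gas_pressure(self.air, 2.45, e / 2.0) == pytest.approx(
            ideal_gas_pressure(self.air, 1.225, e)
        )


class TestDefaultConfig:
    def test_printed_constants_reproduced(self, materials):
        """Every shipped constant round-trips to its conventional printed form."""
        printed = {
            ("scalp", "bulk_modulus", 1e6): "34.7",
            ("scalp", "shear_modulus", 1e6): "5.88",
            ("scalp", "density", 1e3): "1.04",
            ("nasal_cavity", "bulk_modulus", 1e9): "2.19",
            ("nasal_cavity", "shear_modulus", 1.0): "225.3",
            ("skull", "bulk_sound_speed", 1.0): "1850",
            ("skull", "hugoniot_slope", 1.0): "0.94",
            ("skull", "ref_density", 1e3): "1.412",
            ("skull", "shear_modulus", 1e9): "2.664",
            ("csf", "bulk_sound_speed", 1.0): "1647",
            ("csf", "hugoniot_slope", 1.0): "1.921",
            ("csf", "ref_density", 1e3): "0.998",
            ("csf", "shear_modulus", 1.0): "500",
            ("brain", "bulk_modulus", 1e9): "2.19",
            ("brain", "short_term_shear", 1e3): "41",
            ("brain", "long_term_shear", 1e3): "7.8",
            ("brain", "decay_const", 1.0): "700",
            ("brain", "density", 1e3): "1.04",
            ("tnt", "ref_density", 1.0): "1630",
            ("tnt", "detonation_energy_per_mass", 1e6): "4.29",
        }
        for (mat, attr, scale), text in printed.items():
            value = getattr(materials[mat], attr) / scale
            assert f"{value:g}" == text, f"{mat}.{attr}"

    def test_air_initialises_at_one_atmosphere(self, materials):
        air = materials["air"]
        assert ideal_gas_pressure(
            air, air.ref_density, air.ref_internal_energy_per_mass
        ) == pytest.approx(101_325.0)

    def test_override_file_roundtrip(self, tmp_path):
        cfg = tmp_path / "mats.yaml"
        cfg.write_text(
            "foam:\n  law: linear_elastic\n  K: 1.5 MPa\n  G: 0.4 MPa\n  rho: 80 kg/m^3\n"
        )
        mats = load_materials(cfg)
        assert isinstance(mats["foam"], LinearElastic)
        assert mats["foam"].bulk_modulus == pytest.approx(1.5e6)
        assert mats["foam"].density == pytest.approx(80.0)
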