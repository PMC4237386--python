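"""Tissue column: reflection/transmission physics and solver invariants."""

import math

import numpy as np
import pytest

from blasthead.gauges import GaugeTrace
from blasthead.materials import LinearElastic, ViscoelasticBrain
from blasthead.tissue_column import (
    LayerColumn,
    LayerSpec,
    acoustic_transmission,
    load_columns,
    propagate,
    reflected_overpressure,
)

WATER = LinearElastic(2.2e9, 1.0e3, 1000.0, name="waterlike")
BONE = LinearElastic(4.832e9, 2.664e9, 1412.0, name="bonelike")
BRAIN = ViscoelasticBrain(2.19e9, 1040.0, 41.0e3, 7.8e3, 700.0)


def half_sine_load(peak, duration, total, dt=1e-7):
    t = np.arange(0.0, total + 0.5 * dt, dt)
    p = np.where(t < duration, peak * np.sin(np.pi * t / duration) ** 2, 0.0)
    return GaugeTrace(time=t, pressure=p, label="load")


class TestReflectedOverpressure:
    def test_acoustic_doubling_limit(self):
        dp = 10.0  # Pa, vanishing vs one atmosphere
        assert reflected_overpressure(dp) / dp == pytest.approx(2.0, rel=1e-3)

    def test_one_atmosphere_closed_form(self):
        p0 = 101_325.0
        assert reflected_overpressure(p0, p0) == pytest.approx(2.75 * p0, rel=1e-12)
        assert reflected_overpressure(p0, p0) == pytest.approx(278.6e3, rel=1e-3)

    def test_strong_shock_limit(self):
        dp = 1.0e12
        assert reflected_overpressure(dp) / dp == pytest.approx(8.0, rel=1e-4)


class TestAcousticTransmission:
    def test_matched_impedance_passes_unchanged(self):
        assert acoustic_transmission(3.0e6, 3.0e6) == 1.0

    def test_rigid_wall_doubles(self):
        assert acoustic_transmission(1.0e6, 1.0e12) == pytest.approx(2.0, rel=1e-5)

    def test_csf_to_skull_bulk_impedances(self):
        z_csf = 998.0 * 1647.0
        z_skull = 1412.0 * 1850.0
        assert acoustic_transmission(z_csf, z_skull) == pytest.approx(1.228, abs=5e-4)

    def test_nonpositive_impedance_rejected(self):
        with pytest.raises(ValueError):
            acoustic_transmission(0.0, 1.0e6)


class TestPropagatePhysics:
    def test_homogeneous_split_is_transparent(self):
        """A material interface with itself must not reflect."""
        col = LayerColumn(
            layers=[LayerSpec(WATER, 0.02, "a"), LayerSpec(WATER, 0.02, "b")],
            gauges={"prox": 0.010, "dist": 0.030},
        )
        load = half_sine_load(1.0e3, 5e-6, 4e-5)
        traces = propagate(col, load, 4e-5, cell_size=1e-4)
        p_prox = traces["prox"].pressure.max()
        p_dist = traces["dist"].pressure.max()
        assert p_dist == pytest.approx(p_prox, rel=0.03)

    def test_interface_transmission_matches_impedance_ratio(self):
        col = LayerColumn(
            layers=[LayerSpec(WATER, 0.02, "soft"), LayerSpec(BONE, 0.02, "hard")],
            gauges={"incident": 0.010, "transmitted": 0.025},
        )
        load = half_sine_load(1.0e3, 5e-6, 3e-5)
        traces = propagate(col, load, 3e-5, cell_size=1e-4)

        # traction continuity governs total axial stress |sigma| = P + (2/3) vM
        def axial(tr):
            return (tr.pressure + (2.0 / 3.0) * tr.von_mises).max()

        ratio = axial(traces["transmitted"]) / axial(traces["incident"])
        expected = acoustic_transmission(WATER.acoustic_impedance, BONE.acoustic_impedance)
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_viscoelastic_elastic_degenerate_limit(self):
        """With G0 == Ginf the brain must reproduce the elastic solution."""
        g = 41.0e3
        visco = ViscoelasticBrain(2.19e9, 1040.0, g, g, 700.0)
        elastic = LinearElastic(2.19e9, g, 1040.0)
        load = half_sine_load(50.0e3, 1e-4, 1.2e-3)
        kw = dict(cell_size=5e-4, sample_dt=1e-6)
        tr_v = propagate(
            LayerColumn([LayerSpec(visco, 0.1, "brain")], {"mid": 0.05}),
            load, 1.2e-3, **kw,
        )["mid"]
        tr_e = propagate(
            LayerColumn([LayerSpec(elastic, 0.1, "el")], {"mid": 0.05}),
            load, 1.2e-3, **kw,
        )["mid"]
        scale = tr_e.pressure.max()
        assert np.max(np.abs(tr_v.pressure - tr_e.pressure)) < 0.01 * scale
        assert tr_v.von_mises.max() == pytest.approx(tr_e.von_mises.max(), rel=0.01)

    def test_held_strain_relaxes_to_long_term_modulus(self):
        """Deviatoric stress under held load decays toward the Ginf value."""
        col = LayerColumn([LayerSpec(BRAIN, 0.02, "brain")], {"mid": 0.010})
        total = 10.0e-3
        dt = 1e-7
        t = np.arange(0.0, total + 0.5 * dt, dt)
        rise = 1.0e-5
        p = 100.0e3 * np.clip(t / rise, 0.0, 1.0)  # fast ramp, then held
        load = GaugeTrace(time=t, pressure=p, label="step")
        tr = propagate(col, load, total, cell_size=2.5e-4)["mid"]
        # glassy response just after arrival vs relaxed response at late time
        vm = tr.von_mises
        sel_early = (tr.time > 3e-5) & (tr.time < 8e-5)
        sel_late = tr.time > 8.5e-3  # about six relaxation times
        vm_early = vm[sel_early].max()
        vm_late = vm[sel_late].mean()
        eps = 100.0e3 / (BRAIN.bulk_modulus + 4.0 * BRAIN.short_term_shear / 3.0)
        assert vm_early == pytest.approx(2.0 * BRAIN.short_term_shear * eps, rel=0.10)
        assert vm_late == pytest.approx(2.0 * BRAIN.long_term_shear * eps, rel=0.15)
        assert vm_late < 0.3 * vm_early

    def test_brain_depth_attenuation_monotone(self):
        """A short pulse attenuates strictly from proximal to distal gauges."""
        col = LayerColumn(
            [LayerSpec(BRAIN, 0.15, "brain")],
            {f"g{k}": 0.01 + 0.02 * k for k in range(7)},
        )
        load = half_sine_load(200.0e3, 2e-5, 2e-4, dt=2e-8)
        traces = propagate(col, load, 2e-4, cell_size=2.5e-4, sample_dt=2e-7)
        peaks = [traces[f"g{k}"].pressure.max() for k in range(7)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))


@pytest.fixture(scope="module")
def head_run(columns):
    load = half_sine_load(50.0e3, 2e-4, 3e-3)
    return propagate(
        columns["anterior"], load, 3e-3, cell_size=5e-4, return_diagnostics=True
    )


class TestSolverInvariants:

    def test_momentum_balance_per_step(self, head_run):
        _, diag = head_run
        assert diag["max_momentum_residual"] < 1e-6

    def test_cell_masses_invariant(self, head_run):
        _, diag = head_run
        state = diag["state"]
        dx = np.diff(state.node_positions)
        assert np.allclose(state.density * dx, state.cell_masses, rtol=1e-12, atol=0.0)

    def test_energy_non_increasing_after_load(self, head_run):
        _, diag = head_run
        sel = diag["times"] > 2.1e-4
        e = diag["energy"][sel]
        increases = np.diff(e)
        assert increases.max() <= 1e-6 * e.max()


class TestColumnConfig:
    def test_default_orientations_and_skull_thicknesses(self, columns):
        assert set(columns) == {"anterior", "right_lateral", "posterior"}

        def skull_mm(name):
            col = columns[name]
            return [l.thickness for l in col.layers if l.label == "skull"][0] * 1e3

        assert skull_mm("right_lateral") < skull_mm("anterior") < skull_mm("posterior")

    def test_gauges_inside_brain(self, columns):
        col = columns["anterior"]
        assert set(col.brain_gauges()) == set(col.gauges)
        assert "proximal_cortex" in col.gauges and "distal_cortex" in col.gauges

    def test_gauge_outside_column_rejected(self):
        with pytest.raises(ValueError):
            LayerColumn([LayerSpec(BRAIN, 0.1, "brain")], {"out": 0.2})

    def test_brain_column_without_brain_gauge_rejected(self):
        with pytest.raises(ValueError):
            LayerColumn(
                [LayerSpec(WATER, 0.05, "w"), LayerSpec(BRAIN, 0.1, "brain")],
                {"shallow": 0.02},
            )
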