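"""1D spherically symmetric multi-material air-blast solver.

A centrally ignited spherical TNT charge is initialised as
constant-volume-burnt detonation products (JWL EOS, full chemical energy
deposited, at rest at the solid explosive density) surrounded by ambient
ideal-gas air.  The flow is integrated with a staggered-grid Lagrangian
finite-volume scheme (von Neumann-Richtmyer artificial viscosity,
leapfrog time integration, implicit trapezoidal internal-energy update).
Because cell boundaries move with the material, the products/air
interface is tracked exactly and each cell keeps a single equation of
state for the whole run.

The free-field side-on (static) pressure history is recorded at a fixed
Eulerian gauge radius and resampled to a uniform interval, ready for
Friedlander fitting or for loading a tissue column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from blasthead.gauges import GaugeTrace
from blasthead.materials import IdealGasAir, JWLProducts, load_materials

__all__ = [
    "ChargeSpec",
    "RadialGrid",
    "FriedlanderParams",
    "SolverError",
    "charge_radius",
    "detonate_1d",
    "friedlander",
    "fit_friedlander",
    "incident_overpressure_oracle",
]


class SolverError(RuntimeError):
    """Raised when the hydrocode loses a valid state (with time and cell)."""


def charge_radius(mass: float, tnt_density: float = 1630.0) -> float:
    """Radius of a spherical charge of the given mass, m.

    ``r = (3 m / (4 pi rho))^(1/3)``.
    """
    if mass <= 0 or tnt_density <= 0:
        raise ValueError("charge mass and density must be positive")
    return (3.0 * mass / (4.0 * math.pi * tnt_density)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ChargeSpec:
    """Spherical TNT charge defined by mass; radius follows from density."""

    mass: float  # kg
    tnt_density: float = 1630.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.tnt_density <= 0:
            raise ValueError("charge mass and density must be positive")

    @property
    def radius(self) -> float:
        return charge_radius(self.mass, self.tnt_density)


@dataclass
class RadialGrid:
    """Discretisation of the radial domain and the evolving cell state.

    ``edges`` are node radii (strictly increasing, starting at 0); all
    other arrays are cell-centred.  ``is_product`` flags detonation-
    product cells (a contiguous block at the centre).
    """

    edges: np.ndarray
    density: np.ndarray
    velocity: np.ndarray  # node velocities, same length as edges
    internal_energy: np.ndarray  # specific, J/kg
    is_product: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("grid edges must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return int(self.edges.size - 1)

    @property
    def cell_masses(self) -> np.ndarray:
        vol = (4.0 * math.pi / 3.0) * np.diff(self.edges**3)
        return self.density * vol


def build_grid(
    charge: ChargeSpec,
    standoff: float,
    *,
    cell_size: float = 1.0e-3,
    r_max: float | None = None,
    fine_margin: float = 0.3,
    stretch_ratio: float = 1.05,
    air: IdealGasAir | None = None,
    min_charge_cells: int = 40,
) -> RadialGrid:
    """Build the initial radial grid for a detonation run.

    Uniform ``cell_size`` cells cover the charge surroundings out to
    ``standoff + fine_margin``; beyond that the spacing grows
    geometrically (sponge region) to ``r_max``, which keeps outer-
    boundary reflections away from the gauge for the simulated window.
    """
    air = air or IdealGasAir()
    a = charge.radius
    if standoff < a:
        raise ValueError("standoff must be at least the charge radius")
    if r_max is None:
        r_max = standoff + 2.5
    n_charge = max(min_charge_cells, int(round(a / cell_size)))
    charge_edges = np.linspace(0.0, a, n_charge + 1)

    r_fine_end = min(standoff + fine_margin, r_max)
    n_fine = max(1, int(round((r_fine_end - a) / cell_size)))
    fine_edges = np.linspace(a, r_fine_end, n_fine + 1)[1:]

    coarse = []
    dr = cell_size
    r = r_fine_end
    cap = 25.0 * cell_size
    while r < r_max:
        dr = min(dr * stretch_ratio, cap)
        r += dr
        coarse.append(r)
    edges = np.concatenate([charge_edges, fine_edges, np.asarray(coarse)])

    n = edges.size - 1
    is_product = np.zeros(n, dtype=bool)
    is_product[:n_charge] = True
    density = np.where(is_product, charge.tnt_density, air.ref_density)
    energy = np.where(is_product, 0.0, air.ref_internal_energy_per_mass)
    return RadialGrid(
        edges=edges,
        density=density.astype(float),
        velocity=np.zeros(n + 1),
        internal_energy=energy.astype(float),
        is_product=is_product,
    )


def detonate_1d(
    charge: ChargeSpec,
    standoff: float,
    *,
    cell_size: float = 1.0e-3,
    end_time: float = 5.0e-3,
    sample_dt: float = 1.0e-6,
    cfl: float = 0.4,
    r_max: float | None = None,
    materials: dict | None = None,
    gauge_label: str | None = None,
    q_quad: float = 1.5,
    q_lin: float = 0.06,
    return_state: bool = False,
):
    """Detonate a spherical charge and record the gauge at ``standoff``.

    Parameters
    ----------
    charge:
        Charge specification (mass, solid density).
    standoff:
        Gauge radius from the detonation centre, m; must be at least the
        charge radius.
    cell_size:
        Uniform cell width in the resolved region, m (default 1 mm).
    end_time:
        Simulated window, s (default 5 ms — long enough for the positive
        and negative phases to pass the gauge and the field to relax).
    sample_dt:
        Output sampling interval, s (default 1 us).

    Returns
    -------
    GaugeTrace
        Absolute static pressure at the fixed gauge radius, uniformly
        sampled on ``[0, end_time]``.  ``meta`` carries the ambient
        pressure, the charge description and solver diagnostics
        (peak overpressure, energy-balance drift).
    """
    from blasthead import _kernels

    mats = materials or load_materials()
    tnt: JWLProducts = mats["tnt"]
    air: IdealGasAir = mats["air"]
    grid = build_grid(charge, standoff, cell_size=cell_size, r_max=r_max, air=air)

    r = grid.edges.copy()
    u = grid.velocity.copy()
    n_prod = int(grid.is_product.sum())
    vol = (4.0 * math.pi / 3.0) * np.diff(r**3)
    m = grid.density * vol
    e = grid.internal_energy.copy()
    # constant-volume burn: full chemical energy in the products at rest
    e[:n_prod] = tnt.detonation_energy_per_mass

    max_steps = 4_000_000
    steps, times, gauge_p, max_drift, err, err_cell, err_t = _kernels.run_spherical(
        r,
        u,
        m,
        e,
        n_prod,
        air.gamma,
        air.ref_pressure,
        1.0e-3 * air.ref_internal_energy_per_mass,
        tnt.A,
        tnt.B,
        tnt.R1,
        tnt.R2,
        tnt.omega,
        charge.tnt_density,
        q_quad,
        q_lin,
        cfl,
        end_time,
        standoff,
        standoff + 0.25,
        max_steps,
    )
    if err == 1:
        raise SolverError(f"cell inversion at t={err_t:.3e}s, cell {err_cell}")
    if err == 2:
        raise SolverError(f"non-finite state at t={err_t:.3e}s, cell {err_cell}")
    if err == 3:
        raise SolverError(f"time step collapsed at t={err_t:.3e}s")
    if err == 4:
        raise SolverError(f"step budget exhausted at t={err_t:.3e}s")

    p0 = air.ref_pressure
    t_out = np.arange(0.0, end_time + 0.5 * sample_dt, sample_dt)
    p_out = np.interp(t_out, times[: steps + 1], gauge_p[: steps + 1])
    label = gauge_label or f"standoff_{standoff:g}m"
    trace = GaugeTrace(
        time=t_out,
        pressure=p_out,
        label=label,
        meta={
            "ambient_pa": p0,
            "kind": "absolute",
            "charge_mass_kg": charge.mass,
            "standoff_m": standoff,
            "cell_size_m": cell_size,
            "peak_overpressure_pa": float(np.max(p_out) - p0),
            "energy_drift_max": max_drift,
            "steps": steps,
        },
    )
    if not return_state:
        return trace
    # kernel mutated r, u, e in place; masses are fixed in a Lagrangian run
    vol_final = (4.0 * math.pi / 3.0) * np.diff(r**3)
    final = RadialGrid(
        edges=r,
        density=m / vol_final,
        velocity=u,
        internal_energy=e,
        is_product=grid.is_product,
    )
    return trace, final


# --------------------------------------------------------------------------
# Friedlander waveform
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FriedlanderParams:
    """Parameters of the modified Friedlander wave.

    Overpressure ``dP * (1 - tau) * exp(-b * tau)`` with
    ``tau = (t - t_a) / t_d``: instantaneous rise to ``dP`` at the
    arrival time, decay through zero at ``t_a + t_d`` and a recovering
    negative phase.
    """

    peak_overpressure: float  # Pa
    arrival_time: float  # s
    positive_duration: float  # s
    decay_b: float  # dimensionless
    residual: float = 0.0  # RMS fit residual, Pa

    def __post_init__(self) -> None:
        if self.peak_overpressure <= 0:
            raise ValueError("peak overpressure must be positive")
        if self.positive_duration <= 0 or self.decay_b <= 0:
            raise ValueError("positive duration and decay constant must be positive")


def friedlander(t, params: FriedlanderParams):
    """Evaluate the Friedlander overpressure at times ``t`` (Pa).

    Samples an infinitesimal round-off below the arrival time still see
    the instantaneous rise (tolerance 1e-9 in tau), so a sample grid
    that nominally includes ``t_a`` records the full peak.
    """
    t = np.asarray(t, dtype=float)
    tau = (t - params.arrival_time) / params.positive_duration
    tau_c = np.maximum(tau, 0.0)
    wave = params.peak_overpressure * (1.0 - tau_c) * np.exp(-params.decay_b * tau_c)
    return np.where(tau >= -1e-9, wave, 0.0)


def fit_friedlander(trace: GaugeTrace) -> FriedlanderParams:
    """Least-squares Friedlander fit to a gauge trace.

    The overpressure (trace minus its ``meta['ambient_pa']`` baseline, if
    any) is fit over ``[t_a, t_a + 2 t_d]`` with the arrival time pinned
    to the overpressure maximum; peak, positive-phase duration and decay
    constant are free.  Residuals are weighted ``exp(-tau)`` so the fit
    emphasises the front of the positive phase, where the ideal waveform
    describes a real blast best (late-time suction from a finite source
    departs from the Friedlander shape).
    """
    from scipy.optimize import least_squares

    baseline = float(trace.meta.get("ambient_pa", 0.0))
    op = trace.pressure - baseline
    if np.max(op) <= 0:
        raise ValueError("trace has no positive phase; cannot fit a Friedlander wave")
    i_pk = int(np.argmax(op))
    t_a = float(trace.time[i_pk])
    dp0 = float(op[i_pk])
    # first zero crossing after the peak estimates the positive duration
    after = op[i_pk:]
    neg = np.nonzero(after <= 0.0)[0]
    td0 = float(trace.time[i_pk + neg[0]] - t_a) if neg.size else trace.duration / 4.0
    td0 = max(td0, 2.0 * trace.dt)

    # fixed fit window [t_a, t_a + 2 t_d] from the duration estimate
    sel = (trace.time >= t_a) & (trace.time <= t_a + 2.0 * td0)
    t_sel, op_sel = trace.time[sel], op[sel]
    weights = np.exp(-(t_sel - t_a) / td0)

    def resid(x):
        dp, td, b = x
        pars = FriedlanderParams(max(dp, 1.0), t_a, max(td, 1e-9), max(b, 1e-6))
        return weights * (friedlander(t_sel, pars) - op_sel)

    sol = least_squares(
        resid,
        x0=[dp0, td0, 1.0],
        bounds=([1.0, trace.dt, 1e-3], [np.inf, trace.duration, 50.0]),
        xtol=1e-14,
        ftol=1e-14,
    )
    dp, td, b = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2))) if sol.fun.size else 0.0
    return FriedlanderParams(float(dp), t_a, float(td), float(b), residual=rms)


# --------------------------------------------------------------------------
# empirical scaled-distance oracle
# --------------------------------------------------------------------------


def incident_overpressure_oracle(mass: float, standoff: float) -> float:
    """Empirical free-air incident peak overpressure, Pa.

    Classic point-source scaled-distance fit (Brode-type) in terms of
    ``Z = R / m^(1/3)`` (m/kg^(1/3)):

    * near field (above 10 bar): ``dP = 6.7/Z^3 + 1`` bar;
    * far field (0.1-10 bar): ``dP = 0.975/Z + 1.455/Z^2 + 5.85/Z^3 - 0.019`` bar.

    Used only as an independent cross-check of the hydrocode; raises for
    scaled distances outside the fit's validity.
    """
    if mass <= 0 or standoff <= 0:
        raise ValueError("mass and standoff must be positive")
    z = standoff / mass ** (1.0 / 3.0)
    far = 0.975 / z + 1.455 / z**2 + 5.85 / z**3 - 0.019
    if far > 10.0:
        near = 6.7 / z**3 + 1.0
        if z < 0.05:
            raise ValueError(f"scaled distance Z={z:.3g} below fit validity")
        return near * 1.0e5
    if far < 0.1:
        raise ValueError(f"scaled distance Z={z:.3g} beyond fit validity (dP < 0.1 bar)")
    return far * 1.0e5
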