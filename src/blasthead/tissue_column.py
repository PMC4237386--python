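"""1D Lagrangian uniaxial-strain wave propagation through a tissue column.

The head's through-thickness transmission path is reduced to an ordered
planar column — by default scalp / skull / CSF / brain, loaded face
first — driven by a face-on (reflected) pressure history.  Each cell
carries the constitutive law of its layer: volumetric response from the
material's EOS (linear ``P = K*mu`` or the shock Hugoniot), deviatoric
response elastic or, for brain, the single-term viscoelastic shear
relaxation evaluated with a recursive exponential integrator.  Pressure
and von Mises stress (``(3/2)|s_axial|`` in uniaxial strain) are
recorded at virtual gauges fixed to material points.

This is a desk-scale surrogate for 3D head-blast simulation: orientation
effects enter only through configurable layer thicknesses, and no claim
is made of reproducing 3D gauge values (skull curvature, foramen-magnum
funneling and CSF cavitation are out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from blasthead import _kernels
from blasthead.blast_source import SolverError
from blasthead.gauges import GaugeTrace
from blasthead.materials import (
    STANDARD_ATMOSPHERE,
    LinearElastic,
    MaterialModel,
    ShockEOS,
    ViscoelasticBrain,
    load_materials,
    parse_quantity,
)

__all__ = [
    "LayerSpec",
    "LayerColumn",
    "ColumnState",
    "reflected_overpressure",
    "acoustic_transmission",
    "propagate",
    "load_columns",
    "default_columns_path",
]


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: a material model plus its thickness."""

    material: MaterialModel
    thickness: float  # m
    label: str = ""

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.label!r}: thickness must be positive")


@dataclass
class LayerColumn:
    """Ordered layer stack (loaded face first) with gauge depths.

    ``gauges`` maps a gauge label to its depth in metres from the loaded
    surface.  At least one gauge must sit inside a brain layer.
    """

    layers: list[LayerSpec]
    gauges: dict[str, float]
    name: str = "column"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("column needs at least one layer")
        total = self.total_thickness
        for label, depth in self.gauges.items():
            if not (0.0 < depth < total):
                raise ValueError(
                    f"gauge {label!r} depth {depth} m outside column (0, {total:.4g})"
                )
        has_brain = any(isinstance(l.material, ViscoelasticBrain) for l in self.layers)
        if has_brain and not any(
            isinstance(self.layer_at(d).material, ViscoelasticBrain)
            for d in self.gauges.values()
        ):
            raise ValueError("column with a brain layer needs a gauge in it")

    @property
    def total_thickness(self) -> float:
        return float(sum(layer.thickness for layer in self.layers))

    def layer_at(self, depth: float) -> LayerSpec:
        """Layer containing the given depth from the loaded surface."""
        x = 0.0
        for layer in self.layers:
            x += layer.thickness
            if depth < x:
                return layer
        return self.layers[-1]

    def brain_gauges(self) -> list[str]:
        """Labels of gauges lying in viscoelastic (brain) layers."""
        return [
            lbl
            for lbl, d in self.gauges.items()
            if isinstance(self.layer_at(d).material, ViscoelasticBrain)
        ]


@dataclass
class ColumnState:
    """Final Lagrangian state of a column run (cell-centred fields)."""

    node_positions: np.ndarray
    node_velocities: np.ndarray
    cell_masses: np.ndarray  # per unit area, kg/m^2; constant in time
    density: np.ndarray
    pressure: np.ndarray
    deviatoric_axial_stress: np.ndarray
    visco_internal: np.ndarray


def reflected_overpressure(incident_peak, ambient: float = STANDARD_ATMOSPHERE):
    """Normal-reflection overpressure on a blocked face, Pa.

    For gamma = 1.4 air the Rankine-Hugoniot normal-reflection factor
    gives ``dP_r = 2 dP (7 P0 + 4 dP) / (7 P0 + dP)``: acoustic doubling
    for weak waves, a factor of 8 in the strong-shock limit.
    """
    dp = np.asarray(incident_peak, dtype=float)
    out = 2.0 * dp * (7.0 * ambient + 4.0 * dp) / (7.0 * ambient + dp)
    return float(out) if np.ndim(incident_peak) == 0 else out


def acoustic_transmission(z1: float, z2: float) -> float:
    """Normal-incidence pressure transmission coefficient ``2 Z2/(Z1+Z2)``."""
    if z1 <= 0 or z2 <= 0:
        raise ValueError("acoustic impedances must be positive")
    return 2.0 * z2 / (z1 + z2)


def _cell_arrays(column: LayerColumn, cell_size: float):
    """Discretise the column into cells with per-cell constitutive arrays."""
    edges = [0.0]
    vol_law, k_bulk, s_slope, rho0, g0, ginf, beta = [], [], [], [], [], [], []
    for layer in column.layers:
        n = max(2, int(round(layer.thickness / cell_size)))
        x0, x1 = edges[-1], edges[-1] + layer.thickness
        edges.extend(np.linspace(x0, x1, n + 1)[1:].tolist())
        mat = layer.material
        if isinstance(mat, LinearElastic):
            row = (_kernels.VOL_LINEAR, mat.bulk_modulus, 0.0, mat.density,
                   mat.shear_modulus, mat.shear_modulus, 1.0)
        elif isinstance(mat, ShockEOS):
            row = (_kernels.VOL_SHOCK, mat.bulk_modulus, mat.hugoniot_slope,
                   mat.ref_density, mat.shear_modulus, mat.shear_modulus, 1.0)
        elif isinstance(mat, ViscoelasticBrain):
            row = (_kernels.VOL_LINEAR, mat.bulk_modulus, 0.0, mat.density,
                   mat.short_term_shear, mat.long_term_shear, mat.decay_const)
        else:
            raise TypeError(
                f"layer {layer.label!r}: material {type(mat).__name__} is not a "
                "tissue model (expected linear elastic, shock EOS or viscoelastic)"
            )
        for _ in range(n):
            vol_law.append(row[0])
            k_bulk.append(row[1])
            s_slope.append(row[2])
            rho0.append(row[3])
            g0.append(row[4])
            ginf.append(row[5])
            beta.append(row[6])
    x = np.asarray(edges)
    return (
        x,
        np.asarray(vol_law, dtype=np.int64),
        np.asarray(k_bulk),
        np.asarray(s_slope),
        np.asarray(rho0),
        np.asarray(g0),
        np.asarray(ginf),
        np.asarray(beta),
    )


def propagate(
    column: LayerColumn,
    surface_load: GaugeTrace,
    end_time: float | None = None,
    *,
    cell_size: float = 2.5e-4,
    sample_dt: float = 1.0e-6,
    cfl: float = 0.3,
    q_quad: float = 1.5,
    q_lin: float = 0.06,
    return_diagnostics: bool = False,
):
    """Drive ``surface_load`` through the column and record the gauges.

    Parameters
    ----------
    column:
        Layer stack and gauge depths.
    surface_load:
        Overpressure history (Pa, zero baseline) applied as traction on
        the loaded face — normally the *reflected* blast overpressure.
    end_time:
        Simulated window, s; defaults to the load's duration.
    cell_size:
        Nominal cell width, m (default 0.25 mm).

    Returns
    -------
    dict[str, GaugeTrace]
        Per-gauge traces with pressure and von Mises channels, sampled
        every ``sample_dt``.  With ``return_diagnostics=True`` a second
        dict is returned carrying the mechanical-energy history, the
        worst per-step momentum-balance residual and the final
        :class:`ColumnState`.
    """
    if end_time is None:
        end_time = surface_load.duration
    x, vol_law, k_bulk, s_slope, rho0, g0, ginf, beta = _cell_arrays(column, cell_size)
    n = x.size - 1
    m = rho0 * np.diff(x)
    u = np.zeros(n + 1)

    labels = list(column.gauges.keys())
    depths = np.asarray([column.gauges[lbl] for lbl in labels])
    centres = 0.5 * (x[:-1] + x[1:])
    gauge_cells = np.asarray(
        [int(np.argmin(np.abs(centres - d))) for d in depths], dtype=np.int64
    )

    # absorbing impedance of the distal material
    distal = column.layers[-1].material
    z_right = distal.acoustic_impedance

    c_max = max(
        math.sqrt((kb + 4.0 * g / 3.0) / r0) for kb, g, r0 in zip(k_bulk, g0, rho0)
    )
    dt_min = cfl * cell_size / c_max
    max_steps = min(int(3.0 * end_time / dt_min) + 1000, 4_000_000)

    (
        steps,
        times,
        g_press,
        g_vm,
        energy,
        max_mom_resid,
        err,
        err_cell,
        err_t,
        rho_f,
        p_f,
        s_eq_f,
        h_f,
    ) = _kernels.run_column(
        x,
        u,
        m,
        vol_law,
        k_bulk,
        s_slope,
        rho0,
        g0,
        ginf,
        beta,
        surface_load.time,
        surface_load.pressure,
        z_right,
        q_quad,
        q_lin,
        cfl,
        end_time,
        gauge_cells,
        max_steps,
    )
    if err == 1:
        raise SolverError(f"cell inversion at t={err_t:.3e}s, cell {err_cell}")
    if err == 2:
        raise SolverError(f"state out of EOS domain at t={err_t:.3e}s, cell {err_cell}")
    if err == 3:
        raise SolverError(f"time step collapsed at t={err_t:.3e}s")
    if err == 4:
        raise SolverError(f"step budget exhausted at t={err_t:.3e}s")

    t_out = np.arange(0.0, end_time + 0.5 * sample_dt, sample_dt)
    traces: dict[str, GaugeTrace] = {}
    tk = times[: steps + 1]
    for gi, lbl in enumerate(labels):
        traces[lbl] = GaugeTrace(
            time=t_out,
            pressure=np.interp(t_out, tk, g_press[: steps + 1, gi]),
            von_mises=np.interp(t_out, tk, g_vm[: steps + 1, gi]),
            label=lbl,
            meta={
                "kind": "gauge_overpressure",
                "depth_m": float(depths[gi]),
                "column": column.name,
            },
        )
    if not return_diagnostics:
        return traces
    diagnostics = {
        "times": tk.copy(),
        "energy": energy[: steps + 1].copy(),
        "max_momentum_residual": float(max_mom_resid),
        "steps": int(steps),
        "state": ColumnState(
            node_positions=x.copy(),
            node_velocities=u.copy(),
            cell_masses=m.copy(),
            density=rho_f.copy(),
            pressure=p_f.copy(),
            deviatoric_axial_stress=(s_eq_f + h_f),
            visco_internal=h_f.copy(),
        ),
    }
    return traces, diagnostics


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def default_columns_path() -> Path:
    """Path to the shipped per-orientation layer-stack configuration."""
    return Path(resources.files("blasthead").joinpath("data/columns.yaml"))


def load_columns(
    path: str | Path | None = None,
    materials: dict[str, MaterialModel] | None = None,
) -> dict[str, LayerColumn]:
    """Load per-orientation columns; ``None`` loads the shipped defaults.

    Each configured orientation lists its layers (material name +
    thickness) and the gauge depths, given as millimetres into the brain
    layer; depths are converted to absolute depth from the loaded face.
    """
    cfg_path = default_columns_path() if path is None else Path(path)
    mats = materials or load_materials()
    with open(cfg_path) as fh:
        raw = yaml.safe_load(fh)
    columns: dict[str, LayerColumn] = {}
    for name, section in raw.items():
        layers = []
        brain_start = None
        x = 0.0
        for item in section["layers"]:
            mat_name = item["material"]
            if mat_name not in mats:
                raise ValueError(f"column {name!r}: unknown material {mat_name!r}")
            thickness = parse_quantity(item["thickness"])
            if isinstance(mats[mat_name], ViscoelasticBrain) and brain_start is None:
                brain_start = x
            layers.append(LayerSpec(mats[mat_name], thickness, label=mat_name))
            x += thickness
        if brain_start is None:
            raise ValueError(f"column {name!r}: no brain layer")
        gauges: dict[str, float] = {}
        depths_mm = section["brain_gauges_mm"]
        for i, d_mm in enumerate(depths_mm):
            if i == 0:
                lbl = "proximal_cortex"
            elif i == len(depths_mm) - 1:
                lbl = "distal_cortex"
            else:
                lbl = f"brain_{int(d_mm):03d}mm"
            gauges[lbl] = brain_start + d_mm * 1e-3
        columns[name] = LayerColumn(layers=layers, gauges=gauges, name=name)
    return columns
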