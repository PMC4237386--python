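"""Constitutive models for head tissues, TNT detonation products and air.

Five tissue constituents (scalp, skull, CSF, nasal cavity, brain) plus the
explosive and the surrounding air are each represented by a small constant
set and a closed-form pressure (or shear-relaxation) law:

* scalp / nasal cavity — linear elastic (bulk modulus ``K``, shear ``G``);
* skull / CSF — Mie-Gruneisen shock equation of state built from the
  linear shock-velocity / particle-velocity Hugoniot ``U_s = C0 + s*U_p``;
* brain — elastic in dilatation (``K``) with a single-term exponential
  shear relaxation ``G(t) = G_inf + (G0 - G_inf) * exp(-beta*t)``;
* TNT detonation products — Jones-Wilkins-Lee (JWL) equation of state;
* air — ideal gas ``P = (gamma - 1) * rho * e``.

All values are SI internally.  The shipped default configuration
(``data/materials.yaml``) carries the constants in the units they are
conventionally quoted in (MPa, g/cm^3, ...) and is normalised on load.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LinearElastic",
    "ShockEOS",
    "ViscoelasticBrain",
    "JWLProducts",
    "IdealGasAir",
    "EOSDomainError",
    "shock_eos_pressure",
    "brain_relaxation_modulus",
    "jwl_pressure",
    "ideal_gas_pressure",
    "load_materials",
    "default_materials_path",
    "STANDARD_ATMOSPHERE",
]

STANDARD_ATMOSPHERE = 101_325.0  # Pa


class EOSDomainError(ValueError):
    """Raised when a state falls outside an equation of state's domain."""


# --------------------------------------------------------------------------
# material types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearElastic:
    """Isotropic linear elastic solid (volumetric K, deviatoric G)."""

    bulk_modulus: float  # Pa
    shear_modulus: float  # Pa
    density: float  # kg/m^3
    name: str = "linear_elastic"

    def __post_init__(self) -> None:
        if not (self.bulk_modulus > 0 and self.shear_modulus > 0 and self.density > 0):
            raise ValueError(f"{self.name}: K, G and density must be positive")

    @property
    def longitudinal_modulus(self) -> float:
        return self.bulk_modulus + 4.0 * self.shear_modulus / 3.0

    @property
    def longitudinal_sound_speed(self) -> float:
        return math.sqrt(self.longitudinal_modulus / self.density)

    @property
    def acoustic_impedance(self) -> float:
        """Longitudinal impedance rho*c, Pa*s/m."""
        return self.density * self.longitudinal_sound_speed


@dataclass(frozen=True)
class ShockEOS:
    """Mie-Gruneisen shock EOS from the linear U_s-U_p Hugoniot.

    ``U_s = C0 + s * U_p`` with reference density ``rho0``.  Only the
    parameters (rho0, C0, s) enter the pressure: the thermal Gruneisen
    energy term is omitted, matching the three-constant parameterisation.
    An optional shear modulus G carries the deviatoric response.
    """

    ref_density: float  # kg/m^3
    bulk_sound_speed: float  # m/s
    hugoniot_slope: float  # dimensionless
    shear_modulus: float = 0.0  # Pa
    name: str = "shock_eos"

    def __post_init__(self) -> None:
        if not (self.ref_density > 0 and self.bulk_sound_speed > 0 and self.hugoniot_slope > 0):
            raise ValueError(f"{self.name}: rho0, C0 and s must be positive")
        if self.shear_modulus < 0:
            raise ValueError(f"{self.name}: shear modulus must be non-negative")

    @property
    def bulk_modulus(self) -> float:
        """Small-strain bulk modulus rho0*C0^2."""
        return self.ref_density * self.bulk_sound_speed**2

    @property
    def density(self) -> float:
        return self.ref_density

    @property
    def longitudinal_modulus(self) -> float:
        return self.bulk_modulus + 4.0 * self.shear_modulus / 3.0

    @property
    def longitudinal_sound_speed(self) -> float:
        return math.sqrt(self.longitudinal_modulus / self.ref_density)

    @property
    def acoustic_impedance(self) -> float:
        return self.ref_density * self.longitudinal_sound_speed


@dataclass(frozen=True)
class ViscoelasticBrain:
    """Brain tissue: elastic dilatation, single-term shear relaxation.

    ``G(t) = G_inf + (G0 - G_inf) * exp(-beta * t)`` with short-term
    modulus ``G0``, long-term modulus ``G_inf`` and viscous decay
    constant ``beta`` (1/s).
    """

    bulk_modulus: float  # Pa
    density: float  # kg/m^3
    short_term_shear: float  # Pa, G0
    long_term_shear: float  # Pa, G_inf
    decay_const: float  # 1/s, beta
    name: str = "brain"

    def __post_init__(self) -> None:
        if not (self.bulk_modulus > 0 and self.density > 0):
            raise ValueError(f"{self.name}: K and density must be positive")
        if not (self.short_term_shear >= self.long_term_shear > 0):
            raise ValueError(f"{self.name}: need G0 >= G_inf > 0")
        if self.decay_const <= 0:
            raise ValueError(f"{self.name}: decay constant must be positive")

    @property
    def longitudinal_modulus(self) -> float:
        # short-term (glassy) longitudinal modulus governs wave arrival
        return self.bulk_modulus + 4.0 * self.short_term_shear / 3.0

    @property
    def longitudinal_sound_speed(self) -> float:
        return math.sqrt(self.longitudinal_modulus / self.density)

    @property
    def acoustic_impedance(self) -> float:
        return self.density * self.longitudinal_sound_speed


@dataclass(frozen=True)
class JWLProducts:
    """Jones-Wilkins-Lee EOS for detonation-product gases.

    ``P(V, E) = A (1 - w/(R1 V)) exp(-R1 V) + B (1 - w/(R2 V)) exp(-R2 V)
    + w E / V`` with relative volume ``V = rho0/rho`` and ``E`` the
    internal energy per unit *reference* volume (J/m^3).
    """

    A: float  # Pa
    B: float  # Pa
    R1: float
    R2: float
    omega: float
    ref_density: float  # kg/m^3
    detonation_energy_per_mass: float  # J/kg, e0

    def __post_init__(self) -> None:
        if not (self.A > self.B > 0):
            raise ValueError("JWL: need A > B > 0")
        if not (self.R1 > self.R2 > 0):
            raise ValueError("JWL: need R1 > R2 > 0")
        if not (0.0 < self.omega < 1.0):
            raise ValueError("JWL: need 0 < omega < 1")
        if self.ref_density <= 0 or self.detonation_energy_per_mass < 0:
            raise ValueError("JWL: rho0 must be positive and e0 non-negative")


@dataclass(frozen=True)
class IdealGasAir:
    """Calorically perfect gas; ambient state fixed by one atmosphere."""

    gamma: float = 1.4
    ref_density: float = 1.225  # kg/m^3
    ref_pressure: float = STANDARD_ATMOSPHERE  # Pa

    def __post_init__(self) -> None:
        if self.gamma <= 1.0:
            raise ValueError("air: gamma must exceed 1")
        if self.ref_density <= 0 or self.ref_pressure <= 0:
            raise ValueError("air: ambient density and pressure must be positive")

    @property
    def ref_internal_energy_per_mass(self) -> float:
        """e such that (gamma-1)*rho*e equals the ambient pressure, J/kg."""
        return self.ref_pressure / ((self.gamma - 1.0) * self.ref_density)

    @property
    def ambient_sound_speed(self) -> float:
        return math.sqrt(self.gamma * self.ref_pressure / self.ref_density)


MaterialModel = LinearElastic | ShockEOS | ViscoelasticBrain | JWLProducts | IdealGasAir


# --------------------------------------------------------------------------
# pressure / relaxation laws
# --------------------------------------------------------------------------


def shock_eos_pressure(material: ShockEOS, density):
    """Hugoniot pressure at the given density.

    For compression ``mu = rho/rho0 - 1 >= 0`` the jump relations with the
    linear Hugoniot give ``P = rho0 C0^2 mu (1+mu) / (1 - (s-1) mu)^2``;
    in tension the response is linearised to ``P = rho0 C0^2 mu``
    (no spall model).

    Raises
    ------
    EOSDomainError
        For non-positive density, or compression at/above the Hugoniot
        pole ``mu = 1/(s-1)`` (only reachable when ``s > 1``).
    """
    rho = np.asarray(density, dtype=float)
    if np.any(rho <= 0):
        raise EOSDomainError(f"{material.name}: density must be positive")
    mu = rho / material.ref_density - 1.0
    s = material.hugoniot_slope
    if s > 1.0 and np.any(mu >= 1.0 / (s - 1.0)):
        raise EOSDomainError(
            f"{material.name}: compression mu >= 1/(s-1) = {1.0 / (s - 1.0):.4g}; "
            "Hugoniot pressure is singular"
        )
    k0 = material.bulk_modulus
    denom = 1.0 - (s - 1.0) * np.minimum(mu, np.inf)
    compress = k0 * mu * (1.0 + mu) / denom**2
    tension = k0 * mu
    p = np.where(mu >= 0.0, compress, tension)
    return float(p) if np.isscalar(density) or np.ndim(density) == 0 else p


def brain_relaxation_modulus(material: ViscoelasticBrain, t):
    """Shear relaxation modulus ``G(t)``, Pa, for ``t >= 0`` (seconds)."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("relaxation time must be non-negative")
    g = material.long_term_shear + (
        material.short_term_shear - material.long_term_shear
    ) * np.exp(-material.decay_const * tt)
    return float(g) if np.ndim(t) == 0 else g


def jwl_pressure(material: JWLProducts, relative_volume, internal_energy_density):
    """JWL pressure, Pa.

    Parameters
    ----------
    relative_volume:
        ``V = rho0 / rho`` (dimensionless, > 0).
    internal_energy_density:
        ``E``, internal energy per unit reference volume, J/m^3 (>= 0).
    """
    v = np.asarray(relative_volume, dtype=float)
    e = np.asarray(internal_energy_density, dtype=float)
    if np.any(v <= 0):
        raise EOSDomainError("JWL: relative volume must be positive")
    if np.any(e < 0):
        raise EOSDomainError("JWL: internal energy must be non-negative")
    w = material.omega
    p = (
        material.A * (1.0 - w / (material.R1 * v)) * np.exp(-material.R1 * v)
        + material.B * (1.0 - w / (material.R2 * v)) * np.exp(-material.R2 * v)
        + w * e / v
    )
    if np.ndim(relative_volume) == 0 and np.ndim(internal_energy_density) == 0:
        return float(p)
    return p


def ideal_gas_pressure(material: IdealGasAir, density, internal_energy_per_mass):
    """``P = (gamma - 1) * rho * e`` for density kg/m^3 and e J/kg."""
    rho = np.asarray(density, dtype=float)
    e = np.asarray(internal_energy_per_mass, dtype=float)
    if np.any(rho <= 0):
        raise EOSDomainError("air: density must be positive")
    if np.any(e < 0):
        raise EOSDomainError("air: internal energy must be non-negative")
    p = (material.gamma - 1.0) * rho * e
    if np.ndim(density) == 0 and np.ndim(internal_energy_per_mass) == 0:
        return float(p)
    return p


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_UNIT_TO_SI = {
    None: 1.0,
    "": 1.0,
    "pa": 1.0,
    "kpa": 1e3,
    "mpa": 1e6,
    "gpa": 1e9,
    "j/kg": 1.0,
    "kj/kg": 1e3,
    "mj/kg": 1e6,
    "kg/m^3": 1.0,
    "kg/m3": 1.0,
    "g/cm^3": 1e3,
    "g/cm3": 1e3,
    "m/s": 1.0,
    "km/s": 1e3,
    "1/s": 1.0,
    "s^-1": 1.0,
    "mm": 1e-3,
    "m": 1.0,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


def parse_quantity(value) -> float:
    """Parse ``34.7 MPa`` / ``1.04 g/cm^3`` / plain numbers to SI floats."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANTITY_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    mag, unit = m.groups()
    key = unit.lower()
    if key not in _UNIT_TO_SI:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(mag) * _UNIT_TO_SI[key]


def default_materials_path() -> Path:
    """Path to the shipped material-constant configuration."""
    return Path(resources.files("blasthead").joinpath("data/materials.yaml"))


def _build_material(name: str, section: dict) -> MaterialModel:
    law = str(section.get("law", "")).lower()
    q = {k: v for k, v in section.items() if k != "law"}
    if law == "linear_elastic":
        return LinearElastic(
            bulk_modulus=parse_quantity(q["K"]),
            shear_modulus=parse_quantity(q["G"]),
            density=parse_quantity(q["rho"]),
            name=name,
        )
    if law in ("shock_eos", "mie_gruneisen"):
        return ShockEOS(
            ref_density=parse_quantity(q["rho0"]),
            bulk_sound_speed=parse_quantity(q["C0"]),
            hugoniot_slope=parse_quantity(q["s"]),
            shear_modulus=parse_quantity(q.get("G", 0.0)),
            name=name,
        )
    if law == "viscoelastic":
        return ViscoelasticBrain(
            bulk_modulus=parse_quantity(q["K"]),
            density=parse_quantity(q["rho"]),
            short_term_shear=parse_quantity(q["G0"]),
            long_term_shear=parse_quantity(q["Ginf"]),
            decay_const=parse_quantity(q["beta"]),
            name=name,
        )
    if law == "jwl":
        return JWLProducts(
            A=parse_quantity(q["A"]),
            B=parse_quantity(q["B"]),
            R1=parse_quantity(q["R1"]),
            R2=parse_quantity(q["R2"]),
            omega=parse_quantity(q["omega"]),
            ref_density=parse_quantity(q["rho0"]),
            detonation_energy_per_mass=parse_quantity(q["e0"]),
        )
    if law == "ideal_gas":
        return IdealGasAir(
            gamma=parse_quantity(q["gamma"]),
            ref_density=parse_quantity(q["rho"]),
            ref_pressure=parse_quantity(q.get("p0", STANDARD_ATMOSPHERE)),
        )
    raise ValueError(f"material {name!r}: unknown constitutive law {section.get('law')!r}")


def load_materials(path: str | Path | None = None) -> dict[str, MaterialModel]:
    """Load a material configuration; ``None`` loads the shipped defaults.

    Returns a mapping from material name (``scalp``, ``skull``, ``csf``,
    ``nasal_cavity``, ``brain``, ``tnt``, ``air``) to its model object.
    """
    cfg_path = default_materials_path() if path is None else Path(path)
    with open(cfg_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{cfg_path}: expected a mapping of material sections")
    return {name: _build_material(name, section) for name, section in raw.items()}
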