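"""Configuration of a swirling-well model and its dimensionless characterization.

A culture well of radius R, filled to mean depth d, rides on an orbital
shaker of orbit radius a and angular rate ω.  Six dimensionless groups
characterize the flow regime:

    E  = a / L            eccentricity
    F  = a ω² / g         forcing (orbital acceleration over gravity)
    Γ  = d / L            shallowness
    Re = L² ω / ν         Reynolds number
    Bo = (ρw − ρa) g (2L)² / σ   Bond number
    We = ρw U² (2L) / σ   Weber number,  U = R ω (rim speed)

where the characteristic length L is the well radius R for a plain well and
the channel width R_well − R_cylinder when a central cylinder (attached to
the base or suspended above it) turns the well into an annular channel.
E and F together control resonance and wave breaking; Bo and We measure the
importance of gravity and inertia relative to surface tension.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import InvalidConfigurationError

GRAVITY = 9.81  # m/s^2

# Surface tension defaults (N/m): water-like medium at 37 °C for plain wells;
# serum-supplemented medium for wells with added cylinders, where surfactant
# proteins lower σ.
SIGMA_PLAIN = 0.072
SIGMA_CYLINDER = 0.047


@dataclass(frozen=True)
class FluidProperties:
    """Liquid and ambient-air properties of the culture medium."""

    density_liquid: float = 1003.0       # kg/m^3
    density_air: float = 1.1115          # kg/m^3
    dynamic_viscosity: float = 0.78e-3   # Pa.s (water-like medium, 37 °C)
    surface_tension: float = SIGMA_PLAIN  # N/m
    kinematic_viscosity_override: Optional[float] = None  # m^2/s

    def __post_init__(self):
        for name in ("density_liquid", "density_air", "dynamic_viscosity", "surface_tension"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be strictly positive")
        if self.kinematic_viscosity_override is not None and self.kinematic_viscosity_override <= 0:
            raise InvalidConfigurationError("kinematic_viscosity_override must be positive")
        if self.density_liquid <= self.density_air:
            raise InvalidConfigurationError("liquid must be denser than air")


@dataclass(frozen=True)
class Cylinder:
    """Central cylinder modification: none, attached to the base, or suspended above it."""

    kind: str = "none"          # {"none", "attached", "suspended"}
    radius: float = 0.0         # m
    gap: Optional[float] = None  # m, suspended only: clearance above the base

    def __post_init__(self):
        if self.kind not in ("none", "attached", "suspended"):
            raise InvalidConfigurationError(f"unknown cylinder kind {self.kind!r}")
        if self.kind != "none" and self.radius <= 0:
            raise InvalidConfigurationError("cylinder radius must be positive")
        if self.kind == "suspended" and (self.gap is None or self.gap <= 0):
            raise InvalidConfigurationError("suspended cylinder needs a positive gap")


@dataclass(frozen=True)
class WellConfig:
    """One swirling-well model variant (geometry, orbit, tilt, fluid)."""

    well_radius: float                   # m
    mean_depth: float                    # m
    orbital_radius: float                # m
    angular_rate: float                  # rad/s
    gravity: float = GRAVITY             # m/s^2
    cylinder: Cylinder = field(default_factory=Cylinder)
    tilt_angle: float = 0.0              # degrees
    fluid: FluidProperties = field(default_factory=FluidProperties)
    name: str = ""

    def __post_init__(self):
        if self.well_radius <= 0:
            raise InvalidConfigurationError("well_radius must be positive")
        if self.mean_depth <= 0:
            raise InvalidConfigurationError("mean_depth must be positive")
        if self.orbital_radius < 0:
            raise InvalidConfigurationError("orbital_radius must be non-negative")
        if self.angular_rate < 0:
            raise InvalidConfigurationError("angular_rate must be non-negative")
        if self.tilt_angle < 0:
            raise InvalidConfigurationError("tilt_angle must be non-negative")
        if self.cylinder.radius >= self.well_radius:
            raise InvalidConfigurationError("cylinder radius must be smaller than well radius")


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless characterization of one configuration (see module docstring)."""

    E: float
    F: float
    gamma: float
    Re: float
    Bo: float
    We: float
    characteristic_length: float  # m
    characteristic_velocity: float  # m/s, U = R_well * omega

    def table_row(self) -> dict:
        """Values rounded to the precision conventionally printed for them:
        integers for Re/Bo/We, two decimals for E/Γ/F."""
        return {
            "Bo": round(self.Bo),
            "We": round(self.We),
            "Re": round(self.Re),
            "E": round(self.E, 2),
            "Gamma": round(self.gamma, 2),
            "F": round(self.F, 2),
        }


def characteristic_length(config: WellConfig) -> float:
    """Characteristic length L: well radius, or channel width with a cylinder.

    With a central cylinder (attached or suspended) the flow is confined to
    an annular channel and the relevant length is R_well − R_cylinder.
    """
    if config.cylinder.kind == "none":
        return config.well_radius
    return config.well_radius - config.cylinder.radius


def kinematic_viscosity(fluid: FluidProperties) -> float:
    """Kinematic viscosity ν in m²/s.

    Uses the explicit override (e.g. for dextran-thickened medium specified
    directly in mm²/s) when present, otherwise μ/ρ.
    """
    if fluid.kinematic_viscosity_override is not None:
        return fluid.kinematic_viscosity_override
    return fluid.dynamic_viscosity / fluid.density_liquid


def compute_dimensionless(config: WellConfig) -> DimensionlessGroups:
    """Compute E, F, Γ, Re, Bo and We for one configuration.

    All groups that contain a length use the substituted characteristic
    length L (channel width for cylinder models); U is always the rim speed
    R_well·ω, so We is its maximum over the well radius.
    """
    L = characteristic_length(config)
    nu = kinematic_viscosity(config.fluid)
    if L <= 0 or nu <= 0:
        raise InvalidConfigurationError("characteristic length and viscosity must be positive")
    f = config.fluid
    omega = config.angular_rate
    U = config.well_radius * omega
    return DimensionlessGroups(
        E=config.orbital_radius / L,
        F=config.orbital_radius * omega**2 / config.gravity,
        gamma=config.mean_depth / L,
        Re=L**2 * omega / nu,
        Bo=(f.density_liquid - f.density_air) * config.gravity * (2 * L) ** 2 / f.surface_tension,
        We=f.density_liquid * U**2 * (2 * L) / f.surface_tension,
        characteristic_length=L,
        characteristic_velocity=U,
    )


def rpm_to_rad_per_s(rpm: float) -> float:
    return rpm * 2 * math.pi / 60.0


# ---------------------------------------------------------------------------
# Config-file loading.  Keys carry explicit unit suffixes; geometry in mm,
# rates in rad/s (or rpm), viscosity override in mm^2/s.
# ---------------------------------------------------------------------------

def well_config_from_dict(data: dict) -> WellConfig:
    """Build a :class:`WellConfig` from a unit-suffixed key-value mapping.

    Recognized keys::

        well_radius_mm, mean_depth_mm, orbital_radius_mm,
        angular_rate_rad_s | rpm, gravity_m_s2, tilt_angle_deg,
        cylinder: {kind, radius_mm, gap_mm},
        fluid: {density_liquid_kg_m3, density_air_kg_m3,
                dynamic_viscosity_pa_s, surface_tension_n_m,
                kinematic_viscosity_mm2_s}
    """
    d = dict(data)
    try:
        if "rpm" in d and "angular_rate_rad_s" not in d:
            omega = rpm_to_rad_per_s(float(d["rpm"]))
        else:
            omega = float(d["angular_rate_rad_s"])
        cyl_d = d.get("cylinder") or {}
        cylinder = Cylinder(
            kind=cyl_d.get("kind", "none"),
            radius=float(cyl_d.get("radius_mm", 0.0)) * 1e-3,
            gap=float(cyl_d["gap_mm"]) * 1e-3 if "gap_mm" in cyl_d else None,
        )
        fl_d = d.get("fluid") or {}
        sigma_default = SIGMA_PLAIN if cylinder.kind == "none" else SIGMA_CYLINDER
        nu_override = (
            float(fl_d["kinematic_viscosity_mm2_s"]) * 1e-6
            if "kinematic_viscosity_mm2_s" in fl_d
            else None
        )
        fluid = FluidProperties(
            density_liquid=float(fl_d.get("density_liquid_kg_m3", 1003.0)),
            density_air=float(fl_d.get("density_air_kg_m3", 1.1115)),
            dynamic_viscosity=float(fl_d.get("dynamic_viscosity_pa_s", 0.78e-3)),
            surface_tension=float(fl_d.get("surface_tension_n_m", sigma_default)),
            kinematic_viscosity_override=nu_override,
        )
        return WellConfig(
            well_radius=float(d["well_radius_mm"]) * 1e-3,
            mean_depth=float(d["mean_depth_mm"]) * 1e-3,
            orbital_radius=float(d["orbital_radius_mm"]) * 1e-3,
            angular_rate=omega,
            gravity=float(d.get("gravity_m_s2", GRAVITY)),
            cylinder=cylinder,
            tilt_angle=float(d.get("tilt_angle_deg", 0.0)),
            fluid=fluid,
            name=str(d.get("name", "")),
        )
    except KeyError as exc:
        raise InvalidConfigurationError(f"missing config key: {exc}") from exc


def load_well_config(path: Union[str, Path]) -> WellConfig:
    """Load a well configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidConfigurationError(f"{path}: expected a mapping at top level")
    return well_config_from_dict(data)
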