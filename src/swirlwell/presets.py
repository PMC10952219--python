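"""Named configurations of the standard swirling-well model variants.

All variants share the baseline orbit (a = 5 mm, 150 rpm ⇒ ω ≈ 15.708 rad/s)
and a 12-well-plate well (R = 11.05 mm); they differ in fill depth, central
cylinder, medium viscosity and tilt.
"""
from __future__ import annotations

from .config import (
    SIGMA_CYLINDER,
    SIGMA_PLAIN,
    Cylinder,
    FluidProperties,
    WellConfig,
)

OMEGA = 15.708  # rad/s (150 rpm)
WELL_RADIUS = 11.05e-3  # m
ORBIT_RADIUS = 5.0e-3  # m

_WATER = FluidProperties(surface_tension=SIGMA_PLAIN)
_SERUM = FluidProperties(surface_tension=SIGMA_CYLINDER)


def _dextran(nu_mm2_s: float) -> FluidProperties:
    """Serum-like medium thickened with dextran to a stated kinematic viscosity."""
    return FluidProperties(
        surface_tension=SIGMA_CYLINDER,
        kinematic_viscosity_override=nu_mm2_s * 1e-6,
    )


def _well(name, depth_mm, cylinder=Cylinder(), tilt=0.0, fluid=_WATER) -> WellConfig:
    return WellConfig(
        well_radius=WELL_RADIUS,
        mean_depth=depth_mm * 1e-3,
        orbital_radius=ORBIT_RADIUS,
        angular_rate=OMEGA,
        cylinder=cylinder,
        tilt_angle=tilt,
        fluid=fluid,
        name=name,
    )


PRESETS: dict[str, WellConfig] = {
    # fill-volume series (767 / 1151 / 1534 µl -> 2 / 3 / 4 mm mean depth)
    "control": _well("control", 2.0),
    "volume_1151ul": _well("volume_1151ul", 3.0),
    "volume_1534ul": _well("volume_1534ul", 4.0),
    # central cylinder attached to the base (8 mm diameter), depth kept at 2 mm
    "cc": _well("cc", 2.0, cylinder=Cylinder("attached", radius=4.0e-3), fluid=_SERUM),
    # 18 mm cylinder suspended 1 or 2 mm above the base, depth raised to 5 mm
    "sc_1mm": _well("sc_1mm", 5.0, cylinder=Cylinder("suspended", 9.0e-3, gap=1.0e-3), fluid=_SERUM),
    "sc_2mm": _well("sc_2mm", 5.0, cylinder=Cylinder("suspended", 9.0e-3, gap=2.0e-3), fluid=_SERUM),
    # suspended cylinder (2 mm gap) with dextran-increased viscosity
    "sc_nu2.2": _well("sc_nu2.2", 5.0, cylinder=Cylinder("suspended", 9.0e-3, gap=2.0e-3), fluid=_dextran(2.2)),
    "sc_nu3.4": _well("sc_nu3.4", 5.0, cylinder=Cylinder("suspended", 9.0e-3, gap=2.0e-3), fluid=_dextran(3.4)),
    "sc_nu4.0": _well("sc_nu4.0", 5.0, cylinder=Cylinder("suspended", 9.0e-3, gap=2.0e-3), fluid=_dextran(4.0)),
    # tilted variants (surface tension omitted in the source simulations;
    # σ kept at the plain-well value here — it does not enter the flow model)
    "tilt_767ul_2.5deg": _well("tilt_767ul_2.5deg", 2.0, tilt=2.5),
    "tilt_767ul_5deg": _well("tilt_767ul_5deg", 2.0, tilt=5.0),
    "tilt_1534ul_5deg": _well("tilt_1534ul_5deg", 4.0, tilt=5.0),
    "tilt_1534ul_10deg": _well("tilt_1534ul_10deg", 4.0, tilt=10.0),
}


def get_preset(name: str) -> WellConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
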