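"""Synthetic WSS vector time-series and disc fields.

The generator emulates the flow regimes a swirling well produces at its
base, so the whole analysis chain can be exercised without a CFD solver:

* near the well centre the instantaneous WSS vector sweeps a uniform
  *circular* locus (purely multidirectional flow);
* near the edge the locus is an elongated, biased *elliptic* one — nearly
  bidirectional along the tangential direction, spending more of the cycle
  in the wave-travel (negative tangential) direction;
* *uniaxial_oscillatory* and *steady* regimes are the analytic limiting
  cases used to separate OSI from CFI;
* a disc field repeats one radial family of loci around the circumference
  with an azimuthal phase shift (the rotating-wave symmetry), and a tilted
  field breaks that symmetry with an azimuthal amplitude modulation.

Everything is built in the local radial/tangential frame and is exact by
construction: the series at azimuth θ *is* the series at azimuth 0 with its
phase advanced by θ and its frame rotated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .series import Frame, WSSSeries

REGIMES = ("circular", "elliptic", "uniaxial_oscillatory", "steady")


@dataclass(frozen=True)
class LocusSpec:
    """Parameters of one locus regime.

    ``asymmetry`` ∈ [0, 1) warps the phase so more of the cycle is spent at
    negative tangential stress (the wave-travel bias seen at the well edge);
    it is a free shaping knob, not calibrated to any particular well.
    ``steady_offset`` adds a constant vector in the local (radial,
    tangential, normal) frame; for the ``steady`` regime it is the whole
    signal.  Noise is per-component Gaussian, seeded, default off.
    """

    regime: str
    amplitude_tangential: float = 0.0  # Pa
    amplitude_radial: float = 0.0      # Pa
    steady_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Pa, local frame
    asymmetry: float = 0.0
    noise_sd: float = 0.0              # Pa
    seed: Optional[int] = None
    phase: float = 0.0                 # rad, initial phase of the cycle

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.amplitude_tangential < 0 or self.amplitude_radial < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValueError("asymmetry must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.regime == "circular" and not math.isclose(
            self.amplitude_tangential, self.amplitude_radial, rel_tol=0, abs_tol=0.0
        ):
            raise ValueError("circular regime requires equal tangential and radial amplitudes")


def circular(amplitude: float, **kw) -> LocusSpec:
    """Uniform rotating locus of constant magnitude (well-centre regime)."""
    return LocusSpec("circular", amplitude, amplitude, **kw)


def elliptic(amplitude_tangential: float, amplitude_radial: float, **kw) -> LocusSpec:
    """Axis-aligned elliptic locus (elongated edge regime)."""
    return LocusSpec("elliptic", amplitude_tangential, amplitude_radial, **kw)


def uniaxial(amplitude: float, **kw) -> LocusSpec:
    """Purely uniaxial oscillation along the tangential direction."""
    return LocusSpec("uniaxial_oscillatory", amplitude_tangential=amplitude, **kw)


def steady(offset: Sequence[float], **kw) -> LocusSpec:
    """Constant stress vector (local radial, tangential, normal components)."""
    off = tuple(float(c) for c in offset)
    return LocusSpec("steady", steady_offset=off, **kw)


def _warped_phase(psi: np.ndarray, asymmetry: float) -> np.ndarray:
    """Monotone phase warp θ(ψ) = ψ − asym·sin ψ.

    dθ/dψ = 1 − asym·cos ψ is smallest at ψ ≡ 0, so uniform time samples
    cluster where the locus parametrization puts its negative-tangential
    extreme (θ ≈ 0 below).
    """
    return psi - asymmetry * np.sin(psi)


def _local_components(spec: LocusSpec, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(radial, tangential) stress components at phase samples ψ."""
    theta = _warped_phase(psi, spec.asymmetry)
    if spec.regime == "circular" or spec.regime == "elliptic":
        rad = spec.amplitude_radial * np.sin(theta)
        tan = -spec.amplitude_tangential * np.cos(theta)
    elif spec.regime == "uniaxial_oscillatory":
        rad = np.zeros_like(theta)
        tan = -spec.amplitude_tangential * np.cos(theta)
    else:  # steady
        rad = np.zeros_like(theta)
        tan = np.zeros_like(theta)
    return rad, tan


def make_locus(
    spec: LocusSpec,
    n_samples: int = 360,
    period: float = 0.4,
    frame: Optional[Frame] = None,
    phase_offset: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> WSSSeries:
    """Generate one point's WSS series over exactly one cycle.

    Samples are uniform in time, 360 per cycle by default (ample quadrature
    accuracy for the smooth loci generated here; configurable).  The normal
    component is identically zero: the base is flat and shear is in-plane.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    if period <= 0:
        raise ValueError("period must be positive")
    frame = frame or Frame.default()
    times = np.arange(n_samples) * (period / n_samples)
    psi = 2 * math.pi * times / period + spec.phase + phase_offset
    rad, tan = _local_components(spec, psi)
    off_r, off_t, off_n = spec.steady_offset
    local = np.stack(
        [rad + off_r, tan + off_t, np.full(n_samples, off_n)], axis=1
    )
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        local = local + rng.normal(0.0, spec.noise_sd, size=local.shape)
    basis = np.stack([frame.radial, frame.tangential, frame.normal], axis=0)
    vectors = local @ basis
    return WSSSeries(times=times, vectors=vectors, period=period, frame=frame)


# ---------------------------------------------------------------------------
# disc fields
# ---------------------------------------------------------------------------

RadialProfileSpec = Union[dict, Callable[[float], LocusSpec]]


@dataclass(frozen=True)
class FieldPoint:
    """One mesh point of a disc field."""

    r: float        # m
    theta: float    # rad
    series: Optional[WSSSeries]  # None when masked (e.g. under an attached cylinder)

    @property
    def x(self) -> float:
        return self.r * math.cos(self.theta)

    @property
    def y(self) -> float:
        return self.r * math.sin(self.theta)

    @property
    def masked(self) -> bool:
        return self.series is None


@dataclass(frozen=True)
class DiscField:
    """WSS series on a polar mesh over the well base."""

    points: tuple[FieldPoint, ...]
    well_radius: float
    period: float
    mask_radius: float = 0.0       # attached-cylinder footprint: r < mask_radius masked
    tilt_angle: float = 0.0        # degrees
    tilt_phase: float = 0.0        # rad, azimuth of the base's high point

    def __post_init__(self):
        if not self.points:
            raise ValueError("field has no points")

    @property
    def active_points(self) -> tuple[FieldPoint, ...]:
        return tuple(p for p in self.points if not p.masked)


def _resolve_profile(profile: RadialProfileSpec) -> Callable[[float], LocusSpec]:
    if callable(profile):
        return profile
    table = sorted(profile.items())

    def lookup(r: float) -> LocusSpec:
        # nearest-radius lookup for dict-style profiles
        return min(table, key=lambda kv: abs(kv[0] - r))[1]

    return lookup


def _spawn_seed(base: Optional[int], index: int) -> Optional[int]:
    if base is None:
        return None
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def make_disc_field(
    radial_profile: RadialProfileSpec,
    mesh_radii: Sequence[float],
    mesh_azimuths: Sequence[float],
    period: float = 0.4,
    n_samples: int = 360,
    well_radius: Optional[float] = None,
    mask_radius: float = 0.0,
) -> DiscField:
    """Rotating-wave disc field: one locus family repeated around the circumference.

    Every point at radius r sees the same temporal pattern in its local
    radial/tangential frame; the point at azimuth θ sees it with its phase
    advanced by θ (one full cycle per revolution of the wave).  Points with
    r < ``mask_radius`` (an attached cylinder's footprint) carry no series.
    """
    radii = np.asarray(list(mesh_radii), dtype=float)
    azimuths = np.asarray(list(mesh_azimuths), dtype=float)
    if radii.size == 0 or azimuths.size == 0:
        raise ValueError("mesh must contain at least one radius and one azimuth")
    R = well_radius if well_radius is not None else float(radii.max())
    if np.any(radii <= 0) or np.any(radii > R * (1 + 1e-12)):
        raise ValueError("mesh radii must lie within (0, R]")
    lookup = _resolve_profile(radial_profile)
    points = []
    for i, r in enumerate(radii):
        spec = lookup(float(r))
        for j, th in enumerate(azimuths):
            if r < mask_radius:
                points.append(FieldPoint(r=float(r), theta=float(th), series=None))
                continue
            pt_spec = spec
            if spec.noise_sd > 0:
                pt_spec = replace(spec, seed=_spawn_seed(spec.seed, i * len(azimuths) + j))
            series = make_locus(
                pt_spec,
                n_samples=n_samples,
                period=period,
                frame=Frame.at_azimuth(float(th)),
                phase_offset=float(th),
            )
            points.append(FieldPoint(r=float(r), theta=float(th), series=series))
    return DiscField(
        points=tuple(points), well_radius=R, period=period, mask_radius=mask_radius
    )


def make_tilted_field(
    base_profile: RadialProfileSpec,
    mesh_radii: Sequence[float],
    mesh_azimuths: Sequence[float],
    modulation_depth: float = 0.0,
    modulation_phase: float = 0.0,
    period: float = 0.4,
    n_samples: int = 360,
    well_radius: Optional[float] = None,
    mask_radius: float = 0.0,
    tilt_angle: float = 5.0,
) -> DiscField:
    """Tilt-broken field: amplitudes modulated by 1 + depth·cos(θ − phase).

    Tilting the well base breaks the rotating-wave symmetry; the dominant
    first-order effect emulated here is an azimuthal modulation of stress
    amplitude, maximal at the high point of the base (azimuth
    ``modulation_phase``).  ``modulation_depth = 0`` reduces exactly to
    :func:`make_disc_field`.
    """
    if not 0.0 <= modulation_depth < 1.0:
        raise ValueError("modulation_depth must lie in [0, 1)")
    base = make_disc_field(
        base_profile, mesh_radii, mesh_azimuths, period=period,
        n_samples=n_samples, well_radius=well_radius, mask_radius=mask_radius,
    )
    if modulation_depth == 0.0:
        return replace(base, tilt_angle=tilt_angle, tilt_phase=modulation_phase)
    points = []
    for p in base.points:
        if p.masked:
            points.append(p)
            continue
        scale = 1.0 + modulation_depth * math.cos(p.theta - modulation_phase)
        points.append(FieldPoint(r=p.r, theta=p.theta, series=p.series.scaled(scale)))
    return DiscField(
        points=tuple(points),
        well_radius=base.well_radius,
        period=period,
        mask_radius=mask_radius,
        tilt_angle=tilt_angle,
        tilt_phase=modulation_phase,
    )
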