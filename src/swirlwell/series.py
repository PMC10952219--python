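"""Time series of instantaneous wall-shear-stress vectors at one point.

A :class:`WSSSeries` holds the WSS vector sampled uniformly over exactly one
cycle of the orbital motion, together with the local frame (outward radial
direction, tangential direction, wall normal) needed to build polar loci in
the conventions used for swirling-well flow: the radial component is negative
when the stress points toward the well centre, and the tangential component
is negative in the direction of wave travel.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MIN_SAMPLES = 8
# relative tolerance on "times cover exactly one period"
_PERIOD_RTOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """Local orthonormal frame at a point on the well base.

    ``radial`` points outward (away from the well centre); ``tangential`` is
    the in-plane direction whose *negative* sense is the dominant direction
    of wave travel; ``normal`` is the wall normal (out of the fluid-facing
    base, +z for a flat horizontal base).
    """

    radial: np.ndarray
    tangential: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        for name in ("radial", "tangential", "normal"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} direction must be a 3-vector")
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise ValueError(f"{name} direction must be unit length")
            object.__setattr__(self, name, v)
        if abs(self.normal @ self.radial) > 1e-9 or abs(self.normal @ self.tangential) > 1e-9:
            raise ValueError("normal must be orthogonal to the in-plane directions")

    @classmethod
    def at_azimuth(cls, theta: float, wave_ccw: bool = True) -> "Frame":
        """Frame at azimuth ``theta`` on a flat base.

        For a wave travelling counter-clockwise (the usual orbit sense) the
        tangential unit vector is the *clockwise* in-plane direction, so that
        stress components along the wave come out negative.
        """
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        ccw = np.array([-np.sin(theta), np.cos(theta), 0.0])
        e_t = -ccw if wave_ccw else ccw
        return cls(radial=e_r, tangential=e_t, normal=np.array([0.0, 0.0, 1.0]))

    @classmethod
    def default(cls) -> "Frame":
        return cls.at_azimuth(0.0)


@dataclass(frozen=True)
class WSSSeries:
    """Uniformly sampled WSS vectors over exactly one cycle.

    Parameters
    ----------
    times : (n,) array, s
        Uniform sample times; the last sample is one step short of
        ``times[0] + period`` (the cycle is periodic, so the endpoint is
        not duplicated).
    vectors : (n, 3) array, Pa
        Instantaneous WSS vectors (τx, τy, τz) in the global frame.
    period : float, s
        Cycle duration T.
    frame : Frame
        Local radial/tangential/normal directions at the point.
    """

    times: np.ndarray
    vectors: np.ndarray
    period: float
    frame: Frame = field(default_factory=Frame.default)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.vectors, dtype=float)
        if t.ndim != 1 or len(t) < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples, got {t.size}")
        if v.shape != (len(t), 3):
            raise ValueError("vectors must have shape (n_samples, 3)")
        if self.period <= 0:
            raise ValueError("period must be positive")
        dt = np.diff(t)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=0)):
            raise ValueError("times must be strictly increasing and uniform")
        span = t[-1] - t[0] + dt[0]
        if abs(span - self.period) > _PERIOD_RTOL * self.period + 1e-15:
            raise ValueError(
                f"samples must cover exactly one period: span {span!r} != T {self.period!r}"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vectors", v)

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def scaled(self, k: float) -> "WSSSeries":
        """Series with every vector multiplied by ``k`` (viscosity-like scaling)."""
        return replace(self, vectors=self.vectors * k)

    def rotated(self, angle: float) -> "WSSSeries":
        """Series rotated in-plane by ``angle`` about the wall normal."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return replace(self, vectors=self.vectors @ rot.T)
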