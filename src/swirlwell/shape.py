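"""Polar loci, ellipse fitting and the Shape Index.

The tip of the instantaneous WSS vector, plotted in the local
(tangential, radial) frame over one cycle, traces a closed locus whose
shape summarizes multidirectionality: a circle centred on the origin means
the stress sweeps all directions at constant magnitude, a thin elongated
loop means nearly bidirectional flow.  Sign conventions: negative radial
values point toward the well centre; negative tangential values point in
the direction of wave travel.

Circularity is quantified by fitting an ellipse to the locus and computing
the Shape Index

    SI = 4πA / P²,

1 for a circle and 0 for a straight segment.  The ellipse fit is the
direct least-squares conic fit (ellipse-specific, non-iterative); loci too
elongated to support an ellipse — where a fitter would simply fail — are
returned as zero-minor-axis segments with a ``degenerate`` flag, so SI = 0
is reported instead of a gap.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.measure import EllipseModel

from .series import WSSSeries

MIN_POINTS = 6
#: singular-value ratio below which a locus is treated as collinear
_COLLINEAR_RTOL = 1e-9


@dataclass(frozen=True)
class PolarLocus:
    """Closed locus of (tangential, radial) stress pairs over one cycle."""

    points: np.ndarray        # (n, 2): [:, 0] tangential Pa, [:, 1] radial Pa
    sample_interval: float    # s

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 8:
            raise ValueError("locus needs at least 8 (tangential, radial) pairs")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        object.__setattr__(self, "points", pts)

    @property
    def tangential(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def radial(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class EllipseFit:
    """Fitted ellipse parameters (Pa units inherited from the locus)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]   # (major, minor), major >= minor
    orientation: float               # rad, major-axis angle in [0, π)
    rms_residual: float
    degenerate: bool = False

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    @property
    def perimeter(self) -> float:
        return ellipse_perimeter(*self.semi_axes)


def ellipse_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by Ramanujan's second approximation.

    Relative error is below 1e-9 for aspect ratios up to ~20 and worst-case
    ~4e-4 for a fully degenerate segment, far inside the needs of a shape
    index read off a fitted locus.
    """
    if a < 0 or b < 0:
        raise ValueError("semi-axes must be non-negative")
    if a == 0 and b == 0:
        return 0.0
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def locus_from_series(series: WSSSeries) -> PolarLocus:
    """Project a WSS series onto its local frame to build the polar locus.

    The frame's radial direction points outward and its tangential direction
    opposes wave travel, which yields exactly the plotting conventions above.
    """
    tang = series.vectors @ series.frame.tangential
    rad = series.vectors @ series.frame.radial
    return PolarLocus(points=np.stack([tang, rad], axis=1), sample_interval=series.dt)


def _segment_fit(pts: np.ndarray) -> EllipseFit:
    """Best-fit zero-minor-axis 'ellipse' (a segment) for collinear loci."""
    center = pts.mean(axis=0)
    centred = pts - center
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    proj = centred @ axis
    perp = centred @ vt[1] if vt.shape[0] > 1 else np.zeros(len(pts))
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(np.abs(proj).max()), 0.0),
        orientation=float(np.mod(math.atan2(axis[1], axis[0]), math.pi)),
        rms_residual=float(np.sqrt(np.mean(perp**2))),
        degenerate=True,
    )


def fit_ellipse(locus: PolarLocus) -> EllipseFit:
    """Direct least-squares ellipse fit of a polar locus.

    Near-collinear loci (the highly elongated edge plots that defeat a
    conic fitter) come back with ``degenerate=True`` and the best-fit
    segment as a zero-minor-axis ellipse.
    """
    pts = np.asarray(locus.points, dtype=float)
    if len(pts) < MIN_POINTS:
        raise ValueError(f"ellipse fit needs at least {MIN_POINTS} points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals[0] == 0.0 or svals[-1] / svals[0] < _COLLINEAR_RTOL:
        return _segment_fit(pts)
    # fit centred and scaled to unit size: the conic scatter matrix is badly
    # conditioned for loci far from the origin or of extreme magnitude.
    # Certain orientations defeat the conic->geometric conversion; a small
    # rotation of the data (undone afterwards) sidesteps them.
    scale = float(np.abs(centred).max())
    norm = centred / scale
    model, delta = None, 0.0
    for delta in (0.0, math.radians(15.0), math.radians(30.0)):
        c, s = math.cos(delta), math.sin(delta)
        rot = np.array([[c, -s], [s, c]])
        try:
            with np.errstate(invalid="ignore", divide="ignore"):
                model = EllipseModel.from_estimate(norm @ rot.T)
        except (TypeError, ValueError):
            model = None
        if model:
            break
    if not model:
        return _segment_fit(pts)
    a, b = (float(v) * scale for v in model.axis_lengths)  # major, minor
    theta = model.theta if a >= b else model.theta + math.pi / 2
    if a < b:
        a, b = b, a
    if not math.isfinite(theta):
        theta = delta  # a circle has no preferred axis
    c, s = math.cos(delta), math.sin(delta)
    rot = np.array([[c, -s], [s, c]])
    center = rot.T @ np.array(model.center, dtype=float)
    rms = scale * float(np.sqrt(np.mean(model.residuals(norm @ rot.T) ** 2)))
    return EllipseFit(
        center=(
            float(center[0] * scale + centroid[0]),
            float(center[1] * scale + centroid[1]),
        ),
        semi_axes=(a, b),
        orientation=float(np.mod(theta - delta, math.pi)),
        rms_residual=rms,
        degenerate=False,
    )


def shape_index(fit: EllipseFit) -> float:
    """Shape Index SI = 4πA/P² of a fitted ellipse, clipped to [0, 1].

    A degenerate (segment) fit has SI = 0 by definition; a zero-perimeter
    fit (a point) has no shape to index and raises.
    """
    if fit.degenerate:
        return 0.0
    P = fit.perimeter
    if P == 0.0:
        raise ValueError("zero-perimeter fit has no shape index")
    return float(np.clip(4 * math.pi * fit.area / P**2, 0.0, 1.0))


def locus_shape_index(series: WSSSeries) -> tuple[float, EllipseFit]:
    """Convenience: series → polar locus → ellipse fit → (SI, fit)."""
    fit = fit_ellipse(locus_from_series(series))
    return shape_index(fit), fit
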