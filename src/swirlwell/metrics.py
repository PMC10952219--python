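"""Cycle-integral wall-shear-stress metrics and characteristic directions.

Seven scalar metrics reduce one cycle of the instantaneous WSS vector τ⃗(t)
at a point to numbers with established physiological interpretations:

* ``tawss``        — time-average of |τ⃗|, the overall shear magnitude.
* ``mag_mean_wss`` — |⟨τ⃗⟩|, magnitude of the cycle-mean vector.
* ``osi``          — ½(1 − MagMeanWSS/TAWSS) ∈ [0, 0.5]; 0 for flow of fixed
  direction, 0.5 when opposing stresses cancel the mean entirely.
* ``transwss``     — time-average of |τ⃗ · (n⃗ × m̂)|, the absolute component
  perpendicular to the mean direction m̂; cross-flow in Pa.
* ``cfi``          — the same with unit-normalized instantaneous vectors:
  angle-only cross-flow, ∈ [0, 1].
* ``transwss_min`` / ``cfi_min`` — the same two quantities minimized over
  the in-plane reference axis, modelling cells that orient themselves to
  minimize the flow across their long axis.

Four directions accompany them: the mean-vector direction, the modal
direction (most populated of 18 orientation bins over the cycle), and the
two minimizing axes.

For a perfectly circular locus the analytic limits are OSI = 0.5,
CFI = CFImin = 2/π ≈ 0.64 and transWSS = transWSSmin = (2/π)·TAWSS; CFI can
exceed 2/π when large nearly-opposed vectors leave a small perpendicular
mean, but OSI can never exceed 0.5.

Sampling is uniform over one period, so cycle integrals are computed as
plain arithmetic means over samples (the trapezoid rule on a closed periodic
cycle reduces to the same thing, with spectral accuracy for smooth loci).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateReferenceError, UndefinedMetricError
from .series import WSSSeries

#: grid step (rad) of the coarse scan over the reference axis angle
_AXIS_GRID_STEP = math.radians(0.25)
#: relative spread below which the axis objective is considered flat
_FLAT_RTOL = 1e-12
#: |mean vector| below this fraction of TAWSS is roundoff, not a direction
_DEGENERATE_MEAN_RTOL = 1e-12

TWO_OVER_PI = 2.0 / math.pi


@dataclass(frozen=True)
class MetricSet:
    """The seven metrics and four directions for one point.

    Metrics that are undefined for the series (zero total shear, or a
    vanishing mean vector leaving no reference direction) are NaN, with a
    reason code in ``undefined`` — never silently zero.  Axis angles are
    reported in [0, π) (a reference axis has no sign); directions in [0, 2π).
    """

    tawss: float
    mag_mean_wss: float
    osi: float
    transwss: float
    cfi: float
    transwss_min: float
    cfi_min: float
    dir_mean: float
    dir_modal: float
    dir_transwss_min: float
    dir_cfi_min: float
    mean_vector: np.ndarray
    undefined: dict = field(default_factory=dict)
    modal_tie: bool = False
    excluded_samples: int = 0

    def as_dict(self) -> dict:
        return {
            "tawss": self.tawss,
            "mag_mean_wss": self.mag_mean_wss,
            "osi": self.osi,
            "transwss": self.transwss,
            "cfi": self.cfi,
            "transwss_min": self.transwss_min,
            "cfi_min": self.cfi_min,
            "dir_mean": self.dir_mean,
            "dir_modal": self.dir_modal,
            "dir_transwss_min": self.dir_transwss_min,
            "dir_cfi_min": self.dir_cfi_min,
        }


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def mean_vector(series: WSSSeries) -> np.ndarray:
    """Cycle-average WSS vector ⟨τ⃗⟩ (Pa)."""
    return series.vectors.mean(axis=0)


def tawss(series: WSSSeries) -> float:
    """Time-average WSS magnitude (Pa)."""
    return float(np.linalg.norm(series.vectors, axis=1).mean())


def mag_mean_wss(series: WSSSeries) -> float:
    """Magnitude of the cycle-average WSS vector (Pa)."""
    return float(np.linalg.norm(mean_vector(series)))


def osi(series: WSSSeries) -> float:
    """Oscillatory shear index ½(1 − MagMeanWSS/TAWSS) ∈ [0, 0.5]."""
    t = tawss(series)
    if t <= 0.0:
        raise UndefinedMetricError("osi", "zero TAWSS")
    return float(np.clip(0.5 * (1.0 - mag_mean_wss(series) / t), 0.0, 0.5))


def _mean_is_degenerate(series: WSSSeries) -> bool:
    """True when the cycle-mean vector is zero to within roundoff of TAWSS."""
    return np.linalg.norm(mean_vector(series)) <= _DEGENERATE_MEAN_RTOL * tawss(series)


def _reference_perpendicular(series: WSSSeries) -> np.ndarray:
    """Unit vector n⃗ × m̂ perpendicular to the mean direction, in the wall plane."""
    m = mean_vector(series)
    if _mean_is_degenerate(series):
        raise DegenerateReferenceError("mean-direction reference")
    return np.cross(series.frame.normal, m / np.linalg.norm(m))


def transwss(series: WSSSeries) -> float:
    """Transverse WSS: cycle-average |τ⃗ · (n⃗ × m̂)| (Pa), m̂ the mean direction."""
    try:
        p = _reference_perpendicular(series)
    except DegenerateReferenceError:
        raise DegenerateReferenceError("transwss") from None
    return float(np.abs(series.vectors @ p).mean())


def _unit_vectors(series: WSSSeries) -> tuple[np.ndarray, int]:
    """Unit instantaneous vectors, excluding zero-magnitude samples."""
    mags = np.linalg.norm(series.vectors, axis=1)
    keep = mags > 0.0
    excluded = int((~keep).sum())
    if not keep.any():
        raise UndefinedMetricError("cfi", "all samples have zero magnitude")
    return series.vectors[keep] / mags[keep, None], excluded


def cfi(series: WSSSeries) -> float:
    """Cross-flow index: CFI = ⟨|τ̂ · (n⃗ × m̂)|⟩ ∈ [0, 1].

    Zero-magnitude samples carry no direction and are excluded from the
    average.
    """
    try:
        p = _reference_perpendicular(series)
    except DegenerateReferenceError:
        raise DegenerateReferenceError("cfi") from None
    units, _ = _unit_vectors(series)
    return float(np.abs(units @ p).mean())


# ---------------------------------------------------------------------------
# minimized variants: min over the in-plane reference axis angle
# ---------------------------------------------------------------------------

def _axis_objective(vectors: np.ndarray, normal: np.ndarray):
    """Return f(φ) = mean |v⃗ · (n⃗ × (cosφ, sinφ, 0))|, vectorized over φ."""

    def f(phis: np.ndarray) -> np.ndarray:
        phis = np.atleast_1d(np.asarray(phis, dtype=float))
        axes = np.stack([np.cos(phis), np.sin(phis), np.zeros_like(phis)], axis=1)
        perp = np.cross(normal[None, :], axes)  # (m, 3)
        return np.abs(vectors @ perp.T).mean(axis=0)

    return f

def _minimize_over_axis(vectors: np.ndarray, normal: np.ndarray,
                        extra_candidates: tuple = ()) -> tuple[float, Optional[float], bool]:
    """Minimize the axis objective over φ ∈ [0, π).

    The objective has period π.  A coarse grid scan (step 0.25°, plus any
    caller-supplied candidate angles such as the mean-direction axis) is
    refined by bounded scalar minimization around the best grid point.

    Returns ``(value, axis, flat)``; ``axis`` is None and ``flat`` True when
    the objective is constant to within relative tolerance (e.g. a perfectly
    circular locus), in which case the axis is physically indeterminate.
    """
    f = _axis_objective(vectors, normal)
    grid = np.arange(0.0, math.pi, _AXIS_GRID_STEP)
    if extra_candidates:
        grid = np.concatenate([grid, np.mod(extra_candidates, math.pi)])
    values = f(grid)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= _FLAT_RTOL * max(hi, 1e-300):
        return lo, None, True
    i = int(values.argmin())
    phi0 = float(grid[i])
    res = minimize_scalar(
        lambda p: float(f(p)[0]),
        bounds=(phi0 - _AXIS_GRID_STEP, phi0 + _AXIS_GRID_STEP),
        method="bounded",
        options={"xatol": 1e-8},
    )
    # never report worse than the best explicit candidate
    if res.fun <= lo:
        return float(res.fun), float(np.mod(res.x, math.pi)), False
    return lo, float(np.mod(phi0, math.pi)), False


def _mean_axis_candidate(series: WSSSeries) -> tuple:
    if _mean_is_degenerate(series):
        return ()
    m = mean_vector(series)
    return (math.atan2(m[1], m[0]),)


def transwss_min(series: WSSSeries) -> tuple[float, Optional[float]]:
    """Minimized transverse WSS and its axis angle in [0, π).

    Defined for every series (no mean-direction reference needed).  The axis
    is None when the objective is flat (direction indeterminate, e.g. a
    uniform circular locus).
    """
    value, axis, _ = _minimize_over_axis(
        series.vectors, series.frame.normal, _mean_axis_candidate(series)
    )
    return value, axis


def cfi_min(series: WSSSeries) -> tuple[float, Optional[float]]:
    """Minimized cross-flow index and its axis angle in [0, π)."""
    units, _ = _unit_vectors(series)
    value, axis, _ = _minimize_over_axis(units, series.frame.normal, _mean_axis_candidate(series))
    return value, axis


# ---------------------------------------------------------------------------
# directions
# ---------------------------------------------------------------------------

def modal_direction(series: WSSSeries, n_bins: int = 18) -> tuple[float, bool]:
    """Centre angle of the most populated orientation bin over [0, 2π).

    Instantaneous vector orientations (full direction, not axis) are
    histogrammed into ``n_bins`` left-closed bins of width 2π/n_bins; the
    returned flag is True when several bins tie for the maximum (ties break
    toward the lower bin index).  Zero-magnitude samples carry no direction
    and are skipped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    v = series.vectors
    mags = np.linalg.norm(v[:, :2], axis=1)
    angles = np.mod(np.arctan2(v[mags > 0, 1], v[mags > 0, 0]), 2 * math.pi)
    width = 2 * math.pi / n_bins
    idx = np.minimum((angles / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    best = int(counts.argmax())
    tie = int((counts == counts[best]).sum()) > 1
    return (best + 0.5) * width, tie


def mean_direction(series: WSSSeries) -> float:
    """In-plane angle of the cycle-mean vector, in [0, 2π)."""
    m = mean_vector(series)
    if _mean_is_degenerate(series) or np.linalg.norm(m[:2]) == 0.0:
        raise DegenerateReferenceError("dir_mean")
    return float(np.mod(math.atan2(m[1], m[0]), 2 * math.pi))


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def compute_metric_set(series: WSSSeries, n_modal_bins: int = 18) -> MetricSet:
    """All seven metrics and four directions for one series.

    Metrics whose reference does not exist for this series are recorded as
    NaN with a reason code in ``MetricSet.undefined``.
    """
    undefined: dict[str, str] = {}

    t = tawss(series)
    mm = mag_mean_wss(series)
    mvec = mean_vector(series)

    def _try(name, fn):
        try:
            return fn()
        except UndefinedMetricError as exc:
            undefined[name] = exc.reason
            return math.nan

    osi_v = _try("osi", lambda: osi(series))
    trans_v = _try("transwss", lambda: transwss(series))
    cfi_v = _try("cfi", lambda: cfi(series))
    dir_mean_v = _try("dir_mean", lambda: mean_direction(series))

    try:
        units, excluded = _unit_vectors(series)
    except UndefinedMetricError as exc:
        units, excluded = None, series.n_samples
        undefined["cfi_min"] = exc.reason

    cand = _mean_axis_candidate(series)
    tmin_v, tmin_axis, _ = _minimize_over_axis(series.vectors, series.frame.normal, cand)
    if units is not None:
        cmin_v, cmin_axis, _ = _minimize_over_axis(units, series.frame.normal, cand)
    else:
        cmin_v, cmin_axis = math.nan, None

    modal_v, tie = modal_direction(series, n_bins=n_modal_bins)

    return MetricSet(
        tawss=t,
        mag_mean_wss=mm,
        osi=osi_v,
        transwss=trans_v,
        cfi=cfi_v,
        transwss_min=tmin_v,
        cfi_min=cmin_v,
        dir_mean=dir_mean_v,
        dir_modal=modal_v,
        dir_transwss_min=math.nan if tmin_axis is None else tmin_axis,
        dir_cfi_min=math.nan if cmin_axis is None else cmin_axis,
        mean_vector=mvec,
        undefined=undefined,
        modal_tie=tie,
        excluded_samples=excluded,
    )
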