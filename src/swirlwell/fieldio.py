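"""Reading and writing WSS field time-series.

The on-disk dialect is a long-format CSV with one row per (point, time)
sample and columns::

    point_id, x_m, y_m, time_s, tau_x_pa, tau_y_pa, tau_z_pa

Sampling must be uniform per point.  Inputs covering several cycles are
truncated to the final cycle (start-up transients live in the earlier
cycles; only the settled last cycle is analysed).  Round-trips are lossless
at double precision.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import FieldFormatError
from .series import Frame, WSSSeries
from .synthetic import DiscField, FieldPoint

COLUMNS = ["point_id", "x_m", "y_m", "time_s", "tau_x_pa", "tau_y_pa", "tau_z_pa"]
#: tolerance on time-step uniformity, relative to the period
DT_RTOL = 1e-6


def write_field(field: DiscField, path: Union[str, Path]) -> None:
    """Write a field to the CSV dialect (masked points are omitted)."""
    rows = []
    for i, p in enumerate(field.points):
        if p.masked:
            continue
        s = p.series
        rows.append(
            pd.DataFrame(
                {
                    "point_id": i,
                    "x_m": p.x,
                    "y_m": p.y,
                    "time_s": s.times,
                    "tau_x_pa": s.vectors[:, 0],
                    "tau_y_pa": s.vectors[:, 1],
                    "tau_z_pa": s.vectors[:, 2],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _point_series(pid, group: pd.DataFrame, period: Optional[float]) -> tuple[float, float, WSSSeries]:
    t = group["time_s"].to_numpy()
    order = np.argsort(t)
    t = t[order]
    v = group[["tau_x_pa", "tau_y_pa", "tau_z_pa"]].to_numpy()[order]
    if len(t) < 8:
        raise FieldFormatError(f"point {pid}: fewer than 8 samples")
    dt = np.diff(t)
    if dt.min() <= 0:
        raise FieldFormatError(f"point {pid}: duplicate or non-increasing times")
    T_ref = period if period is not None else t[-1] - t[0] + dt[0]
    if np.abs(dt - dt[0]).max() > DT_RTOL * T_ref:
        raise FieldFormatError(f"point {pid}: non-uniform time step")
    if period is not None:
        n_cycle = int(round(period / dt[0]))
        if n_cycle < 8 or n_cycle > len(t):
            raise FieldFormatError(
                f"point {pid}: period {period} not covered by {len(t)} samples at dt {dt[0]}"
            )
        t, v = t[-n_cycle:], v[-n_cycle:]
        T = n_cycle * dt[0]
    else:
        T = t[-1] - t[0] + dt[0]
    x = float(group["x_m"].iloc[0])
    y = float(group["y_m"].iloc[0])
    frame = Frame.at_azimuth(math.atan2(y, x))
    return x, y, WSSSeries(times=t - t[0], vectors=v, period=T, frame=frame)


def read_field(
    path: Union[str, Path],
    format: str = "csv",
    period: Optional[float] = None,
    decimate: int = 1,
) -> DiscField:
    """Read a field of WSS series from disk.

    Parameters
    ----------
    period : float, optional
        Cycle duration in seconds.  When given, inputs spanning several
        cycles are truncated to the final cycle; when omitted, the whole
        span of each point is taken as one cycle.
    decimate : int
        Keep every ``decimate``-th time sample (e.g. 10 to mimic
        every-10th-step extraction from a solver run); default 1 (off).
    """
    if format == "vtk-series":
        raise NotImplementedError(
            "VTK series input is not supported in this build; convert to the "
            "documented CSV dialect (columns: point_id, x_m, y_m, time_s, "
            "tau_x_pa, tau_y_pa, tau_z_pa)"
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FieldFormatError(f"{path}: missing columns {missing}")
    if decimate > 1:
        df = df.sort_values(["point_id", "time_s"])
        df = df[df.groupby("point_id").cumcount() % decimate == 0]
    points = []
    radii = []
    expected_n: Optional[int] = None
    for pid, group in df.groupby("point_id", sort=True):
        x, y, series = _point_series(pid, group, period)
        if expected_n is None:
            expected_n = series.n_samples
        elif series.n_samples != expected_n:
            raise FieldFormatError(f"point {pid}: ragged time axis ({series.n_samples} samples)")
        r = math.hypot(x, y)
        radii.append(r)
        points.append(FieldPoint(r=r, theta=math.atan2(y, x), series=series))
    if not points:
        raise FieldFormatError(f"{path}: no points")
    return DiscField(
        points=tuple(points),
        well_radius=max(radii),
        period=points[0].series.period,
    )
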