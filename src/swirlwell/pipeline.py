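"""Field-level orchestration: metric maps, radial profiles, scenario runs.

For non-tilted wells every point at one radius sees the same temporal
pattern (phase-shifted around the circumference), so per-point metrics can
be collapsed into radial profiles.  Tilting breaks that symmetry and the
full 2-D metric map over the base must be kept.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import synthetic
from .config import compute_dimensionless, well_config_from_dict
from .fieldio import read_field, write_field
from .metrics import compute_metric_set
from .presets import get_preset
from .shape import fit_ellipse, locus_from_series, shape_index
from .synthetic import DiscField, LocusSpec, make_disc_field, make_tilted_field

METRIC_COLUMNS = [
    "tawss", "mag_mean_wss", "osi", "transwss", "cfi", "transwss_min", "cfi_min",
    "dir_mean", "dir_modal", "dir_transwss_min", "dir_cfi_min",
]


@dataclass
class DecisionLog:
    """Structured record of fallback decisions taken during a run.

    Silent fallbacks (degenerate ellipse fits, excluded zero-magnitude
    samples, cycle truncation) would corrupt downstream comparisons, so each
    one is logged as an explicit record.
    """

    records: list = field(default_factory=list)

    def add(self, event: str, **details) -> None:
        self.records.append({"event": event, **details})

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def metric_maps(discfield: DiscField, log: Optional[DecisionLog] = None,
                with_shape: bool = True) -> pd.DataFrame:
    """Per-point metrics (and Shape Index) over the well base.

    Returns a tidy frame with coordinates (x, y, r, θ), the seven metrics,
    the four directions, SI and bookkeeping flags.  Masked points (under an
    attached cylinder's footprint) are excluded — they carry no metrics.
    """
    rows = []
    for p in discfield.points:
        if p.masked:
            continue
        ms = compute_metric_set(p.series)
        row = {"x_m": p.x, "y_m": p.y, "r_m": p.r, "theta_rad": p.theta}
        row.update(ms.as_dict())
        row["modal_tie"] = ms.modal_tie
        row["excluded_samples"] = ms.excluded_samples
        if log is not None:
            for name, reason in ms.undefined.items():
                log.add("undefined_metric", r_m=p.r, theta_rad=p.theta,
                        metric=name, reason=reason)
            if ms.excluded_samples:
                log.add("excluded_samples", r_m=p.r, theta_rad=p.theta,
                        count=ms.excluded_samples)
        if with_shape:
            fit = fit_ellipse(locus_from_series(p.series))
            row["shape_index"] = shape_index(fit)
            row["ellipse_degenerate"] = fit.degenerate
            if fit.degenerate and log is not None:
                log.add("degenerate_ellipse", r_m=p.r, theta_rad=p.theta)
        rows.append(row)
    return pd.DataFrame(rows)


def locate_extrema(maps: pd.DataFrame, metric: str) -> dict:
    """Azimuth/radius of the maximum and minimum of one metric over the base."""
    sub = maps.dropna(subset=[metric])
    hi = sub.loc[sub[metric].idxmax()]
    lo = sub.loc[sub[metric].idxmin()]
    return {
        "max": {"value": float(hi[metric]), "r_m": float(hi.r_m), "theta_rad": float(hi.theta_rad)},
        "min": {"value": float(lo[metric]), "r_m": float(lo.r_m), "theta_rad": float(lo.theta_rad)},
    }


def radial_profile(
    maps_or_field: Union[pd.DataFrame, DiscField],
    n_bins: int = 50,
    r_max: Optional[float] = None,
    log: Optional[DecisionLog] = None,
) -> pd.DataFrame:
    """Average per-point metrics within annular bins.

    Bins are half-open [r_i, r_{i+1}) over [0, r_max].  Empty bins (e.g.
    inside an attached cylinder's footprint) are reported with zero
    occupancy and NaN aggregates, never interpolated.  For azimuthally
    symmetric fields the per-bin dispersion (also returned, ``<metric>_std``)
    vanishes to numerical precision.
    """
    if isinstance(maps_or_field, DiscField):
        if r_max is None:
            r_max = maps_or_field.well_radius
        maps = metric_maps(maps_or_field, log=log)
    else:
        maps = maps_or_field
        if r_max is None:
            r_max = float(maps.r_m.max())
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.minimum(np.searchsorted(edges, maps.r_m.to_numpy(), side="right") - 1, n_bins - 1)
    value_cols = [c for c in maps.columns if c in METRIC_COLUMNS + ["shape_index"]]
    rows = []
    for b in range(n_bins):
        sel = maps[idx == b]
        row = {"bin_center_m": centers[b], "count": len(sel)}
        for c in value_cols:
            vals = sel[c].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            row[c] = vals.mean() if vals.size else math.nan
            row[c + "_std"] = vals.std() if vals.size else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# built-in synthetic scenarios
# ---------------------------------------------------------------------------

def _control_profile(r: float, r_plateau=7.0e-3, r_edge=10.5e-3, amp=0.3) -> LocusSpec:
    """Control-well regime: uniform circular loci out to ~7 mm, then
    progressively elongated, amplified, wave-biased elliptic loci."""
    if r <= r_plateau:
        return synthetic.circular(amp)
    s = min((r - r_plateau) / (r_edge - r_plateau), 1.0)
    return synthetic.elliptic(
        amplitude_tangential=amp * (1.0 + 2.0 * s),
        amplitude_radial=amp * (1.0 - 0.9 * s),
        asymmetry=0.3 * s,
    )


def _cc_profile(r: float) -> LocusSpec:
    """Attached-cylinder regime: near-uniaxial tangential flow in the channel."""
    return synthetic.elliptic(
        amplitude_tangential=0.4, amplitude_radial=0.05, asymmetry=0.2
    )


def _sc_profile(r: float, r_cyl=8.5e-3, r_edge=10.5e-3, amp=0.1) -> LocusSpec:
    """Suspended-cylinder regime: uniform circular loci across the whole
    span under the cylinder, elongated outside it."""
    if r <= r_cyl:
        return synthetic.circular(amp)
    s = min((r - r_cyl) / (r_edge - r_cyl), 1.0)
    return synthetic.elliptic(
        amplitude_tangential=amp * (1.0 + 3.0 * s),
        amplitude_radial=amp * (1.0 - 0.9 * s),
        asymmetry=0.3 * s,
    )


SCENARIOS = {
    "control_like": dict(profile=_control_profile, r_min=0.5e-3, r_max=10.5e-3, mask=0.0),
    "cc_like": dict(profile=_cc_profile, r_min=4.5e-3, r_max=10.5e-3, mask=4.0e-3),
    "sc_like": dict(profile=_sc_profile, r_min=0.5e-3, r_max=10.5e-3, mask=0.0),
}


def make_scenario_field(
    name: str,
    n_radii: int = 20,
    n_azimuths: int = 8,
    n_samples: int = 360,
    period: float = 0.4,
    modulation_depth: float = 0.0,
    modulation_phase: float = 0.0,
    tilt_angle: float = 0.0,
) -> DiscField:
    """Generate one of the named synthetic well scenarios."""
    try:
        sc = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}") from None
    radii = np.linspace(sc["r_min"], sc["r_max"], n_radii)
    azimuths = np.arange(n_azimuths) * (2 * math.pi / n_azimuths)
    if modulation_depth > 0 or tilt_angle > 0:
        return make_tilted_field(
            sc["profile"], radii, azimuths,
            modulation_depth=modulation_depth, modulation_phase=modulation_phase,
            period=period, n_samples=n_samples, well_radius=11.05e-3,
            mask_radius=sc["mask"], tilt_angle=tilt_angle,
        )
    return make_disc_field(
        sc["profile"], radii, azimuths, period=period, n_samples=n_samples,
        well_radius=11.05e-3, mask_radius=sc["mask"],
    )


def run_pipeline(config: dict, outdir: Union[str, Path]) -> dict:
    """Run a full analysis from a config mapping; write artifacts to ``outdir``.

    Config keys (all optional except one of ``scenario``/``input``/``well``)::

        well:      unit-suffixed well configuration -> characterization row
        scenario:  {name, n_radii, n_azimuths, n_samples, period,
                    modulation_depth, modulation_phase, tilt_angle, seed}
        input:     {path, period, decimate}  — CSV field instead of a scenario
        profile_bins: int (default 50)

    Outputs: ``characterization.json``, ``field.csv``, ``metric_maps.csv``,
    ``radial_profile.csv`` and ``decisions.jsonl``.  Deterministic for a
    fixed config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = DecisionLog()
    artifacts: dict = {}

    if "well" in config:
        well = config["well"]
        cfg = get_preset(well) if isinstance(well, str) else well_config_from_dict(well)
        groups = compute_dimensionless(cfg)
        row = groups.table_row()
        (outdir / "characterization.json").write_text(json.dumps(row, indent=2))
        artifacts["characterization"] = row

    discfield = None
    if "scenario" in config:
        sc = dict(config["scenario"])
        name = sc.pop("name")
        sc.pop("seed", None)
        discfield = make_scenario_field(name, **sc)
        write_field(discfield, outdir / "field.csv")
    elif "input" in config:
        inp = dict(config["input"])
        discfield = read_field(inp["path"], period=inp.get("period"),
                               decimate=int(inp.get("decimate", 1)))
        if inp.get("period") is not None:
            log.add("cycle_truncation", period=inp["period"])

    if discfield is not None:
        maps = metric_maps(discfield, log=log)
        maps.to_csv(outdir / "metric_maps.csv", index=False)
        profile = radial_profile(maps, n_bins=int(config.get("profile_bins", 50)),
                                 r_max=discfield.well_radius)
        profile.to_csv(outdir / "radial_profile.csv", index=False)
        artifacts["maps"] = maps
        artifacts["profile"] = profile

    log.write(outdir / "decisions.jsonl")
    artifacts["log"] = log
    return artifacts
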