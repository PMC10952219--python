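# swirlwell

Wall-shear-stress (WSS) analysis for the **swirling-well** cell-culture
model: endothelial cells grown on the base of a dish or multiwell-plate
well that rides on an orbital shaker. The orbit drives a wave rotating
around the well, exposing cells to spatially and temporally complex shear —
a cheap, high-throughput stand-in for the hemodynamic environments thought
to localize atherosclerosis. This package provides the post-processing
side of that workflow for CFD engineers and cell biologists: it
characterizes well configurations, reduces WSS vector time-series (from a
solver export or from its own synthetic generator) to the standard shear
metrics, and aggregates them into radial profiles and 2-D maps.

## What it computes

**Dimensionless characterization.** A well of radius *R* filled to mean
depth *d*, on an orbit of radius *a* at angular rate *ω*, is characterized
by

> E = a/L, F = aω²/g, Γ = d/L, Re = L²ω/ν, Bo = (ρw−ρa)g(2L)²/σ, We = ρwU²(2L)/σ

with U = Rω the rim speed and characteristic length L = R for a plain
well, or the channel width R_well − R_cylinder when a central cylinder
(attached to the base, or suspended above it) turns the well into an
annular channel.

**Seven WSS metrics** per point, from one cycle of the instantaneous WSS
vector τ⃗(t):

* TAWSS = (1/T)∫|τ⃗|dt and MagMeanWSS = |⟨τ⃗⟩|;
* OSI = ½(1 − MagMeanWSS/TAWSS) ∈ [0, 0.5];
* transWSS = (1/T)∫|τ⃗·(n⃗×m̂)|dt, the cross-flow past the mean direction
  m̂, and CFI, its unit-vector (angle-only) counterpart;
* transWSSmin and CFImin, the same quantities minimized over the in-plane
  reference axis — the cross-flow past a cell that orients itself to
  minimize it —

plus four characteristic directions (mean, modal over 18 orientation bins,
and the two minimizing axes). For a perfectly circular polar locus the
analytic limits are OSI = 0.5 and CFI = CFImin = transWSSmin/TAWSS = 2/π ≈
0.64.

**Shape Index.** The polar locus (vector-tip trajectory in the local
tangential/radial frame) is summarized by fitting an ellipse and reporting
SI = 4πA/P²: 1 for a circle (fully multidirectional flow), 0 for a straight
segment (uniaxial flow).

**Fields.** Per-point metrics over the well base, radial-bin profiles for
rotating-wave-symmetric flows, extremum location for tilt-broken maps, and
a documented CSV dialect for solver exports
(`point_id, x_m, y_m, time_s, tau_x_pa, tau_y_pa, tau_z_pa`).

A synthetic generator emulates the regimes the well produces — uniform
circular loci at the centre, elongated biased loci at the edge, uniaxial
oscillation, steady flow, rotating-wave disc fields with azimuthal phase
shift, and tilt-broken modulated fields — so the whole chain runs and is
tested without a commercial solver.

## Worked example

```python
>>> import swirlwell as sw
>>> row = sw.compute_dimensionless(sw.get_preset("control")).table_row()
>>> row
{'Bo': 67, 'We': 9, 'Re': 2466, 'E': 0.45, 'Gamma': 0.18, 'F': 0.13}
>>> s = sw.make_locus(sw.circular(1.0), n_samples=360, period=0.4)
>>> round(sw.osi(s), 3), round(sw.cfi_min(s)[0], 2)
(0.5, 0.64)
>>> si, fit = sw.locus_shape_index(s)
>>> round(si, 6)
1.0
```

The first line characterizes the baseline well (R = 11.05 mm, d = 2 mm,
a = 5 mm, 150 rpm, water-like medium): moderately forced (F = 0.13),
shallow (Γ = 0.18), inertial (Re = 2466, Bo ≫ 1). The circular locus —
the flow at the well centre — sits at the oscillatory-shear ceiling
(OSI = 0.5) and the multidirectional limit (CFImin = 2/π), and its polar
locus is a perfect circle (SI = 1).

Same from the shell:

```bash
swirlwell characterize --model control
swirlwell synth --scenario sc_like --out field.csv
swirlwell profile --in field.csv --out profile.csv --period 0.4
```

## Layout

```
src/swirlwell/
  config.py     well/orbit/fluid configuration, dimensionless groups
  presets.py    the standard model variants (control, volumes, CC, SC, tilt)
  series.py     WSSSeries + local radial/tangential frame
  synthetic.py  locus and disc-field generator
  metrics.py    the seven metrics and four directions
  shape.py      polar loci, ellipse fit, Shape Index
  fieldio.py    CSV field dialect
  pipeline.py   metric maps, radial profiles, scenario runner
  cli.py        command-line interface
docs/methods.md   model description, conventions, numerical choices
```
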