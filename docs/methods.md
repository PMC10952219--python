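# Methods

## The physical system

A cylindrical culture well (radius R, fluid depth d) sits on an orbital
shaker whose platform translates in a horizontal circle of radius a at
angular rate ω. In the platform frame the fluid feels the periodic body
force (aω²cos ωt, −aω²sin ωt, −g); a gravity wave rotates around the well
once per orbit, and the viscous stress it exerts on the base — the wall
shear stress (WSS) experienced by cultured cells — varies over the cycle
and over the base. Near the centre the instantaneous WSS vector sweeps all
directions at nearly constant magnitude; near the wall it oscillates along
a nearly tangential axis, spending more of the cycle in the wave-travel
direction. Central cylinders modify this: attached to the base they force
nearly uniaxial annular flow, suspended above it they extend the
multidirectional central regime across the whole span beneath them.
Tilting the well base breaks the rotational symmetry.

## Dimensionless characterization

`compute_dimensionless` reports E = a/L, F = aω²/g, Γ = d/L, Re = L²ω/ν,
Bo = (ρw−ρa)g(2L)²/σ and We = ρwU²(2L)/σ, with U = Rω (rim speed, i.e. the
maximum of We over the base) and characteristic length L equal to the well
radius or, for cylinder models, the annular channel width
R_well − R_cylinder. Every group containing a length uses the substituted
L, so cylinder variants are characterized by their channel.

Numerical conventions, fixed by reproducing the printed characterizations
of the standard model variants:

* **F = aω²/g** — the ratio of orbital acceleration to gravity (0.13 for
  the baseline orbit).
* **ν = μ/ρ** for water-like medium (0.78 × 10⁻³ Pa·s / 1003 kg/m³ =
  7.78 × 10⁻⁷ m²/s). Dextran-thickened media are specified directly by
  kinematic viscosity (`kinematic_viscosity_override`).
* **σ defaults**: 0.072 N/m (plain wells, serum-free medium) and
  0.047 N/m (cylinder variants, serum-supplemented medium — serum proteins
  are surfactants). Both overridable. Note that for cylinder variants the
  conventional printed Bo is consistent with σ = 0.047 while the printed
  We is consistent with σ = 0.072; this package computes both from the one
  configured σ and leaves the tension documented rather than resolved.
* **Printed precision**: `table_row()` rounds Re/Bo/We to integers and
  E/Γ/F to two decimals.

## WSS series and frames

A `WSSSeries` holds n uniform samples of the stress vector over exactly
one cycle (endpoint not duplicated); eight samples minimum. Analyses use
the final, settled cycle of a simulation; `read_field(period=...)`
truncates longer exports accordingly. Each point carries a local frame:
radial unit vector pointing outward, tangential unit vector whose
*negative* sense is the wave-travel (counter-clockwise) direction, and the
wall normal. Polar loci built in this frame therefore follow the plotting
convention that negative radial components point at the well centre and
negative tangential components point along the wave.

## Metrics: definitions and numerical choices

Cycle integrals are plain arithmetic means over the uniform samples —
for a periodic integrand this is the spectrally accurate quadrature, and
the trapezoid rule on a closed cycle reduces to it. With the default 360
samples/cycle the circular-locus limits are met to ~2 × 10⁻⁵.

The cross-flow integrands use absolute values, |τ⃗·(n⃗×m̂)| and
|τ̂·(n⃗×m̂)|: the signed components cancel over a cycle by construction,
and the absolute forms are what give the circular-locus limits
transWSS = (2/π)·TAWSS and CFI = 2/π their meaning.

* **Degenerate references.** OSI requires TAWSS > 0; transWSS and CFI
  require a nonzero mean vector. A mean magnitude below 10⁻¹² × TAWSS is
  roundoff, not a direction; these metrics then surface as NaN with a
  reason code (`MetricSet.undefined`), never as silent zeros. The
  minimized variants remain defined for every series.
* **Axis minimization** (transWSSmin, CFImin): the objective has period π;
  a 0.25° grid scan over [0, π) — augmented with the mean-direction axis
  as an explicit candidate, so the minimized value can never exceed its
  unminimized counterpart — is refined by bounded scalar minimization
  (xatol 10⁻⁸). A spread below 10⁻¹² (relative) marks the objective flat,
  e.g. for a perfect circular locus, and the axis is reported
  indeterminate (None/NaN) rather than arbitrary.
* **CFI-type averages** exclude zero-magnitude samples (no direction to
  normalize); the excluded count is recorded.
* **Modal direction**: full directions (not axes) in [0, 2π), 18
  left-closed bins of 20°; ties break to the lower bin index and set a
  flag — uniform circular sweeps tie across all bins by construction.
* **Reported ranges**: directions in [0, 2π), minimizing axes in [0, π).

## Polar loci and the Shape Index

An ellipse is fitted to the locus by the direct (non-iterative)
least-squares conic method, via scikit-image's `EllipseModel`, with the
data centred on its centroid and scaled to unit size first — the conic
scatter matrix is otherwise badly conditioned for offset or large loci —
and a small-rotation retry for the rare orientations that defeat the
conic-to-geometric conversion. Loci collinear to within a singular-value
ratio of 10⁻⁹ return the best-fit segment as a zero-minor-axis ellipse
with a `degenerate` flag, so highly elongated loci report SI = 0 instead
of a fitting failure.

SI = 4πA/P² uses Ramanujan's second perimeter approximation (relative
error < 10⁻⁹ at the aspect ratios arising here, bounded in the tests
against the exact elliptic-integral perimeter); SI is clipped to [0, 1].

## The synthetic generator

The generator emulates the *statistical and geometric structure* of
swirling-well WSS fields, not their fluid dynamics: no Navier–Stokes or
free-surface physics is solved, and amplitudes are plausible round numbers
(0.1–0.5 Pa, matching the order of magnitude of measured well shears)
rather than predictions. Regimes:

* `circular` — constant-magnitude rotating vector (well-centre limit);
* `elliptic` — axis-aligned ellipse with optional phase warp
  θ(ψ) = ψ − α·sin ψ (α ∈ [0, 1)) that concentrates samples at negative
  tangential stress, emulating the wave-travel bias of edge loci; the
  bias magnitude is a free shaping knob, uncalibrated;
* `uniaxial_oscillatory` — zero-mean tangential oscillation;
* `steady` — constant vector, with optional seeded Gaussian noise.

One cycle is generated (matching last-cycle analysis), 360 samples by
default, τz ≡ 0 (flat base; the metrics still consume three components).
Disc fields repeat one radial locus family around the circumference with
the local phase advanced by the azimuth θ — the rotating-wave symmetry,
exact by construction (the advance sign is a convention; the physical
content is the one-cycle-per-revolution phase shift). Tilted fields scale
amplitudes by 1 + depth·cos(θ − phase), which moves the TAWSS maximum to
the high-point azimuth while leaving scale-invariant metrics (OSI, CFI,
CFImin) untouched — the first-order symmetry-breaking signature. What
passing tests on these fields demonstrate is the correctness of the
metric, fitting and aggregation machinery under known ground truth; they
do not validate any CFD prediction.

## Fields, profiles, maps

Radial profiles average per-point metrics in half-open annular bins
(default 50 over [0, R]) and report per-bin dispersion; for symmetric
fields the dispersion vanishes (asserted at 10⁻⁶ in tests), so a profile
equals any single member's metrics. Empty bins (e.g. under an attached
cylinder's footprint, where no fluid touches the base) keep zero occupancy
and NaN aggregates. Maps keep (r, θ) per point; `locate_extrema` reads out
symmetry breaking. The pipeline logs every fallback (truncation, excluded
samples, degenerate fits) as structured JSONL records.

Coordinates: origin at the well centre, x toward the tilt high point,
θ counter-clockwise.

Supported field input is the documented CSV dialect; VTK surface series
are not read in this build (`read_field(format="vtk-series")` raises with
the CSV alternative named).

## Problem sizes

Tests and the acceptance script run on desk-scale inputs chosen for clean
analytics: 360 samples/cycle for single-locus limits (quadrature error
~10⁻⁵), 64–96 samples for randomized property suites (100 seeds each),
fields of ~10–20 radii × 4–12 azimuths, and 100-point circles for fitting.

## Known limitations

* No fluid-dynamics solver: field *values* from any real well must come
  from CFD or measurement; this package post-processes them.
* The edge-locus bias parameter and scenario amplitude profiles are
  shaping choices, not calibrated fits.
* The minimized-axis report is meaningful only when the objective has a
  pronounced minimum; flat objectives are flagged, and near-flat ripple
  (quadrature aliasing, ~10⁻⁵ relative at 64 samples) makes the *axis*
  (not the value) sensitive for near-circular loci.
* Bo/We for cylinder variants depend on which σ convention is adopted
  (see above).
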