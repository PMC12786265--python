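# Methods

## Model

A filament is m_max identical subunits stacked with monomer spacing p₀ and
azimuthal step Δψ₀ per monomer.  Every scatterer site of the subunit (atom
or coarse grain, with helix-cylinder radius r₀, first-monomer azimuth ψ₁ and
axial offset z₁) traces its own *discontinuous helix* — a helical path
sampled only at the monomer positions.  The filament transform is the sum of
the Bessel-order expansions of all these helices, each site weighted by its
electron count and by the transform of a uniform sphere of its equivalent
radius; the reported pattern is the cylindrical average of |f|² over a set
of azimuthal viewing angles.  Defaults describe the vertebrate actin thin
filament: p₀ = 27.36 Å, 13 monomers per 6 turns (Δψ₀ = −6·2π/13, the
left-handed genetic helix, pitch 59.28 Å, half-period 355.7 Å), m_max = 364
(≈1 µm).  The azimuthal step is not printed alongside the spacing in the
usual parameter tables; 13/6 symmetry is adopted because it reproduces both
the 27.36 Å spacing and the 355.7 Å half-period.

Assumptions inherited from the underlying treatment of contracting muscle:

- crossbridge force transfer is concentrated in a single plane through the
  bound monomer's centre of mass; local distortion of the monomer at the
  binding interface is neglected;
- deformation is purely axial — azimuthal progression is that of the relaxed
  filament (no twisting/unwinding);
- hydrogens are excluded (negligible scattering);
- no lattice disorder, detector geometry, beam polarisation or Ewald
  curvature — patterns are ideal single-filament transforms.

## Strained geometry

Load planes at axial positions z_l partition the filament into segments.
Tension accumulates from the free tip (z = 0) toward the Z-line, so segment
l carries T_l = Σ_{j<l} f_j and spacing p_l = p₀(1 + T_l/K_a) with
K_a = 6.5×10⁴ pN.  Deformed coordinates are produced by a piecewise-linear
map D(z) of the relaxed coordinates (slope 1 + T_l/K_a between planes,
anchored D(0) = 0).  This construction makes the three defining properties
exact by construction: within-segment spacings equal p_l; a site whose
spacing straddles a plane gets the two segment strains blended in proportion
to its axial offset fractions about the plane; a uniform profile rescales
every coordinate by (1+δ).  Plane positions are snapped to monomer-centre
planes; forces landing on the same monomer are summed.  Sites within ε of a
plane (default ε = 10⁻⁶ p₀; there is no canonical value, only the need for a
tie-break) are treated as on-plane and take the Z-side segment spacing.  A profile with all
strains zero returns the relaxed coordinates bit-exactly (exact fast path).

The five boundary regions used to assign straddling sites to monomer
indices are exposed as `classify_boundary_region`; the coordinate map above
realises the same geometry without explicit index bookkeeping and is
verified against the brute-force oracle (below).

## Diffraction engine

Amplitudes use the plane-wave normalisation: the transform of a single
monomer equals Σ w e^{2πi q·r} exactly (Jacobi–Anger identity), which is
what the independent direct-summation oracle evaluates, and what makes the
forward-scattering amplitude equal Σw·m_max.  An optional `radius_prefactor`
multiplies each helix by r₀/√(2π) for the ring-density convention in which
intensities scale with r₀²; profile comparisons can instead remove the r₀²
scaling via the `r0_squared` normalisation mode.

Numerical choices:

- **Bessel truncation**: |n| ≤ ⌈x⌉ + ⌈6 x^⅓⌉ + 10 with x = 2π R_max r₀_max,
  placing the discarded orders in the Airy decay region (|J_n| ≲ 10⁻¹⁰); a
  run-time check warns if the last retained order is not negligible.
- **Azimuthal averaging**: 18 uniform angles on [0, 2π).  Any even count
  makes the average exactly Friedel-symmetric (the angle set is invariant
  under Ψ → Ψ+π).  Convergence was checked against denser angle sets in the
  test suite.
- **Sphere form factor**: Φ(x) = 3(sin x − x cos x)/x³ evaluated by series
  1 − x²/10 + x⁴/280 below x = 0.1 to avoid cancellation.  Its first zero
  (the resolution cutoff of a grain model) is found at run time from
  tan x = x (x* ≈ 4.4934), giving the Bragg spacing d = 2π r_s / x*.
- **Lorentz correction**: I′ = R·I (multiplicative-in-R convention, the
  R = 0 column maps to zero); the exact factor used for published fiber
  patterns is rarely stated, so the correction is optional and flagged.
- **Oracle**: `direct_sum_intensity` evaluates the plane-wave sum over every
  (site, monomer) pair with no Bessel expansion; the two routes agree to
  machine precision on small filaments (relaxed and nonuniformly strained)
  and the equivalence is enforced in the tests at ≤10⁻⁶ relative.

Default grid: R ∈ [0, 0.16] Å⁻¹, Z ∈ [−0.16, 0.16] Å⁻¹ at 5×10⁻⁴ Å⁻¹
(covers the 4th meridional at ≈0.147 Å⁻¹).  Meridional peak *positions* are
measured on the R = 0 column with a Z step of 2×10⁻⁵ Å⁻¹, fine enough to
resolve the length-limited peak width ≈1/(m_max p₀) ≈ 10⁻⁴ Å⁻¹.

## Structure handling and coarse-graining

Heavy atoms get Bondi-type van der Waals radii (Alvarez consensus values for
metals Bondi did not tabulate; unknown elements fall back to 1.70 Å with a
warning) and neutral-atom electron counts.  Effective atomic volume is
`volume_scale`·(4/3)π r³.  The default `volume_scale` is 1 (raw vdW
volumes): the single-sphere equivalent radius of a full actin monomer is
only consistent with unscaled volumes, whereas a 0.34 packing prefactor
(selectable) would shrink every equivalent radius by 0.34^⅓ ≈ 0.70.

Coarse-graining clusters the unweighted Cartesian atom coordinates
(k-means++, Lloyd iterations, tolerance 10⁻⁶, ≤300 iterations per run —
iteration controls are configurable since no canonical values exist).  Out
of `restarts` independent runs (default 100) the run with minimal grain-
volume standard deviation is selected; a standard-error criterion is
available.  Grain weight is the summed member electron count (conserved
exactly under any k), grain radius the equivalent-sphere radius of the
summed member volume.  Empty clusters are relocated by the clustering
backend.

## Synthetic data

Two generators define the simulated study conditions:

- `generate_synthetic_monomer` — a *synthetic* actin-like subunit: 2991
  heavy atoms (the heavy-atom count of G-actin) with typical protein
  composition (C 62.6 / N 17.2 / O 19.2 / S 1.0 %), uniformly packed in a
  24×24×22 Å spheroid centred 16.2 Å off the filament axis (the actin
  centre-of-mass helix radius), a realistic ≈0.056 atoms/ų packing.  It
  reproduces what the diffraction physics cares about — total electron
  count, equivalent-volume budget, radial extent of the helix radii — and
  its coarse-grain radius ladder lands within a few percent of the values
  published for a real actin monomer (22.39 / 10.75 / 6.2 / 3.48 / 2.18 Å
  for k = 1/9/47/260/1016).  It does **not** reproduce real secondary
  structure, the two-lobed subdomain architecture, or the exact atomic
  radial distribution, so all-atom layer-line *intensity distributions*
  computed from it are illustrative, not predictions for actin; tests
  passing on it validate the machinery, not a specific structure.  Real
  monomers (e.g. PDB 1ATN, 3MFP, 2ZWH oriented with the filament axis along
  z) can be substituted directly via `load_monomer`.
- `simulate_crossbridges` — a deliberately simple surrogate for a spatially
  explicit sarcomere Monte Carlo: Poisson attachment count, uniform
  positions snapped to monomer planes, truncated-normal forces
  (3 ± 2 pN, floor −2 pN so occasional compressive bridges occur).  The
  default density of 105 bridges/µm makes the mean cumulative Z-line force
  ≈315 pN, the mean isometric per-filament force in frog sartorius muscle;
  with K_a this yields ≈0.24 % mean filament strain.  It omits crossbridge
  kinetics, spatial correlation between the three neighbouring thick
  filaments, and filament compliance feedback; the published nine-state
  cycle constants are shipped in `data/crossbridge_cycle_reference.yaml`
  for reference only.

Because observed patterns average over very many filaments, the broadening
analyses average intensities over an ensemble (16 independent draws in the
tests): single-filament meridional peaks are split by the particular strain
staircase, and ensemble averaging recovers the smooth order-dependent
broadening with the first meridional insensitive to nonuniformity.

## Profiles and peak metrics

Meridional profiles integrate |R| ≤ R_window (default 0.004 Å⁻¹, single
column if the window holds one grid column); layer-line profiles integrate a
Z window (default ±0.002 Å⁻¹) — published integration windows are not
stated, so these are configurable.  Peak position is parabola-refined and
reported as Bragg spacing d = 1/q (no 2π); FWHM is linear interpolation at
half height (no model fitting); integrated intensity is the trapezoid rule.
A flat profile yields a distinct no-peak result (None).

## Problem sizes

The test-suite and acceptance computations use the 9-grain or single-sphere
subunit models at full filament length (364 monomers, 18 viewing angles) for
geometry checks, and ≤5-site/≤8-monomer filaments for the oracle
equivalence; these sizes fully determine reflection positions and the
strain phenomenology, which depend on helical symmetry and the strain model
rather than on site count.  All-atom runs (2991 sites) use the identical
code path and scale linearly in site count.

## Known limitations

- Single filament in vacuo: no inter-filament interference, lattice
  sampling, disorder or instrument broadening, so simulated patterns are
  sharper and richer than experimental ones.
- No torsional deformation; strain is axial only.
- Equivalent spheres are isotropic; anisotropic grain shapes are not
  modelled.
- The tension normalisation assumes the vertebrate hexagonal lattice with
  two thin filaments per thick filament.
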