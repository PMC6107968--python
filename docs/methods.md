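# Methods

This note records the modelling assumptions, parameter defaults, generator
scope and numerical choices behind the `toepad` package. Every number
quoted here is computed by the package (see `toepad.reproduce` and the
test suite); no empirical claim is made beyond what those computations
state.

## 1. Geometry model

### Assumptions

- The pad is a flat disc of diameter *D*; its projected area is π*D*²/4.
  Real pads are roughly heart-shaped and slightly curved; the disc is the
  simplest shape consistent with a single published diameter, and all
  derived fractions are area ratios that are insensitive to outline shape.
- Epidermal cells and nanopillars are regular hexagonal prisms on an
  infinite triangular lattice. "Diameter" always means across-corners
  (*d*), so edge length *a* = *d*/2, across-flats width *f* = (√3/2)*d*,
  apical area (3√3/2)*a*². A cell of width *f* plus half the surrounding
  channel of width *w* on each side tiles the plane with tile area
  (√3/2)(*f* + *w*)².
- Counts are infinite-lattice densities times the projected area, rounded
  to the nearest integer. Edge effects at the pad rim are ignored: for
  ~1.3 × 10⁵ cells on a 3.6 mm disc the rim correction is below 1%.
- Channel walls are vertical; wall (channel-side) area per element is
  perimeter × height. Dimples are treated as flat discs punched out of the
  pillar top; their depth does not enter the area budget, only their
  footprint.

### Outputs

`area_budget()` partitions each unit tile into microchannel floor
(tile − hexagon footprint), pillar-scale channels (hexagon footprint −
pillar footprints), dimples, and the full-contact remainder; it also
reports the wetted-area fold: (tile + wall area)/tile at the cell scale,
plus per-cell pillar wall area for the total. For the reference geometry
(*D* = 3.6 mm; cells *d* = 10 µm, *h* = 10 µm, *w* = 1 µm; pillars
*d* = 300 nm, *h* = 300 nm, *w* = 100 nm, dimple 240 nm) this yields
125 947 cells, 579 pillars per cell (72.9 × 10⁶ total), folds 4.71 and
6.65, and fractions 19.6% (microchannel), 58.1% (all channels), 32.4%
(dimples), 9.5% (full contact).

### Validation

A brute-force lattice oracle (`tests/conftest.py`) enumerates triangular
lattice points inside a disc and confirms the density-times-area count;
property tests check scale invariance and that the four fractions sum to
1 within 10⁻⁹ for arbitrary valid geometries.

## 2. Force laws

All mechanics functions are direct transcriptions of standard
continuum results; their regime of validity is the caller's
responsibility.

- **Capillary, plate-plate**: *F* = 2π*R*<sub>azi</sub>γ sin φ +
  π*R*<sub>azi</sub>²γ(1/*R*<sub>mer</sub> − 1/*R*<sub>azi</sub>). When
  built from a gap width, *R*<sub>mer</sub> = *d*/(2 cos φ). Assumes a
  circular contact line and a toroidal meniscus; gravity is neglected,
  valid because contact radii (≲ 2 mm) are below the capillary length
  κ = √(γ/ρ*g*) = 2.71 mm for mucus-like liquid.
- **Capillary, sphere-plate**: implemented with the filling-angle factor
  *c* = [cos(φ + β) + cos φ]/2, recovering the classical 4π*R*γ limit as
  the filling angle β → 0 at φ = 0. The constructor rejects parameter
  combinations with non-positive *c* (meniscus cannot exist).
- **Squeeze film**: Reynolds lubrication for rigid, parallel, no-slip
  surfaces in a Newtonian film: *F* = −(3/2)πμ*r*⁴*ḋ*/*d*³ (plate) and
  −6πμ*R*²*ḋ*/*d* (sphere). The sign convention is physical: separation
  (*ḋ* > 0) gives negative (attractive/resisting) force;
  `adhesive_magnitude()` takes the attractive part.
- **Film shear**: Couette friction *F* = μ*Av*/*d*; `gap_for_shear_stress`
  inverts it. Assumes a full, continuous film — the package itself
  demonstrates (see `examples/force_laws.py`) that this underpredicts
  measured friction by ~3 orders of magnitude at micrometre gaps, which is
  the argument for boundary lubrication.
- **Stribeck**: *St* = μ*v*/*P* with *P* the load per area. The regime
  cut-points (10⁻¹⁰, 10⁻⁸, 10⁻⁶ m) are order-of-magnitude placeholders
  typical of lubrication practice, closed on the left; they classify,
  they do not predict.
- **van der Waals**: non-retarded plate-plate pressure integrated over the
  effective contact fraction, |*F*| = *f*<sub>eff</sub>*A*
  *A*<sub>H</sub>/(6π*d*³). Retardation (relevant above ~10 nm) is
  ignored, which overestimates the force at large gaps — conservative for
  the package's main use (lower bounds on required proximity). The thermal
  lower bound on the Hamaker constant, 0.7 *k*<sub>B</sub>*T* = 2.93 ×
  10⁻²¹ J at 299.15 K, uses *k*<sub>B</sub> = 1.4 × 10⁻²³ J/K to match
  the two-significant-figure convention of the headline numbers; the CODATA
  value is also exported (`K_B_EXACT`).
- **Coulomb friction** acts on the sum of gravitational load and adhesive
  pre-load; **effective modulus** *E*\* = *E*/(1 − ν²) with ν restricted
  to (−1, 0.5].

## 3. Sensitivity analysis

Tenacity fields are computed on log-spaced 2-D grids (log spacing because
the parameters span decades). Feasibility against a measured band
[σ<sub>lo</sub>, σ<sub>hi</sub>] is a boolean mask; region boundaries are
extracted with scikit-image's marching squares (`find_contours`) at both
band levels, which is resolution-limited but requires no root finding.
Closed-form inversions are preferred where they exist:
`critical_gap_vdw` solves *d* = (*f*<sub>eff</sub>*A*<sub>H</sub>/6πσ)^(1/3),
and `predict_meniscus_curvature` uses *R*<sub>mer</sub> = γ/σ̃ with σ̃ the
geometric mean of the band edges (geometric, not arithmetic, because the
band spans nearly an order of magnitude; this gives 154 µm for the
0.177-1.29 mN mm⁻² band).

## 4. Measurement inversions

- **Rotating platform**: at the slip angle α<sub>∥</sub>, friction equals
  *mg* sin α<sub>∥</sub>; at the fall angle α<sub>⊥</sub> (past vertical),
  adhesion equals −*mg* cos α<sub>⊥</sub>. Adhesion is only measurable if
  the animal passes 90° (`measurable_adhesion`). Quasi-static rotation and
  rigid-body statics are assumed; dynamic effects of the rotating platform
  are not modelled.
- **Indentation**: for a spherical indenter of radius *r*<sub>i</sub>
  pressed to depth *d*<sub>i</sub>, the contact is taken as the spherical
  cap of area 2π*r*<sub>i</sub>*d*<sub>i</sub>, so tenacity
  σ = *F*/(2π*r*<sub>i</sub>*d*<sub>i</sub>). This assumes full conformal
  contact over the cap and no depth-dependence of σ; depths are restricted
  to *d*<sub>i</sub> ≤ 2*r*<sub>i</sub>.
- **Power-law fits**: ordinary least squares on log₁₀-transformed data via
  `scipy.stats.linregress`; the 95% CI on the exponent uses the
  t-distribution with *n* − 2 degrees of freedom. This matches the
  standard allometry workflow; reduced major axis regression is not
  implemented.
- **Fixtures**: `toepad/data/*.csv` hold literature-style performance
  records (stiffness, adhesion, friction) with explicit units and source
  tags, loaded through `importlib.resources` with row-level validation.
  Single-valued entries store `value_lo = value_hi`.

## 5. Synthetic data generators

The generators emulate two experiment types well enough to validate the
inversion code, not to simulate frog biology:

- **Population**: snout-vent length log-uniform on a range; pad area
  *A* = *a*·ℓ^*k*·e^ε and mass *m* = *b*·ℓ^*k′*·e^ε with independent
  log-normal noise ε. Defaults *k* = 2.0, *a* = 0.04 mm²·mm⁻ᵏ, *k′* = 3.0,
  *b* = 8 × 10⁻⁵ g·mm⁻ᵏ′, sd = 0.1 — chosen to give realistic magnitudes
  (a 60 mm frog: ~17 g, ~144 mm² total pad area) and the classic
  area-per-weight disadvantage of large animals.
- **Trials**: platform angles from inverse statics
  (α<sub>∥</sub> = arcsin min(1, σ<sub>∥</sub>*A*/*mg*),
  α<sub>⊥</sub> = arccos(−min(1, σ<sub>⊥</sub>*A*/*mg*))) plus Gaussian
  angle noise, clipped to [0°, 180°]; animals whose adhesion exceeds their
  weight never fall and are flagged `can_fall = False`. Indentation trials
  draw depths uniformly (50-350 µm, 1.5 mm indenter) and add
  multiplicative force noise.
- **Omitted**: behaviour (repositioning, peeling), substrate variation,
  pad viscoelasticity, within-individual repeated measures, and any
  species structure. All randomness flows from `numpy.random.default_rng`
  seeded in the spec dataclasses; identical specs give identical frames.

Generator parameters are documented defaults, not fitted constants, and
the validation tests assert statistical properties (bias < 2%, CI
coverage) rather than exact values.

## 6. Numerical and design choices

- SI units internally everywhere; a small suffix-based converter
  (`toepad.units`, e.g. `"3.6mm"`, `"71.97mN_per_m"`) handles config I/O
  because no general units library is available in the target environment.
- Frozen dataclasses for all physical specifications; validation at
  construction (e.g. dimple smaller than pillar across-flats, pillar pitch
  no larger than the cell).
- Nearest-integer rounding for element counts (not floor): counts are
  density estimates, not packings.
- `math.isclose` with per-quantity relative tolerances in the reproduction
  checks; tolerances reflect the printed precision of each expected value.
- Tests use hypothesis with fixed seeds/derandomization so the suite is
  deterministic across runs and machines.

## 7. Limitations

- The geometry model is planimetric: it cannot address channel
  cross-sectional shape, pillar tip curvature, or pad curvature, all of
  which matter for real contact mechanics.
- The force laws are rigid-surface, Newtonian-liquid idealizations; mucus
  is non-Newtonian and the pad is soft (*E* of tens of kPa), so computed
  forces bound rather than predict measured ones.
- The drainage-crossover gap *d*₀ = *w*(*h*/(*w* + *d*<sub>c</sub>))^(1/3)
  is a scaling estimate (≈ 0.97 µm for the reference cells), and the
  far/near-field classification threshold (factor 3) is a convention.
- Feasible-region boundaries inherit the sweep grid resolution; refine the
  axes where the boundary matters.
- The fixture tables are small curated extracts for testing and examples,
  not a systematic review.
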