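# Methods

## Physical model

The package asks a narrow quantitative question: when a nanoparticle (NP)
sits a few nanometres from — or partially embedded in — the plasma
membrane of a cell in an electroporation cuvette, how much does it change
the electric field the membrane experiences?

The model is the standard 2D continuum idealization: a circular cell
(radius R = 10 µm) with a thin shell membrane (d = 5 nm), immersed in
extracellular medium inside a rectangular domain with plate electrodes on
the left and right boundaries (Dirichlet potentials ±U/2) and insulating
walls top and bottom. Conductivities: cytoplasm 0.2 S/m, membrane
5·10⁻⁷ S/m, extracellular medium 1.5 S/m, gold 4.11·10⁷ S/m, silica
10⁻³ S/m. NPs are discs (radius 10 or 50 nm) or a capsule (radius 17 nm,
tip-to-tip length 60 nm), placed either 10 nm outside the membrane ("gap"
mode) or dipping 2 nm into it ("embedded" mode, locally thinning the
membrane to 3 nm).

The governing equation is stationary current conduction, ∇·(σ∇V) = 0,
with E = −∇V. A pure conduction (DC) solve is appropriate because the
membrane charging time of this cell/medium combination is ~1 µs, far
shorter than the 100 µs pulses the assay design assumes, and because the
conductivity contrasts — not permittivities — control every reported
quantity. Relative permittivities are parsed and stored for completeness
but enter no computation.

Because the problem is linear and every reported metric is a ratio of
fields computed at the same drive, all percentages are provably
independent of the applied voltage (verified to 10⁻¹⁰ in the tests). The
default drive, 8 V over the 80 µm box (a nominal 1 kV/cm), only sets the
absolute scale of exported fields.

## Nanoparticle placement (a deliberately considered default)

The angular position of the NP on the cell perimeter is genuinely open in
this model family, and it matters. At the electrode-facing pole the
exterior field *stagnates*: the insulating membrane forces the normal
field to ~0 there and symmetry kills the tangential component, so a
10 nm-gap NP at the pole sits in a field of ~10⁻³ of the applied one and
produces no meaningful gap-field structure — and a conductive NP there
yields a *larger* center field than an insulating one, the opposite of
the qualitative behaviour this model family is known for.

The default is therefore `angular_position = π/4`, where the surface
field retains both components. There, every expected feature appears:

* silica NPs concentrate current into the gap and produce a sharp field
  peak directly beneath their centre, larger for the larger disc;
* gold NPs, being equipotential bodies, suppress the tangential field
  beneath themselves (a central dip, with the current entering and
  leaving through their flanks);
* the tilted capsule (long axis along the applied field, i.e.
  `orientation = −π/4` relative to the local normal, so one tip faces the
  membrane) produces a clearly asymmetric profile;
* the gap-field excess decays to the background over a few NP radii.

Both angles are configurable per scenario.

## Meshing

The scale ratio (5 nm membrane in an 80 µm box) is the whole difficulty.
A single Delaunay triangulation of a graded point cloud is *not* safe
here: in the strongly anisotropic boundary layer far from the NP,
Delaunay happily creates long "needle" elements that connect nodes across
the thin membrane, and each such element is a conductive short that
destroys the transmembrane voltage (observed, not hypothetical: the first
implementation lost 66% of the TMV this way). The mesher therefore
triangulates three zones and stitches them conformally:

1. **Boundary-layer band.** A graded master angular grid (arc spacing
   2 nm inside a refined window around the NP, growing geometrically to a
   sagitta-limited 150 nm elsewhere). Each angle carries a radial column
   of stations: 6 membrane layers inside the window (3 outside, nested),
   then geometrically growing offsets (ratio 1.35) on both sides, every
   column ending on shared inner/outer circles. Columns that intersect
   the NP are rerouted with stations placed exactly on the NP surface, so
   the mesh conforms to the NP boundary, the gap keeps ≥ 3 element layers
   and the thinned membrane ≥ 2. Adjacent columns are joined by an
   explicit two-pointer strip triangulation of their radially monotone
   chains — by construction no element can cross a material interface.
2. **Cytoplasm core** and 3. **far field**: isotropic graded rings (plus
   a frame lattice and the electrode boundary) triangulated by Delaunay.
   The hole the far-field triangulation fills inside the band's outer
   circle is removed purely by vertex index (all three vertices on the
   circle), which provably leaves both sides attached to the same chord
   polygon — the meshes stitch without hanging nodes, and an explicit
   edge-incidence check enforces conformity.

Everything is a pure function of (geometry, controls); meshes are
bit-identical across runs. Quality: the metrology zone (membrane and gap
beneath the NP) keeps minimum angles ≥ 15° (typically 18–23°); the far
membrane band is deliberately anisotropic (aspect up to ~100:1), the
standard and appropriate choice for a thin layer whose field is locally
one-dimensional. A 20° floor everywhere would cost ~100× more elements
for no accuracy gain in the reported metrics.

Default meshes run ~17–20k nodes; `level` scales all targets (level 2 ≈
4× the elements).

## Solver

Lagrange P2 triangles by default (P1 behind a flag) assembled with a
3-point degree-2 quadrature; the system is SPD after elimination of the
electrode Dirichlet data and factorized with sequential sparse LU —
deterministic by construction. The 4.11·10⁷/5·10⁻⁷ S/m conductivity
contrast costs the factorization several digits, recovered by iterative
refinement with a componentwise backward-error stop (≤ 10⁻¹⁰); global
conductivity rescaling by the geometric mean of the extremes is applied
as well. A strongly conducting NP can instead be collapsed to a single
floating-potential unknown (`treat_conductor_as_equipotential`); the two
routes agree on gap and membrane metrics to < 10⁻³ relative, and the
equipotential path refuses silica (flagging a poor conductor as
equipotential is a usage error, not a numerical choice).

Validation anchors:

* uniform-conductivity box → exact slab field (10⁻⁹ relative);
* current through the left electrode balances the right one (consistent
  boundary-residual flux; ~10⁻¹³ relative in practice, 1% asserted);
* discrete maximum principle within 10⁻⁶·U;
* the no-NP baseline reproduces the closed-form shelled-cylinder membrane
  field. This comparison is run on a 320 µm domain: the analytic solution
  assumes an unbounded medium, and the default 80 µm box carries a real
  (physical, not numerical) finite-electrode image effect of −4.8% on the
  TMV that scales as 1/W² (−4.8 / −1.2 / −0.3% at 80 / 160 / 320 µm,
  while mesh refinement at fixed W moves the value by < 0.01%).

### Matched baselines

The headline membrane comparison is a sub-0.3% difference. Comparing two
independently meshed solves would drown it in discretization noise, so
the no-NP baseline for each scenario is solved **on the identical mesh**
with NP elements re-tagged to the material they would hold in the no-NP
geometry. With/without differences are then resolved far below 0.01%.
An independent no-NP baseline is still solved for oracle validation.

### Two-stage submodeling

`extract_submodel` + `solve_submodel` implement classical submodeling: a
window (default half-width 20 NP radii) is cut out of the global mesh and
re-solved with Dirichlet data interpolated from a global solution on the
cut. With the single graded global mesh already cheap (~3 s a solve),
submodeling is kept as a *validation* device rather than the default
solve path: the no-NP self-consistency check reproduces the global
membrane field in-window to < 0.5%, and the NP-window solve matches the
single-mesh metrics to < 1%.

## Reported metrics

* **Evaluation-line profile**: |E| sampled at 801 points on a straight
  segment through the gap midline (half the clearance above the membrane
  outer surface), parallel to the local tangent, centred beneath the NP
  centre, ±200 nm. Straight vs arc differs by a 0.5 Å sagitta over this
  span — negligible. Fields are exported in V/cm.
* **Membrane field per station**: |E| averaged over 11 samples across the
  membrane thickness along the radial normal — a thickness average, never
  a point sample, for robustness to element-level noise.
* **Membrane-field increase** (gap mode): 100·(max/max − 1) of the
  station values over a ±200 nm window, with-NP vs matched baseline. Both
  computed variants (max-over-window and the NP-facing station) agree on
  the builtin set. Sign convention: conductive NPs *shield* (negative
  change), insulating NPs enhance (positive); the builtin maximum is
  +0.276% (silica, r = 50 nm) — no scenario reaches ±0.3%.
* **Embedded thinning ratio**: 100·(with/baseline), thickness-averaged
  across the thinned 3 nm membrane beneath the NP centre over the full
  5 nm baseline at the same station. Printed alongside as an increase
  (ratio − 100) so the two conventions can never be confused.
* **Decay length**: distance from the central peak at which the excess
  over the plateau (mean of the outermost 10% of samples) falls to 1/e;
  undefined (None) when no central peak exists — gold profiles dip rather
  than peak, so this metric applies to the silica profiles.
* **Asymmetry index**: Σ|E(s) − E(−s)| / Σ(E(s) + E(−s)) over s > 0.

### The embedded-NP bound

The thinning ratio converges to 167%, i.e. 0.4% above the two-resistor
value d/(d − embed) = 5/3, not to the ~210% sometimes quoted for this
configuration. The physics is transparent: the gold NP is equipotential
and its surface potential is pinned by the surrounding exterior medium,
whose potential is locally *flat* near the membrane (the insulating shell
forces a stagnation zone). The transmembrane voltage across the thinned
patch is therefore unchanged, and the in-membrane field scales exactly as
the inverse remaining thickness. Lateral current redistribution adds only
~10⁻⁴ (the patch conductance is ~10⁻⁶ of the adjacent media). The result
is mesh-converged (167.4% → 166.7% from level 1 to 2) and insensitive to
evaluating the pointwise maximum instead of the thickness average (170%).
A materially larger ratio would require a different effective remaining
thickness (~2.4 nm) or a near-singular point sample at the NP–membrane
contact line; neither is part of the stated geometry, so the package
reports the bound it can defend.

## Assay arithmetic

The measurement chain for permeabilization and gene electrotransfer
(GET) scoring:

* **Gating**: closed convex scatter polygon in (FSC-A, SSC-A) and a
  singlet band |FSC-A − k·FSC-H| ≤ 0.25·k·FSC-H; `auto_gates` anchors the
  box on the median scatter (±0.4/+0.55 decades) and sets k to the median
  area/height ratio. Gating is idempotent and boundary-inclusive.
* **Sham-anchored thresholds**: the 0 V control is split into live and
  (if present) dead modes by a deterministic two-means on log₁₀
  fluorescence. t_low = 99.5th percentile of the live mode; t_high =
  log-scale midpoint between t_low and the dead mode's 0.5th percentile;
  a unimodal sham falls back to t_high = 30·t_low (flagged). The
  percentile rule is a disclosed surrogate for gates drawn by eye in
  instrument software; both percentiles and the fallback are parameters.
* **Partition**: A1 (live) = fl < t_low; A2 (viable permeabilized) =
  [t_low, t_high); A3 (dead) = fl ≥ t_high. Exact, half-open.
* **Viability**: 100·(sample absorbance / matched 0 V control); values
  above 100% are legitimate noise.
* **Overall GET** = %GFP × %survival / 100; `best_voltage` takes the
  argmax with ties to the lower voltage.
* **Statistics**: one-way ANOVA plus two-sided pooled-variance t-tests of
  each group against the control, step-down Šidák adjusted
  (adjᵢ = 1 − (1 − p₍ᵢ₎)^(m−i+1), monotonized). The family-wise error is
  verified ≤ 0.05 + 3·SE over 10,000 simulated null experiments.

## Synthetic data — what it does and does not establish

The generators produce the *structure* the chain assumes: log-normal
fluorescence modes ordered live < permeabilized < dead (defaults at
log₁₀ = 1.9 / 2.9 / 4.5, one-decade separations), scatter clouds with
low-scatter debris (15%), doublets at area ≈ 2× height (16%), and
logistic dose curves (permeabilization half-maximal at 150 V; GFP and
survival logistics whose product peaks at 250 V on the 0–275 V grid; an
optional NP effect of +15 pp at 150 V only, sized to be detectable with
three replicates). All draws are pure functions of (model, n, seed).

Passing the recovery suite (permeabilized fraction MAE ≤ 1.5 pp over 20
seeds, dose-midpoint within ±10 V, FWER control) demonstrates that the
*arithmetic* is correct and well-calibrated under its own assumptions.
It does not show that the thresholds would be correct for a real
instrument: real cytometry has spillover, autofluorescence drift,
non-log-normal tails and gate placement by eye, none of which are
modelled. Conclusions about real samples inherit those caveats.

## Numerical choices and degenerate inputs

* Solver stop: componentwise backward error ≤ 10⁻¹⁰ (hard fail at 10⁻⁹).
* Point queries on element edges resolve to the element the point locator
  returns — deterministic, repeat-query stable.
* NP–ray intersections thinner than 0.6·h_fine are treated as misses
  (the sliver is below mesh resolution); surviving stations are re-graded
  so pruning never leaves a jump wider than the local spacing.
* Empty event tables gate to empty tables (not an error); empty shams,
  non-positive control absorbances, singleton replicate groups and
  degenerate gate polygons raise typed errors.
* Two identical statistics groups give F = 0, p = 1, no flags.

## Limitations

* 2D plane model: enhancement factors are cylinder values (conductor
  limit 2); the 3D "factor of 3" lives in the closed-form sphere oracle
  and is never conflated with the 2D solve.
* No pulse-time dynamics and no pore-formation model: the solve is the
  pre-poration DC field distribution.
* Absolute field axes depend on the assumed drive; only ratios, shapes
  and orderings are claims.
* The NP angular position is a modelling choice (defaulted to π/4 for the
  reasons above), not a measured quantity.
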