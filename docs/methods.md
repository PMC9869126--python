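# Methods

## The thickness model

The package estimates the relative thickness distribution of an aneurysm
wall from geometry alone. The modelling assumption is that the sac formed by
ballooning of a patch of parent-artery wall (the neck region, area S_B,
uniform initial thickness δ_B) into its present shape (area S_A), with no
growth or repair of wall tissue. The wall is treated as an incompressible
thin membrane, so tissue volume is conserved:

    V = S_B · δ_B = S_A · δ̄_B,     δ_i = δ_B / λ_i,

where λ_i is the local area stretch of the mapping from the flat-lying neck
patch onto the sac and δ̄_B the post-inflation mean thickness. Everything
downstream is a ratio, so δ_B defaults to 1 and all thicknesses are reported
in multiples of the initial wall thickness; absolute (mm) thickness would
require knowing δ_B, which angiography cannot supply. Three dimensionless
coefficients summarize an aneurysm: I_S = S_A/S_B, I_BA = δ_B/δ_B′ (δ_B′ the
minimum thickness over the sac, at the "minimum extreme point"), and the
inhomogeneity coefficient I_δ = I_BA/I_S = δ̄_B/δ_B′.

Assumptions worth keeping in mind: no wall repair/proliferation, no mural
thrombus or calcification, no hemodynamic loading or pre-stress, and a
uniform initial thickness. Real walls remodel, so simulated minima are
thinner than reality; the claim defended by the tests is ordinal (where the
wall is thinnest, and how uneven it is), not metric.

## The inflation surrogate

The mapping from patch to sac is produced by a quasi-static geometric
inflation rather than a transient shell solve. The original workflow uses a
commercial generalized-Newtonian blow-molding solver; its material
parameters and boundary conditions are not part of the data, and for the
quantities consumed downstream (area stretch, hence thickness) only the
geometric mapping class matters. The solver here iterates, with no
randomness anywhere:

1. advance every free vertex along its area-weighted normal by
   min(step, distance to the mold);
2. blend in tangential umbrella smoothing (interior vertices only) to keep
   the parameterization even;
3. freeze vertices within the contact tolerance of the mold.

Advancing by at most the current closest-point distance cannot carry a
vertex through the mold (moving a distance d' ≤ d in any direction leaves
the new distance ≥ d − d' ≥ 0), so contact needs no ray casting. Distances
come from exact point–triangle tests on candidates taken from a KD-tree over
mold-triangle centroids; vertices whose lower bound exceeds one step skip
the narrow phase.

Per-vertex stretch is the ratio of barycentric vertex areas after/before,
which makes the conservation identity Σ aᵢδᵢ = S_B·δ_B hold to round-off by
construction; the residual tested (< 1 %) absorbs only the contact-tolerance
gap between the inflated surface and the mold.

Parameters (`InflationConfig`; lengths as fractions of the joint
patch+mold bounding-box diagonal, which makes the solver scale-equivariant):

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `delta_b` | 1.0 | initial thickness (dimensionless; outputs are ratios) |
| `step` | 0.005 | max normal advance per iteration; small enough to track curved molds, ~200 iterations across the box |
| `contact_tol` | 1e-3 | contact freeze distance; must be below `step` |
| `smooth_weight` | 0.5 | tangential umbrella blend; evens out the parameterization without moving the surface off the mold |
| `max_iterations` | 2000 | cap; non-convergence returns diagnostics instead of raising |

Validated against two closed-form molds: coaxial cylinders a→b give uniform
thickness δ_B·a/b (within 2 %), and disk→hemisphere gives mean thickness
δ_B/2 with exact mass conservation.

Limitation: strongly overhanging domes (equator much wider than the neck)
are only partially covered by the advancing front — vertices freeze on first
contact with the overhang's underbelly, so the far side of the equator
receives few vertices and the measured stretch there is extrapolated from
sparse coverage. I_S is therefore always computed from the *geometric* sac
and patch areas, not from the inflated mesh area. Consequences are ordinal,
not metric, as above.

## Neck handling and reconstruction

The neck (ostium) is a closed curve on the vessel surface, treated as the
boundary of a curved surface patch — a planar cut would bias S_B, volume and
I_S. Neck delineation is interactive in practice, so the neck polyline is an
explicit input (for synthetic pairs it is known exactly); it is snapped to
mesh vertices and bridged along edges. Cutting those edges must split the
surface into exactly two components; the component carrying no vessel port
is the sac.

When only Model A exists, the parent artery is reconstructed by filling the
neck hole: centroid fan, midpoint subdivision for interior freedom, then
interior vertices placed at the fixed point of umbrella (graph-Laplacian)
smoothing with the rim held — the discrete harmonic fill, solved directly as
a sparse linear system rather than by finite iteration, so re-smoothing
moves nothing (tested to < 1e-8 mm). On a cylinder wall with a hole of 20 %
of the vessel radius the harmonic patch stays within 2 % of the true
cylinder; the sag grows roughly with (hole radius)²/(4·vessel radius), so
very wide necks reconstruct less faithfully.

## Thickness-field reading

Isolines: 200 evenly spaced interior levels between field min and max
(contour-plot convention, endpoints excluded), extracted by marching
triangles with edge interpolation and chained into polylines. Exact
vertex-level hits are nudged by 1e-12 of the field range so crossings are
strict sign changes.

Extreme points: strict local minima over 1-ring neighborhoods (the
neighborhood scale is a package choice; plateaus are suppressed since a flat
region is not a nest of rings). The global minimum is always reported and
flagged — it is the predicted translucent/rupture site. A constant field has
no extreme points.

Isoline regularity: the original reading — rings "gradually sparse" near a
dangerous minimum vs "regular and evenly spaced" near a stable one — is
qualitative; the package quantifies it (as an extension) by the coefficient
of variation of consecutive level-crossing spacings along the
steepest-ascent streamline from the extreme point, traced exactly through
the piecewise-linear field (straight within each triangle, with vertex-hop
handling). A locally linear field gives CV ≈ 0; a flattening basin gives
CV > 0.

## Cohort statistics

The bundled table (48 aneurysms: groups A ruptured, B translucent
unruptured, C non-translucent unruptured) is shipped as CSV and audited at
load time: unique ids, group sizes 20/17/11, all coefficients positive, and
the identity I_δ·I_S = I_BA within 1e-6 relative on every row.

- Correlations are Spearman rank correlations (average ranks on ties; the
  bundled data has none). Rank correlation reproduces all three published
  I_S–volume coefficients (0.900 / 0.745 / 0.241) exactly at the printed
  precision, which settles the "Spearman or Pearson" ambiguity in favor of
  Spearman.
- AUC is pairwise concordance P(pos > neg) + ½P(pos = neg), computed from
  midranks; tests pin it to a brute-force double loop exactly.
- Youden-optimal cutoffs scan midpoints between consecutive distinct pooled
  values, call positive at marker ≥ cutoff (higher marker = higher risk),
  and break ties toward higher specificity. This midpoint convention
  reproduces all three published cutoffs (2.0753, 4.3991, 6.4424) with their
  operating points.
- The published comparisons exclude a few extreme aneurysms per analysis;
  the id lists are shipped verbatim as `EXCLUSIONS` and used as-is. The
  original outlier rule was never stated, so the Tukey-fence utility
  provided for exploration is *not* used to derive them (its output is
  logged against the published lists, not asserted).
- Bootstrap CIs are percentile intervals from stratified resampling (default
  2000 draws, seeded). Coverage at n = 17 vs 11 is verified ≥ 88 % at
  nominal 95 % over 200 simulated cohorts — percentile intervals undercover
  slightly at these sample sizes, which is expected.
- The rupture-prediction AUC printed in the source material (0.731) is not
  consistent with concordance on the printed data under any documented
  exclusion set (the package computes 0.767); `reproduce_paper` reports the
  computed value with an explicit note, and the printed cutoff, sensitivity
  and specificity from the same analysis do reproduce. The printed Z/P
  values of the group-comparison tables are recomputed under both
  Mann–Whitney and KS but not asserted, since the original test-to-row
  pairing is ambiguous.

## Synthetic data

`make_model_pair` builds a tubular parent artery (radius 2 mm, length 20 mm
by default — a typical intracranial vessel) carrying an ellipsoidal dome
(semi-axes along the vessel, around it, and outward; default
2.2 × 2.0 × 2.4 mm) over a circular neck (default radius 1.6 mm, giving
I_S ≈ 6.7, within the observed cohort range). The tube is meshed as an
O-grid (a structured annulus blending the exact rim circle onto a square
collar, Delaunay outside), so both models share the identical tube mesh and
rim polyline vertex-for-vertex; the dome is an ellipsoid cap blended onto
the rim over a smoothstep collar, with an optional Gaussian bleb. The neck
patch of Model B is the isometrically unrolled tube wall, so its true area
is exactly π·r_n²; sac area/volume ground truth is computed by refining the
parametric surface until quadrature changes by < 0.1 %.

What the generator does *not* emulate: patient-specific irregularity,
imaging/segmentation noise, non-circular necks, mural thrombus, vessel
curvature and branching. Passing tests therefore demonstrate correctness of
the geometric and statistical machinery on smooth saccular geometry, not
clinical performance on patient data.

Synthetic cohorts draw log-normal I_S and I_BA per group (both strictly
positive and right-skewed in the bundled data), with group parameters fitted
once from the bundled table; I_δ is always derived as I_BA/I_S, never
sampled. Volume follows a per-group log-linear model in I_S with fitted
residual spread, which reproduces the decreasing correlation pattern across
groups. Sampling I_S and I_BA independently slightly inflates the I_δ
spread relative to reality (the two are positively correlated within
groups) and allows occasional non-physical I_δ < 1 draws in group C; the
closed-form generating AUC used as truth in recovery tests accounts for
this by construction.

## Numerical choices and problem sizes

- 0-based vertex indexing, mm units, outward CCW orientation; degenerate
  faces (area < 1e-12 mm²) and non-manifold edges rejected at construction.
- Enclosed volume is the signed-tetrahedron divergence sum; an independent
  z-flux formula agrees to 1e-12 relative in tests. Open meshes raise an
  error naming their boundary loops; negative totals raise an orientation
  error.
- Port capping is a centroid fan: any triangulation of a planar port gives
  the same enclosed volume, and the vessel ports are planar by construction.
- Welding merges vertices within 1e-8 mm; winding consistency is restored
  by breadth-first propagation and the global sign by requiring positive
  capped volume.
- Test meshes use target edge lengths of 0.3–0.45 mm on ~2 mm vessels
  (10³–10⁴ triangles), the resolution at which the refinement studies sit
  comfortably within their stated tolerances; the property suite runs 20
  random aneurysm specs drawn from a realistic range (dome semi-axes
  1.8–3 mm, neck 60–85 % of the smallest dome axis).
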