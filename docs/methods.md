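# Methods

## Model

A T = 1 icosahedral capsid is treated as a tiling of the unit sphere by 60
congruent tiles, one per subunit.  Every admissible tile arises by cutting
the spherical dihedron — the doubly-covered fundamental triangle of the
chiral icosahedral group, covering 1/120 of the sphere — along a Y-shaped
tree of three geodesics that meet at a junction point and end at the 2-,
3- and 5-fold vertices, then unfolding.  The resulting polygon alternates
the three axis points with the three mirror images of the junction point
across the triangle's edges (reflections in the great circles through the
corresponding axis pairs).  Its spherical area is exactly 4π/60 for every
junction placement, and the 60 rotated copies partition the sphere.

Two consequences of the construction are used throughout:

- The 2-fold axis point is always a straight (angle π) vertex of the
  hexagonal vertex list whenever the junction is off that axis, because the
  two incident edges are images of one cut branch under the half-turn.
  Generic tiles are therefore geometrically pentagonal.  `Tile` exposes both
  views: `vertices_distinct` (coincident role vertices merged: 6 generic,
  4 in each degenerate class) and `corners` (straight vertices absorbed:
  5 generic, 4 on the 2-fold, 3 on the 3- and 5-fold axes).
- Tile adjacency is generated by the local 2-, 3- and 5-fold symmetry steps,
  but a contact only exists while its interface arc has positive length;
  placing the junction on an axis collapses that contact, which is what
  switches the dual polyhedron between the four classes.

### Coordinate frame

The VIPER convention fixes two 2-fold axes along z and x.  The fundamental
triple used here is axis2 = +z, axis3 = (1, 0, φ²)/‖·‖ (20.905° from z, in
the xz plane) and axis5 = (0, ±1, φ)/‖·‖ (31.717° from z), with the sign of
the y-component selecting the handedness; the right-handed triple has its
2, 3, 5 vertices counterclockwise seen from outside (positive triple
product).  The three points are pairwise adjacent axes (3–5 separation
37.377°) and bound a triangle of area π/30.  Note that the 5-fold axis of a
*mutually adjacent* triple necessarily lies off the xz plane: the xz plane
contains 3- and 5-fold axes, but the in-plane 5-fold (58.28° from z) is not
adjacent to both z and the in-plane 3-fold, and three coplanar-with-origin
points cannot bound a triangle.

The 60 rotations are generated by closure from the 72° rotation about axis5
and the half-turn about axis2, deduplicated at 1e-6 on matrix entries and
sorted lexicographically on rounded entries for deterministic ordering.

### Gnomonic projection

All planar reasoning uses the central projection onto the plane tangent at
+z, under which geodesics are straight lines.  Junction points are specified
in this plane; the projected fundamental triangle has vertices (0, 0),
(1/φ², 0) ≈ (0.382, 0) and (0, ±1/φ) ≈ (0, ±0.618).

## Validity, degeneracy and point-in-tile numerics

A junction is valid when all tile vertices lie strictly inside the
projection hemisphere and the projected polygon is simple; simplicity is
delegated to shapely's polygon validity (touching at shared vertices
allowed), with an independent brute-force segment-intersection oracle in the
test-suite.  The allowed ("gray") region is thereby defined operationally by
the self-intersection test.  Degeneracy labels use an angular tolerance of
1e-6 rad (configurable) between the junction direction and each axis point.

Point-in-tile tests rotate the tile's vertex centroid to the pole before
projecting (avoiding hemisphere clipping) and use planar polygon containment
(even-odd, via shapely), which handles concave tiles.  Coverage tests
exclude a boundary band by comparing containment in ±2e-3-buffered polygons.

The dual spherical map is built geometrically: all 360 tile-vertex images
are clustered at 1e-6 rad (KD-tree union-find); every cluster where k ≥ 3
distinct tiles meet is a tiling vertex contributing one k-sided dual face.
Clusters with only two incident tiles (the straight 2-fold points of generic
tilings) are absorbed into edges automatically by the k ≥ 3 rule.  Euler's
formula V − E + 60 = 2 is verified in all four classes
(V, E = 92, 150 generic; 62, 120 on the 2-fold; 32, 90 on the 3- and
5-fold).

## Fitting

- **Normalization.** Each Cα position is radially projected to the unit
  sphere; the effective amino-acid radius r (default 3.3 Å, configurable)
  becomes an angular radius r/‖x_i‖ and, in the plane, a disc of radius
  tan(r/‖x_i‖)/cos^1.5 θ_i — the equal-area magnification of the gnomonic
  map at colatitude θ_i.
- **Domain re-orientation.** Deposited chains may occupy any of the 60
  symmetry domains; the group rotation bringing the mean atom direction
  closest to a chirality-neutral target (the normalized sum of both
  triangles' vertices) is applied first, making the fit equivariant under
  group rotations of the input.
- **Chirality.** argmin over σ of max_j min_i dist(p_i, X_j^σ) with planar
  distances to the three projected axis points; an exact tie (1e-9) raises
  rather than guessing, and σ can be forced.
- **Dice objective.** Region areas are exact planar polygon areas (shapely;
  discs as 16-segment buffers) rather than raster sums — deterministic,
  unbiased by grid resolution, and fast enough for a population optimizer.
  The objective is 1 − D + P with the penalty P = 1 on invalid junctions:
  a constant suffices for a population-based search, and no functional form
  is otherwise implied by the model.
- **Optimizer.** Seeded scipy differential evolution (Sobol init, popsize
  parameter 16, ≤ 60 generations, no polish) over the valid region's
  bounding box padded 20 % (the box is found once per handedness by a
  coarse validity scan), followed by a Nelder–Mead refinement of the best
  point.  Two runs with the same seed are bit-identical.

On synthetic capsids at the study conditions (150 points/subunit, 100 Å
shell, 0.5 Å isotropic jitter) this recovers the generating junction with
median error well under 0.02 plane units and the correct chirality in all
tested placements, including near-degenerate and concave ones.

## Screw analysis

The relative transform of a pose pair comes from least-squares (Kabsch)
superposition over all supplied points — mathematically equivalent to the
three-point Rodriguez solution for rigid inputs, and better conditioned
under noise; the test-suite asserts the Rodriguez relations pointwise at
< 1e-6 Å on noiseless pairs.  The rotation angle comes from the rotation
vector (φ ∈ [0°, 180°]); at φ = 180° the (ω, φ) ↔ (−ω, −φ) ambiguity is
resolved by making ω's first nonzero component positive; φ = 0 with
translation uses the translation direction as axis, and the identity is
flagged degenerate.  ρ solves (I − R)ρ = t⊥ in the plane normal to ω, then
is slid to the foot of monomer 1's centroid.

Reference pairs are all 60 × 59 = 3 540 ordered pairs of symmetry copies;
their screw angles take only the group's conjugacy-class values
{72°, 120°, 144°, 180°} (with multiplicities 720/1200/720/900) and d∥ = 0.
RMSD against references is *anchored*: monomer 1 is superposed exactly, and
monomer 2's deviation is measured without refitting.  When every pose shares
the reference monomer this minimization reduces exactly to a minimum over
the 59 non-identity group elements, which is how the maps are computed (a
test cross-checks the reduction against the brute-force pairwise path).

Maps bin poses at 1° in φ and 0.5 Å in d∥ (translation range data-driven),
keep the per-cell maximum score and minimum reference RMSD, and smooth along
the rotation axis with a ~5° boxcar.  For smoothing, empty cells are first
filled with a neutral baseline (grid minimum for scores, maximum for RMSD),
matching the filled-contour reading of such heatmaps; raw grids keep NaN.
The raw maximum map is monotone non-decreasing under added poses.

## Synthetic generators

`synth_capsid` samples directions uniformly in area inside the generating
tile by rejection from its bounding spherical cap (numpy PCG64, seeded),
scales to the shell radius, adds isotropic Gaussian jitter, and copies by
all 60 rotations into chains A–9 (chain A is the generating subunit; PDB
output is CA-only glycines, byte-deterministic per seed).  Defaults — 150
points/subunit, 100 Å radius, 0.5 Å jitter — are the study conditions used
by the recovery tests; 100 Å is a typical T = 1 shell radius.  `synth_poses`
plants n_near poses at the exact symmetry step about a chosen axis perturbed
by small random rotations (sd noise_deg, default 1°), with scores
score_gap (default 6, unit sd) above n_decoys uniform random rigid poses.

What the generators deliberately omit: real chain connectivity, secondary
structure, non-uniform atom density, shell thickness, and docking-score
physics.  Passing recovery tests therefore demonstrate the estimators'
correctness and identifiability under the model's own assumptions, not
robustness to the full complexity of experimental capsids, which
additionally requires VIPER-aligned coordinates and (for maps) a docking
engine's pose ensembles.

## Problem sizes and determinism

The shipped tests and the acceptance script run entirely on generated data:
tilings of 60 tiles, 10 000-point coverage samples (2 000 per junction in
the 100-junction sweep), Monte-Carlo area oracles at 4 × 10⁵ samples, 1 000
random rigid pairs for the Rodriguez property, 9 recovery fits at the study
conditions, and pose ensembles of 180 poses against the full 3 540-pair
reference set.  Every stochastic step takes an explicit integer seed; there
is no hidden global state.

## Known limitations

- The description is strictly 2-D on the sphere: radial (shell-thickness)
  interactions and stacked interfaces are outside the model, and capsids
  dominated by them will fit poorly even with the correct symmetry.
- T ≠ 1 lattices are supported only through the Caspar–Klug T-number
  helper; tile construction itself is T = 1 (a dimer can be treated as one
  tile, as for 120-subunit shells).
- Input structures must already be in the VIPER icosahedral orientation;
  no re-alignment is attempted.
- A single effective amino-acid radius is used for the silhouette (a
  per-residue table could be slotted in at `SubunitCloud.radius_r`).
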