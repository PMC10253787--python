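# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several conventions were
defensible.

## Superposition and fluctuation analysis

Frames are rigid-body superposed onto a reference (the first frame by
default, or any supplied frame) by the least-squares rotation (Kabsch
solution, computed via `scipy`'s `Rotation.align_vectors`), fitted over a
configurable atom selection and applied to all atoms.  The default fit
region is the backbone of residues 432–713 across all chains — the
transmembrane domain plus the conserved juxtamembrane helix of the
channel family this package targets.  Superposition requires at least
three non-collinear fit atoms; degenerate fits raise.

RMSF is computed per residue about the time-mean position after
superposition, from a representative atom (Cα by default; whether
published per-residue profiles use Cα or all heavy atoms is often
unstated, and Cα matches the Cα-based distance analyses, so it is the
logged default).  Both per-chain and chain-averaged profiles are
produced; the subunits of a symmetric tetramer sample equivalent
environments, so the chain average halves sampling noise in state
comparisons.

The state-comparison statistic is the fractional fluctuation change

    ΔRMSF/RMSF̄ = 2 (RMSF₁ − RMSF₂) / (RMSF₁ + RMSF₂),

bounded in [−2, 2], antisymmetric under state exchange, and defined as 0
where both profiles vanish.  For an isotropic per-coordinate Gaussian
fluctuation of standard deviation σ the expected RMSF is σ√3, which is
the closed form recovery tests use.

## Pore radius profile

At each z on a grid (default step 0.25 Å), the pore radius is

    R(z) = max_{|p−c| ≤ b}  min_i ( |p − xᵢ| − rᵢ ),

the radius of the largest probe sphere centred in the slice that touches
no atom's van der Waals surface, with the center confined to a lateral
disk of radius `b` (default 8 Å) around a search center.  Distances are
3-D — atoms above and below the slice constrain it.  Radii default to
the Bondi set with 1.70 Å for unknown elements; the HOLE-distribution
"simple" set is available (`VdwTable.hole_simple()`).

The maximisation runs a dense coarse lateral grid (0.8 Å), takes the
five best coarse points as starts, and refines each with three levels of
nested 9×9 local grids (final resolution ≈ 0.0125 Å).  The multi-start
refinement is deterministic — no random restarts — so identical inputs
give identical profiles.  The whole search is compiled with numba (a
pure-numpy fallback produces the same values).  The test suite holds the
profiler to within 0.05 Å of an exhaustive 0.05 Å-grid search on a
battery of constructed pores (rings, cones, hourglasses, mixed radii).
Radii are capped at 10 Å and flagged where the cap or an empty slice is
hit; a grid-based maximisation also preserves the exact-shift identity
(inflating every vdW radius by δ lowers every radius by exactly δ).

Structures are assumed oriented with the pore axis along z (the
generator guarantees this; for experimental structures align the
symmetry axis to z first).  One caveat specific to the synthetic bundle:
four bare helices around an axis enclose the pore only near the gate
ring — a probe allowed to wander 8 Å laterally escapes through the
windows between helices and reports the fenestration, not the pore.
Synthetic-data analyses therefore use a tighter lateral bound (4 Å),
which brackets the on-axis gate without touching the windows.  Real
channels, whose pore lining is sealed by the S5/pore-helix wall, do not
need this.

**Permeability.**  A frame is water-permeable when its minimal pore
radius strictly exceeds a threshold, default 1.15 Å — the radius below
which single-file water passage is blocked.  The literature also uses a
~2.0 Å criterion for hydrophobic-gate opening; both are plain
parameters (`permeable_fraction(series, threshold=...)`).

**Water flux.**  A permeation event is one complete traversal of both
gate planes (defaults: the mean z of the selectivity-filter residues
643–644 and of the bundle-crossing residue 679, both configurable or
overridable with explicit z values) while remaining within a lateral
bound of the axis whenever between the planes.  Partial entries and
oscillations across a single plane are not counted; a water that jumps
across both planes between consecutive frames counts once.

## Domain geometry

Rg is the unweighted root-mean-square distance of the selected atoms to
their centroid, per frame.

The twist angle of a pore-lining helix (default residues 658–692) is
computed per chain per frame: the helix principal axis is the dominant
eigenvector of the 3×3 positional covariance of its Cα atoms
(equivalent to a least-squares line fit), sign fixed toward +z; the
radial unit vector r points from the z axis to the helix centroid with
its z component removed (the anchor point for r is the centroid — a
choice, since a gate residue would serve equally); the axis component
along r is projected out and the angle to ẑ of the remainder is
reported in [0°, 90°].  The projection makes the angle a *tangential*
lean measure: a purely radial lean reports 0°, and in the generator's
convention (radial tilt applied first, tangential second) the recovered
angle equals the tangential tilt exactly, independent of radial tilt.
Degenerate cases (centroid on the axis, axis parallel to r) are flagged
undefined rather than guessed.

Distance matrices are time-mean Cα–Cα distances within one subunit;
residues lacking a Cα are dropped with a warning.  The state comparison
is ΔD = D₁ − D₂ together with a correlation heat map C where C[i, j] is
the Pearson correlation of rows i and j of ΔD — each residue's vector of
distance changes to all others.  (Correlating the rows of ΔD, rather
than rows of D₁ against rows of D₂, is the logged choice; the input to
`numpy.corrcoef` is ΔD, so the alternative is one call away.)
Zero-variance rows (identical states) yield NaN, flagged rather than
silently 1.

## Hydrogen bonds

A bond between acceptor A, hydrogen H and donor heavy atom D is present
when d(A, D) < 3.0 Å **and** ∠A–H–D > 135° (measured at H), both strict
— the boundary values are absent.  Donors and acceptors default to N
and O heavy atoms (S excluded; the bonds of interest are backbone and
side-chain N–O contacts); hydrogens are paired with the nearest eligible
heavy atom within 1.2 Å.  A donor with several hydrogens forms the bond
in a frame if any hydrogen satisfies the angle criterion.  Topologies
without hydrogens raise a configuration error instructing the user to
supply a protonated topology.

Occupancy is the exact fraction of frames in which a candidate pair
satisfies both criteria; pairs whose A–D distance never drops below a
prefilter radius (8 Å) are skipped without per-frame evaluation, which
cannot change any reported occupancy.  The differential report lists
bonds whose occupancy changes by more than a threshold between two
states — 0.20 by default, interpreted as an *absolute* difference
(the natural reading of a ">20%" cut on probabilities that are
themselves fractions); bonds seen in only one state use 0 for the other.

## Dihedral PCA and free-energy surfaces

Backbone φ/ψ are computed from consecutive N, CA, C atoms with the
standard atan2 torsion formula (IUPAC sign convention, verified against
an independent implementation), wrapped to (−180°, 180°].  Terminal
residues lacking a complete dihedral are excluded.  Chain continuity is
judged on the *time-mean* structure (mean C(i)–N(i+1) distance ≤ 2 Å):
with uncorrelated per-frame positional noise the instantaneous bond
distance fluctuates above any fixed cutoff, while the mean structure is
a stable connectivity reference.

Each angle θ is mapped to (sin θ, cos θ) before covariance construction
— the standard dPCA treatment of angular periodicity; a raw-angle mode
exists behind `circular=False` for comparison.  The covariance of the
stacked variables is eigendecomposed (symmetric `eigh`, eigenvalues
clipped at 0 and sorted descending) and frames are projected onto the
leading components.  The eigenvalue sum equals the total variance of the
sin/cos data to numerical precision (trace conservation), which the
tests assert at 1e-10.

The free-energy surface over (PC1, PC2) is F = −k_B T ln(ρ/ρ_max) from
a 2-D histogram (default 50×50 bins), so the most populated bin is 0 and
all occupied bins are ≥ 0; empty bins are NaN, never infinite.  The
default temperature is 303 K, the production temperature of the
simulations this pipeline addresses, with k_B = 0.0019872041
kcal/(mol·K) applied at the configured T exactly (k_B·303 K ≈ 0.602
kcal/mol).

## The synthetic-channel generator

The generator emulates the *statistical* structure the analyses consume,
not the physics that produces it:

- **Geometry.**  n (default 4) ideal α-helical backbone traces (N, CA,
  C, O placed by internal-coordinate construction at φ = −57°,
  ψ = −47°), exactly n-fold symmetric about z, each tilted about its
  centroid (radial tilt first, tangential second) and placed at a set
  distance from the axis.  Default chains span residues 432–713,
  matching the fit region.  A gate ring of carbons at z = 0 has ring
  radius = aperture + r_C, so the axis clearance *is* the aperture
  analytically.
- **Dynamics.**  Helix atoms receive i.i.d. per-frame Gaussian noise
  with per-residue σ (default 0.5 Å — the magnitude of a rigid
  transmembrane helix, whose RMSF stays below ~2 Å); there is no
  autocorrelation, which suffices for RMSF, occupancy and geometry
  recovery.  Correlated-motion tests instead plant explicit dihedral
  modes (`planted_dihedral_series`).  The gate switches between a closed
  and an open aperture in an exactly planted fraction of frames, so the
  permeable fraction has a known exact value.  The default state mirrors
  the studied closed channel: aperture 0.59 Å, tangential tilt 25°,
  2000 frames at 250 ps (500 ns of production).
- **Planted hydrogen bonds.**  Each triplet is three atoms (donor N,
  H, acceptor O) far from the pore; on exactly ⌊occupancy·n_frames⌉
  frames the geometry satisfies the criteria (d = 2.8 Å, linear), on the
  rest it violates the distance (4.5 Å).  Occupancy recovery is
  therefore exact, not statistical.
- **Waters.**  Single-particle pseudo-atoms named OW; traversing waters
  move monotonically from below the lower gate plane to above the upper
  one, resident waters oscillate strictly below the lower plane.
- **Manifest.**  Every dataset carries a JSON manifest with all planted
  truth; recovery tests read truth only from the manifest.  A fixed seed
  yields bit-identical output.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: temporal autocorrelation and
conformational substates, side chains and realistic packing (the bundle
is an open lattice away from the gate; see the lateral-bound caveat
above), solvent and membrane, and any coupling between gate aperture and
helix motion.  The pipeline's correctness on real trajectories rests on
the geometry of each measurement being validated, not on the generator
resembling a force field.

## Problem sizes

The default test and acceptance workloads use bundles of 4 × 74-residue
helices (residues 640–713, which contain the pore-lining helix, both
gates and the helix–linker region) at 2000 frames for parameter-recovery
runs, and smaller bundles for unit tests.  These sizes give sampling
errors comfortably inside the asserted tolerances (e.g. the relative
standard error of an RMSF estimate at n = 2000 is ≈ 1.6%, against a 5%
band) while keeping a full suite run in the low minutes on one CPU.
Full-length chains (432–713) are exercised where only construction and
selection are at stake.

## Known limitations

- The pore profiler's lateral search is grid-initialised; a pore whose
  cross-section at some z is split into disconnected pockets narrower
  than the coarse step (0.8 Å) could in principle hide its true optimum
  from all five starts.  None of the oracle battery's geometries —
  or any plausible channel cross-section — does this.
- `min_radius_series` profiles every frame independently; it does not
  follow the HOLE convention of walking a connected channel path, so it
  reports the largest sphere per slice even if slices are not mutually
  connected.
- H-bond donor/hydrogen pairing is inferred from the first frame's
  geometry; topologies with mobile protons (proton hops) would need an
  explicit donor list.
- Replica handling: multiple trajectories of one state are analysed
  independently (or concatenated by the caller); no replica-weighting
  scheme is provided.
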