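# Methods

## Model and procedure

`polarframe` treats a protein chain as a list of standard amino-acid
residues with resolved heavy atoms and asks, for each central arginine or
lysine, where the side chains of neighboring residues sit relative to the
charged terminus. Three constructions carry the analysis:

**Canonical frame.** A frame definition names an origin atom, an ordered
anchor triple, and three reference coordinates (first = origin). The
transform translates the origin atom to (0,0,0) and applies the Kabsch
rotation of the translated anchors onto the reference *about the pinned
origin* — both point sets are expressed relative to their origins and no
centroid re-centering is performed, so the origin atom lands exactly at
(0,0,0). A centroid-centered variant (`method="centroid"`) is available
for sensitivity checks; with it the origin atom is only approximately at
the origin. The Kabsch solution is the SVD closed form with the
reflection branch corrected to det = +1, so frame handedness (NH1 on +y,
guanidinium normal = +z) is identical for every residue. Collinear
anchors raise a degeneracy error rather than returning an arbitrary
rotation.

The reference triples are dimensionless (unit-scale) while real anchors
have ~1.0–1.5 Å bonds. The rotation is applied without scaling: a
pure-rotation fit of a similar triangle still orients the plane and the
in-plane bisector exactly, which is all the frame requires. NH1/NH2
labels are taken as deposited and never swapped, since label-specific
density (e.g. adjacent to NH1) is a reportable signal; users who want
label-free maps can duplicate pairs with the labels exchanged.

**Pair extraction.** Neighbor distances are measured between neighbor
side-chain heavy atoms and the central *defining-atom set* (Arg: NE, CZ,
NH1, NH2; Lys: CD, CE, NZ), with 5 Å as the default cutoff; an
alternative all-side-chain-atom mode exists because the two readings of
"within 5 Å of the residue" differ. Glycine is never a neighbor (no side
chain); sequence-adjacent residues are included by default with an
optional |Δseq| ≤ k exclusion for sensitivity analysis; the search is
within-chain by default. The spatial search uses a k-d tree whose
contract is exactness — the test suite holds it to a brute-force
all-pairs scan at 1e-9 Å.

**Spherical-polar summary.** In the canonical frame, θ = arccos(z/r)
(degrees from the +z normal; 90° = in-plane) and ψ = atan2(y, x)
(degrees from +x, in (−180, 180]); points on the z-axis take ψ = 0, the
origin takes θ = 0. The polar origin is the frame origin atom (CZ/NZ)
while distance cutoffs use the defining set — the two deliberately
differ, and the choice of origin atom does affect the distributions. The
closest-atom rule picks the neighbor side-chain heavy atom with minimal
distance to the defining set (6 Å default cutoff), breaking exact ties
by atom-name order. Distance shells are half-open (d_min, d_max] so
consecutive per-class cutoffs (3.5/3.75/4.0/4.5 Å) partition atoms
exactly once. Atom-class selectors (carboxylate-O, amide-O/N,
hydroxyl-O, S, indole-N, sidechain-C, sidechain-heavy) are shipped as
data keyed by residue type.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| extraction cutoff | 5.0 | Å | side-chain contact range around the charged terminus |
| polar (closest-atom) cutoff | 6.0 | Å | broader envelope used for angular maps |
| shell cutoffs | 3.5 / 3.75 / 4.0 / 4.5 | Å | per-atom-class close-contact rendering classes |
| density bins | 5 × 5 | deg | resolves the ~60°-spaced guanidinium N–H directions with ≥10 bins between modes |
| subsampling | first 4000 | pairs | caps very large interaction classes; a seeded random policy is available |
| axial cap | 45 | deg | isotropic reference value 1 − cos 45° ≈ 0.293 sits well clear of 0 and 1 |

Solid-angle weighting of density maps is off by default (raw counts,
with the polar-distortion caveat documented); when enabled each bin is
divided by sin(θ_center), guarded below by sin(half a bin width).

## Reading policies

PDB input goes through gemmi. Model 1 only; standard amino acids only
(HETATM, waters and modified residues such as MSE excluded); hydrogens
dropped; alternate locations resolved to the highest-occupancy conformer
with ties broken by alphabetical altloc code — deposited files do not
state a preferred conformer, so the rule is chosen to be deterministic
and conventional. Per-pair output files contain side-chain heavy atoms
only (no backbone N/CA/C/O/OXT, no hydrogens) in fixed-width PDB ATOM
format, which quantizes coordinates to 1e-3 Å; CB counts as side chain.

## The synthetic generator

The generator emulates exactly the geometric degrees of freedom the
analysis measures, with exact ground truth:

* **Ideal central residues** whose anchors sit exactly on the reference
  coordinates times an anchor scale (Arg 1.33 ≈ the guanidinium C–N bond
  in Å; Lys 1.0, the dimensionless frame convention). Non-anchor atoms
  sit at fixed idealized positions with realistic bonded distances;
  rotamer realism is deliberately out of scope.
* **Planted neighbors** whose contact atom sits at a requested
  (r, θ, ψ); remaining atoms extend radially outward in 1.6 Å steps,
  which guarantees (and the generator verifies) that the contact atom is
  the unique closest atom. Optional isotropic Gaussian jitter models
  coordinate noise.
* **Random poses** uniform over SO(3) (normalized Gaussian quaternion)
  with translations uniform in a 20 Å box, from a seeded generator;
  fixed seeds give byte-identical PDB text and ledgers.
* **Population mixtures** of three angular components: axial caps
  (area-uniform within θ < cap or θ > 180° − cap), equatorial bands
  (θ uniform in 90° ± band; ψ Gaussian around modes defaulting to the
  three guanidinium N–H sector directions 60°, −60°, 180°, sd 15°), and
  uniform-sphere controls. Contact radii are uniform on [3.0, 4.5] Å,
  the range spanned by the close-contact shells. The Arg-like preset
  (non-polar axial + polar equatorial) and Lys-like preset (both
  isotropic) encode the qualitative segregation the survey observes.

Steric validity is enforced **between** residues (≥ 1.5 Å): covalently
bonded atoms within a residue are legitimately closer (a carbonyl C=O is
1.23 Å), so an all-atom limit would be unsatisfiable by real geometry.
Clash-rejected draws are retried within the already-chosen mixture
component so component weights are honored exactly.

What the generator does **not** emulate: packing against a full protein
environment, backbone-mediated contacts, waters, crystal symmetry,
occupancy/altloc disorder, or correlated multi-neighbor geometry. A
passing parameter-recovery test therefore shows the *pipeline* is
faithful (correct frames, distances, angles, counts under arbitrary
poses and labeled mixtures); it does not by itself validate conclusions
about real proteins, which additionally depend on the culled input set.

## Numerical choices

* Kabsch degeneracy threshold: second singular value ≤ 1e-8 × the first.
* Rotation properness and orthogonality asserted at 1e-9 on
  construction of every rigid transform.
* Ideal anchors are recovered at < 1e-12 after a pose; the 1e-6
  tolerances quoted on worked examples leave headroom for accumulated
  rounding in long compositions.
* Pair files round-trip coordinates at the 1e-3 Å precision of the PDB
  fixed-width format; for exact-recovery work the generator hands back
  full-precision in-memory residues alongside the text.
* Closest-atom ties (exactly equal distances) break by atom-name order;
  ψ at the −180° boundary is normalized to +180°.

## Problem sizes

The test and acceptance workloads use synthetic populations of 30–2000
structures (two residues, ~20 atoms each), 50 randomized structures for
oracle equivalence, 1e5 points for density-map uniformity, and 1e3
randomized trials for the invariant suite — sizes at which the planted
statistics (e.g. a binomial 99% CI at n = 2000 of ±0.026 around an
axial fraction of 0.7) are sharp enough to detect real pipeline defects.

## Known limitations

* Real-data mode trusts the culled chain list; resolution/R-factor
  fields are not re-validated from PDB headers.
* No mmCIF input, symmetry expansion, or biological-assembly reasoning;
  cross-chain contacts are only found when a full multi-chain file is
  scanned without a chain list.
* Backbone (main-chain carbonyl) interactions with the central residue
  are not analyzed.
* Density maps are raw 2-D histograms; no kernel density estimation or
  enrichment significance testing is provided.
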