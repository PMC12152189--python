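# Methods

This note records the geometric models implemented by `frapc`, the
conventions and defaults that matter, what the synthetic generators do and
do not emulate, and the numerical choices behind the tolerances in the test
suite.  It states no empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Structure model and input policy

Structures are read with biotite (mmCIF/PDBx and PDB) into a light
hierarchical container (chains → residues → atoms).  Policy decisions:

* **First model only.**  Cryo-EM depositions are single-model; NMR-style
  multi-model files contribute only model 1.
* **Alternate locations** are resolved per atom name: highest occupancy
  wins, ties go to the lexicographically first altloc identifier.  All
  downstream calculators assume a single conformer.
* **Hydrogens** are retained on input but ignored by every geometric
  calculation (cryo-EM models carry none; criteria are heavy-atom based).
* **Chain roles are external.**  The mapping chain → subunit role (ApcA,
  ApcB2, ApcD5, ApcE2, …), cylinder index, ring index and ApcE2 REP-domain
  residue ranges comes from a TSV/dict supplied by the user, never from
  sequence inference.  This keeps the pipeline deterministic and testable;
  deposited entries need a small per-entry table.

## Bilin planarity

Ring planes are defined by fixed atom triplets — A: (NA, C3A, C4A),
B: (NB, C3B, C4B), C: (NC, C3C, C4C), D: (ND, C3D, C4D) — and the plane
normal is normalize((p₂−p₁)×(p₃−p₁)).  The inter-plane angle is the
arccosine of the normal dot product (clamped to [−1, 1] against rounding),
centered by θ → 180°−θ for θ > 90°.  The centering makes the statistic
invariant under the arbitrary sign of a cross-product normal; it is why all
reported angles live in [0°, 90°].

A deliberate choice: the normal comes from the three defining atoms only,
not from a least-squares plane over all five ring atoms.  The SVD-plane
variant exists in the test suite as an independent oracle (for three points
both definitions coincide exactly), never as the implementation.

θ_BC is computed and stored alongside θ_AB and θ_CD even though the central
B–C pair barely varies in real structures — keeping it lets that claim be
checked rather than assumed.

## Conformer classification

Stereodescriptors like ZZZ,ssa name, per methine bridge (A–B, B–C, C–D),
the configuration about the bridge double bond and the conformation about
the ring-adjacent single bond.  The literature rarely prints the exact
torsion atoms, so the package fixes them explicitly; for the bridge between
rings X and Y with methine carbon CH:

* configuration: torsion(N_X, C4X, CH, C1Y), |τ| < 90° ⇒ Z, else E;
* conformation: torsion(C4X, CH, C1Y, N_Y), |τ| < 90° ⇒ syn (s), else anti (a).

Torsions within 5° of the 90° boundary set a `boundary_warning` flag on the
label instead of silently committing to one side.  The synthetic bilin
generator realizes any requested label and verifies itself with this same
classifier at build time, so the convention is closed under round trip.

## Cylinder axes and twist

Ring centroids are unweighted means of backbone atoms N, CA, C, O
(CB excluded — "backbone" in the conventional sense) over polymer residues
of the chains annotated to that ring, minus ApcC chains and ApcE2 residues
inside REP-domain ranges; both thread the cylinder interior and would bias
the centers.  The axis is the total-least-squares line: anchor at the
centroid mean, direction the first principal direction of the centered
centroids (sign from ring 1 toward ring 4), with the root-mean-square
perpendicular distance reported as fit quality.  With only four well-spread
centroids any reasonable line definition agrees to within noise; TLS is the
standard reading of "line of best fit" for a 3-D point set.

The twist between two cylinders is the inter-axis angle folded to [0°, 90°]
by the same centering rule.  Folding is the substantive convention: the two
cylinders of a bicylindrical antenna are antiparallel, so the raw
inter-vector angle is obtuse (≈150° for a 30° twist) and only the folded
angle matches the quantity of interest.

## C2 axes

The two-fold axis relating two halves of a complex is extracted by Kabsch
superposition of pooled CA pairs (paired position-by-position over shared
residue numbers per chain pair), then reading the rotation: angle from the
rotation-vector norm, direction from the eigenvector with eigenvalue 1, and
an anchor point solving (I−R)p = t⊥ by least squares (the minimum-norm
solution on the screw axis).  Superpositions whose rotation is below 150°
raise "not an approximate two-fold" — the gate that catches wrong pairings.

## Composite assembly and pigment distances

Components are never mutated: fitting returns a lazy rigid transform from
pooled CA pairs (Kabsch via scipy's `Rotation.align_vectors`, reflections
impossible by construction), requiring at least 50 pairs as anchor.  Placed
chains are renamed `"<role>:<original>"` — collision-free and reversible.

Edge-to-edge distance is the minimum over retained heavy-atom pairs.  The
retained set is the conjugated system relevant to excitation energy
transfer: for chlorophylls the phytyl tail (plain-numbered carbons C1–C20
and the ester oxygens) is excluded by default; for bilins all heavy atoms
count, with `exclude_propionates=True` exposing the ambiguity of whether
the propionate arms belong to the "edge".  The arg-min atom pair is always
reported so a surprising distance can be inspected.

## Pocket contacts

All criteria are plain distances/angles over heavy atoms, with defaults
from common structural-biology practice (H-bond donor–acceptor ≤ 3.5 Å,
salt bridge ≤ 4.0 Å, ring centroids ≤ 5.5 Å with normals within 30° after
folding, steric ≤ 4.0 Å).  The source comparisons these reproduce are
qualitative, so none of these numbers is science — they are configuration,
and enlarging any cut-off can only add contacts of that type (a tested
monotonicity property).  Donor/acceptor roles come from a minimal built-in
chemistry table (standard residues + the bilin: ring nitrogens donate,
oxygens accept, propionate carboxylates salt-bridge); no protonation
inference is attempted.  A charged-N/carboxylate pair inside both cut-offs
is reported once, as a salt bridge.  "Steric" contact — one record per
partner residue at the closest not-otherwise-classified pair — is a
stand-in definition; the term has no agreed distance in the literature.

## Synthetic generators: what they emulate, what they do not

The generators produce *geometry*, not physics: bond lengths and angles are
plausible (1.38 Å ring bonds, ~120° bridge angles) but not energy-minimized,
pseudo-subunits are backbone-only rings of residues, and no cryo-EM density
or B-factor structure is emulated.  A green round-trip test therefore
establishes that the analysis code measures what the constructor prescribed
— it says nothing about model quality of real depositions, radiation
damage, or map interpretation.

* **Bilins**: planar baseline assembled ring by ring, bridge torsions set
  exactly (0° or 180°), then rings A/D (and the C+D block) tilted about the
  bridge bonds, which lie in the shared plane — so the prescribed
  inter-plane angles are exact by construction, and the build self-verifies
  against the package's own analyzers before returning.
* **Bicylinder**: cylinder 2 is the exact 180° image of cylinder 1 about
  the prescribed C2 axis; the cylinder axes are tilted off that axis by
  half the raw angle, so the folded twist is exact and the C2 relation
  holds simultaneously.  Backbone atoms are placed with full rotational
  symmetry about each ring center, making the noise-free ring centroids
  exact.  Decoy ApcC chains and ApcE2 chains living entirely inside their
  REP ranges are excluded *completely* by a correct implementation, which
  keeps the with-decoy centroids exact too — an intentionally sharp test.
* **Pockets**: partner residues are rigid idealized templates placed so the
  named contact atom sits at exactly the requested distance, along the
  first clash-free direction from a deterministic candidate list (≥ 2.45 Å
  clearance for every non-contact pair).  π-stack partners are placed
  plane-parallel at the requested centroid separation.
* Noise, where requested, is iid isotropic Gaussian per atom under a
  mandatory spec seed; identical specs produce byte-identical files.

Default ensemble parameters in `analysis/01_generate_fixtures.py` encode
the stated far-red-versus-white-light contrast: white-light-like bilins
with ring D 30–40° and ring A 20–50° off plane, far-red α-sites much more
planar (ring A ≤ 15°, ring D ≤ 30°), far-red β-sites keeping the
white-light ring-D twist.  Light coordinate noise (σ = 0.01 Å) keeps the
ensembles non-degenerate without obscuring the contrast.

## Numerical choices and tolerances

* Collinearity threshold for plane triplets: cross-product norm < 1e-6 Ų.
* Zero-noise round trips are tested at 0.5° (bilin angles), 1e-3°
  (cylinder twist) and 0.1° (C2 axes); the constructions are exact, so
  these bounds are slack absorbing only floating-point error.
* Angle-recovery under noise: a 0.05 Å perturbation on atoms 1.4 Å apart
  tilts a three-atom plane by degrees.  A 200-repetition pilot at
  σ = 0.05 Å gave mean ≈ 5.4° and 95th percentile ≈ 11° error on prescribed
  ring angles; the frozen test bounds (mean over 20 seeds < 7°, single
  fixed draw < 12°) come from that pilot.
* Kabsch rmsd under iid N(0, σ²) coordinate noise approaches σ√3 (three
  coordinates per pair; the six rigid degrees of freedom are negligible at
  n = 500); tested loosely at ±20%.
* Dot products are clamped to [−1, 1] before arccos everywhere; a rotation
  angle of 180°+ε from floating point is clamped to 180°.

## Known limitations

* Deposited-model regression values (cylinder twist, α-site pigment count,
  white-light planarity ranges, mesoscale marker distances, antenna-vs-
  photosystem C2 angle) need the multi-megabyte wwPDB files plus a small
  per-entry chain-role table; the corresponding test runs the genuine
  pipeline only when those files are present under `data/deposited/`.
* Template fitting is rigid, chain-anchored superposition — a reproducible
  proxy for the visual/density fitting used in practice; no density is
  read, and no flexible fitting is attempted.
* No spectral prediction: the planarity → red-shift link motivates the
  statistics but absorption wavelengths are never computed from structure.
* Cylinders with other than four annotated rings, automatic ring/cylinder
  detection, and symmetry expansion of assemblies are out of scope; the
  first two fail loudly rather than guess.
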