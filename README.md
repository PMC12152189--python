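# frapc — geometry of far-red allophycocyanin structures

Cyanobacteria that grow under far-red light (far-red light photoacclimation,
FaRLiP) remodel their light-harvesting apparatus: the phycobilisome core is
replaced by a small bicylindrical far-red allophycocyanin (FR-APC) antenna
whose phycocyanobilin pigments absorb at 700+ nm.  What shifts the pigments
is not their chemistry — it is the *geometry*: how planar each open-chain
tetrapyrrole is held, how its protein pocket grips it, and how the antenna
cylinders sit against the photosystem.

`frapc` is a toolkit for exactly those measurements on cryo-EM coordinate
models (mmCIF/PDB), plus synthetic-structure generators with exact ground
truth so every stage is testable offline.  It is aimed at structural
photosynthesis researchers comparing paralogous pigment sites across
deposited models.

## What it computes

**Bilin planarity.**  A phycocyanobilin (PDB component CYC) has four pyrrole
rings A–D joined by methine bridges.  Each ring plane is defined by a fixed
atom triplet (ring A: NA, C3A, C4A, and likewise for B, C, D); the normal is
the cross product of two in-plane vectors, and the inter-plane angle is

θ = arccos(n₁·n₂),  with θ → 180° − θ whenever θ > 90°,

so every reported angle lies in [0°, 90°] and is invariant to the sign of
either normal.  Per bilin the package reports (θ_AB, θ_BC, θ_CD) and the
methine-bridge stereodescriptor (e.g. ZZZ,ssa: Z/E from the torsion about
each bridge bond C4X–CH, syn/anti from the torsion about CH–C1Y, threshold
|torsion| = 90°).

**Cylinder twist.**  An APC cylinder is four stacked (αβ)₃ rings.  Each ring
centroid is the unweighted mean of backbone atoms (N, CA, C, O), excluding
ApcC chains and ApcE2 REP-domain residues; the cylinder axis is the
total-least-squares line through the four centroids; the twist between two
cylinders is the inter-axis angle folded into [0°, 90°] (antiparallel
cylinders at a raw 150° report a 30° twist).

**C2 symmetry axes.**  Kabsch superposition of one half of a complex onto
the other; rotation angle from the rotation matrix, axis from its rotation
vector, anchored at the fixed point of the screw transform.  Rotations
below 150° are rejected as "not an approximate two-fold".

**Pocket contacts.**  Heavy-atom geometric criteria (all configurable):
H-bonds (donor/acceptor N/O pairs ≤ 3.5 Å), propionate salt bridges
(carboxylate O to Arg/Lys/His N ≤ 4.0 Å), π-stacking (ring centroids
≤ 5.5 Å and normals within 30°), steric contacts (≤ 4.0 Å).  Two pockets
are compared by set-difference over (contact type, partner residue).

**Composite assembly.**  Components are placed onto a template supercomplex
by pooled-CA Kabsch superposition over a user-supplied chain pairing; on the
composite the package counts pigments per subunit group and measures
edge-to-edge distances (minimum heavy-atom separation of the conjugated
systems; chlorophyll phytyl tails excluded by default).

## Worked example

```sh
python analysis/01_generate_fixtures.py --seed 1
python analysis/02_bilin_planarity.py
python analysis/03_cylinder_twist.py
python analysis/05_composite_assembly.py --seed 1
```

prints (abridged):

```
mean angles (deg) and recovery error per ensemble:
          theta_AB  theta_CD  err_AB  err_CD
fr_alpha      7.69     17.29    0.93    0.78
fr_beta      20.84     35.63    0.98    0.72
wl_apc       32.52     34.99    1.06    0.89

twist between cylinders: 29.9984 deg (ground truth 30.0, error 1.60e-03)
C2 rotation: 179.997 deg about [-0.0001, -0.0, 1.0]

pigment inventory: {'alpha-site': 24, 'beta-site': 24}; 2 far-red chlorophylls
marker Chl 507: prescribed 31.0 A from ApcD2 bilin A/201, recovered 31.0000 A edge-to-edge
marker Chl 508: prescribed 36.0 A from ApcD3 bilin 6/201, recovered 36.0000 A edge-to-edge
```

Reading it: the far-red α-site ensemble is generated (and measured) as far
more planar than the white-light-like ensemble — the geometric signature of
the red shift; the twist and C2 measurements recover the bicylinder's
constructed 30° / 180° to millidegrees despite 0.05 Å coordinate noise and
decoy chains that must be excluded; and the composite pipeline reproduces
the prescribed pigment marker distances exactly after refitting randomly
displaced components.

`analysis/04_pocket_contacts.py` likewise contrasts two synthetic pockets
around the same chromophore and lists the contacts unique to each.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates all synthetic fixtures from the seed, runs every analysis stage
(planarity round trip, bicylinder twist + pigment inventory + C2 axis,
pocket contact detection, composite marker distances), prints the recovered
values next to the generator ground truth, and writes the results JSON.

## Layout

```
src/frapc/        library: structure_io, bilin_geometry, assembly_geometry,
                  docking_assembly, pocket_environment, synthetic_fixtures
analysis/         numbered narrative drivers writing tables under results/
scripts/          acceptance runner
tests/            pytest suite incl. acceptance criteria
docs/methods.md   models, conventions, tolerances, limitations
```
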