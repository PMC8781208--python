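# Methods

`gqwaters` analyses the structured water molecules that mediate small-molecule
binding to G-quadruplex (GQ) DNA in crystal structures. This note records the
models and procedures the package implements, the parameters that matter, and
the choices made where the design was genuinely open.

## Structure model and acceptance filter

Coordinates are read from PDB or mmCIF files through gemmi into a small
in-memory model (`Atom` / `Residue` / `Structure`); coordinates are Angstroms
throughout and no unit-conversion layer exists. Residue categories
(`nucleotide`, `water`, `ligand`, `ion`, `other`) are assigned
deterministically: waters by residue code (`HOH`, `WAT`, `DOD` by default),
ligands only by an explicit user-supplied code list — never by heuristics —
and single-atom residues with common counter-ion codes as ions. Ions are
therefore never counted as waters; deposited water counts are reproduced
as the number of water residues.

Degenerate-input policy:

* alternate locations are collapsed to the highest-occupancy conformer,
  ties broken by the alphabetically first altloc code (contact tables report
  single-conformer geometry);
* only model 1 of a multi-model file is used (the target structures are all
  X-ray);
* hydrogens are parsed only on request and ignored by the default analysis —
  at the ~2 A resolutions considered, deposited structures carry none.

A structure is *accepted* for water analysis iff its resolution is known and
at most `max_resolution` (default 2.5 A) and, when required, at least one
accepted ligand–water hydrogen bond exists. A missing resolution is an
explicit rejection reason, not a silent pass. Acceptance is monotone in the
resolution cutoff.

## Hydrogen-bond detection

A donor–acceptor pair is accepted when the heavy-atom distance is at most
`max_distance` (default 3.25 A) and an angular criterion holds. Because the
input structures carry no hydrogens, the angular rule "donor–H...acceptor
within 30 degrees of ideality" cannot be evaluated literally; three modes are
provided:

* `antecedent_proxy` (default): the angle antecedent–donor–acceptor must lie
  within `max_angle_deviation` (default 30 deg) of the donor's ideal
  hybridisation angle — 120 deg for sp2, 109.5 deg for sp3. Deterministic and
  hydrogen-free.
* `ideal_hydrogen`: a hydrogen is placed 0.98 A from the donor, anti to the
  centroid of its covalent antecedents, and the D–H...A deviation from
  linearity must be within the tolerance. This is a geometric idealisation,
  not a protonation model.
* `distance_only`: the cutoff alone.

Water oxygens are free rotors with no antecedent and are exempt from every
angle test; without this exemption no water bond would ever be acceptable.
Donors whose antecedent atoms are not located in the file are likewise
treated as angle-exempt rather than silently dropped.

Built-in role chemistry covers the DNA bases (guanine N1/N2 donors and
O6/N3/N7 acceptors, the thymine, adenine and cytosine edges) and the
backbone oxygens (OP1/OP2, O4', O5', O3'). Ligand atoms acquire roles only
through explicit configuration — e.g. declaring a protonated morpholino or
piperazine nitrogen an sp3 donor — because ligand protonation is an input
assumption, not something inferred from geometry.

Two criteria presets are exposed. The default applies the 3.25 A / 30 deg
rule. The `table2` preset (3.45 A, distance-only) exists because published
contact tables for these complexes list interactions out to 3.4 A; exposing
both avoids silently reconciling the discrepancy in either direction.

Neighbor search uses a k-d tree but is contractually identical to an
all-pairs scan; tests enforce equality against an independently written
brute-force filter. Pairs within one residue are excluded; covalently
bonded atoms in *adjacent* residues (e.g. O3'–P across a phosphodiester
link) are not specially excluded, which can label backbone contacts as
DNA–DNA "bonds" in real files — a known limitation that does not affect the
ligand- and water-centric statistics.

Distances are reported to one decimal and B factors as integers in emitted
tables, matching crystallographic reporting convention; full precision is
retained internally.

## Contact network analysis

Accepted bonds form an undirected graph over polar-atom labels. On it:

* **Bridges**: simple paths ligand -> water^k -> DNA with 1 <= k <=
  `max_waters` (default 4 — the longest mediating chain reported for these
  complexes is four waters). Waters are distinct within a path; enumeration
  is tested against exhaustive simple-path search.
* **Shells**: first-shell waters touch a non-water node; second-shell waters
  touch only first-shell waters; the rest are bulk-like. The labels
  partition the water nodes.
* **Clusters**: connected components of the water–water subgraph, each with
  its non-water anchors; isolated waters are singleton clusters, so cluster
  sizes always sum to the water count.
* **Mediation summary**: the count of direct ligand–DNA hydrogen bonds
  versus distinct ligand atoms adjacent to at least one water. Mediated
  contacts are counted per ligand *atom*, not per hydrogen bond, which is
  the convention that reproduces the published direct-versus-mediated
  tallies; full bridge reachability is reported alongside because a
  printed table may omit a water's DNA partner.

Ligand chromophore carbonyl oxygens count as ligand atoms, so water bridges
to them are ligand-mediating contacts. Groove labels are annotations carried
from input tables or configuration; the package does not compute groove
geometry (groove assignment in the source structures was done by
inspection, and no algorithm is defined for it).

## Mobility

B factors convert to root-mean-square displacements via
`<U> = sqrt(B / (8 pi^2))`. Group summaries report the `<U>` of the group's
*mean B* (not the mean of per-atom `<U>`), which is the convention used when
a group of atoms is quoted as "mean B of 51 A^2, corresponding to <U> of
0.8 A"; the per-atom mean is reported alongside. Means are printed to the
nearest integer (B) and one decimal (U).

## Superposition and conserved waters

Two structures are superposed on their quartet guanines by a least-squares
rigid fit (Kabsch, SVD with reflection correction). The fitted atom set is
the guanine base heavy atoms (N1, C2, N2, N3, C4, C5, C6, O6, N7, C8, N9);
backbone atoms are excluded because sugar-phosphate conformations differ
between native and ligand-bound forms. The guanine pairing is explicit
configuration (a TSV of residue pairs) — for the packaged human-telomeric
pair the mapping is the identity on residues 2–4, 8–10, 14–16, 20–22 of
chain A, covering all three quartets. Fits with fewer than three pairs or a
collinear atom set raise a degenerate-fit error.

Waters are then matched across the transformed structures by greedy
mutual-nearest-neighbour pairing under a threshold (default 1.0 A, the
conventional criterion for calling two crystallographic waters "the same"
given their own positional uncertainty of ~0.6 A at these B values). Each
water joins at most one pair. A minimum-total-distance Hungarian assignment
is available as an option; on well-separated water sets the two agree.

## Synthetic scenes

The generator emulates exactly the geometric features the analysis consumes:

* quartets as four planar pseudo-guanines (regular fused-ring geometry,
  bond length 1.39 A, real guanine atom names so the production role table
  applies unmodified) around a 4-fold axis, stacked 3.4 A apart, with
  perimeter phosphate-oxygen anchors;
* a planar pseudo-ligand stacked 3.4 A above the top quartet with four
  side-chain nitrogens (sp3 donors with covalent antecedent carbons) and two
  carbonyl oxygens;
* planted bridges: each is a circular-arc chain of k waters from a ligand
  nitrogen to a phosphate OP2 with all consecutive contacts at
  `hbond_length` (default 2.8 A, the canonical O...O hydrogen-bond length);
  the arc solves for the unique circle on which k+1 equal chords of that
  length span the endpoints, bulging away from the structure;
* antecedent carbons of bridge-head nitrogens are oriented so the planted
  donor angle is exactly the sp3 ideal, making planted bonds pass every
  angle mode by construction;
* decoy waters rejection-sampled at least `cutoff + 0.5 A` from every polar
  atom and from each other, so they can form no bond and remain bulk-like
  singletons;
* coordinate jitter as a norm-truncated Gaussian (capped at 1.4 sigma), so
  that at the largest supported jitter (0.15 A in the recovery tests) a
  planted 2.8 A contact can never drift past the 3.25 A cutoff — planted
  truth remains exactly recoverable by design, which is what makes 100%
  recovery a correctness check rather than a statistical accident;
* per-category Gaussian B factors (DNA 25±5, ligand 50±8, water 30±6 A^2,
  floored at 2), reflecting the typical ordering ligand side chains > waters
  > DNA core in these complexes;
* a "native" copy: a rigid transform of the DNA plus a chosen fraction of
  the waters (re-jittered), fresh decoys and no ligand, with the conserved
  pair list and true post-fit displacements recorded as ground truth.
  Native-copy decoys are kept clear of the images of *all* original waters
  so they cannot fake a conserved pair.

A single seeded generator stream drives every stochastic choice in a scene,
so scenes are reproducible and two seeds share topology (truth) while
differing in noise. Placement failures after bounded retries raise a
generation error naming the constraint.

What the scenes deliberately do **not** emulate: helical twist, the central
ion channel, loop conformations, sequence realism, crystallographic symmetry
or solvent beyond the planted and decoy waters. Passing recovery tests
therefore demonstrates the correctness of detection, graph analysis and
matching on contact geometry — not performance on the full heterogeneity of
real crystal structures.

## Packaged fixtures

The published hydrogen-bond tables of the MM41–quadruplex complex (PDB
3UYH; 17 contacts across grooves 1–4) and the BRACO19–quadruplex complex
(PDB 3CE5; 14 contacts) are shipped as edge lists with distances and B
factors, so the network, counting and mobility stages reproduce the printed
analyses with no download: two direct nitrogen–phosphate bonds (2.9 and
3.1 A) and a groove-1 cluster of four waters for MM41; exactly one direct
drug–DNA bond and five water-adjacent ligand atoms for BRACO19; a mean
terminal-ring-nitrogen B of 51 A^2 (<U> = 0.8 A). Analyses against the
actual deposited coordinate files are supported through the same interfaces
(including the packaged 1KF1/3UYH quartet correspondence) but require the
user to supply the files.

## Problem sizes

Test and acceptance runs use scenes of 2–3 quartets (128–208 atoms), 1–4
planted bridges of 1–4 waters, and 50-seed recovery sweeps; these sizes
exercise every code path while keeping the whole suite in the seconds
range. All quantities the documentation quotes are recomputed by the test
suite or by `scripts/acceptance.py` at run time.
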