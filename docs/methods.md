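# Methods

`dnadock` models protein–DNA complexes by rigid-body docking: exhaustive
FFT-accelerated shape-complementarity search over orientations and
translations, followed by rescoring with a physics-motivated energy function
whose parameter set covers nucleotides, optional experimental restraints,
and redundancy removal by clustering.  This note records the model, the
parameters that matter, the numerical choices, and what the synthetic test
fixtures do and do not demonstrate.

## Structures and force-field annotation

Structures are heavy-atom only.  Crystallographic PDB inputs rarely carry
hydrogens, so a united heavy-atom convention is used: each hydrogen's AMBER94
partial charge is summed into its bonded heavy atom.  This preserves every
residue's template net charge exactly (0 for neutral residues, ±1 for
charged ones, −1 per internal nucleotide), which is what the electrostatics
term is sensitive to at docking resolution.  Hydrogens present in an input
file are dropped on reading.

Every heavy atom receives:

* **partial charge** *q* (e) — AMBER94 (Cornell et al.) residue templates for
  the 20 amino acids and DA/DC/DG/DT, transcribed into
  `src/dnadock/data/{amino94,nuc94}.dat`;
* **vdW parameters** r\*, ε — AMBER94 6-12 values per atom type
  (`atomtypes.dat`); the pair minimum is at R<sub>ij</sub> = r\*<sub>i</sub> + r\*<sub>j</sub>
  with depth ε<sub>ij</sub> = √(ε<sub>i</sub>ε<sub>j</sub>);
* **atom type** — the AMBER94 type, which doubles as the key for solvation
  lookup;
* **ASP** (atomic solvation parameter, kcal·mol⁻¹·Å⁻²) — the coefficient
  multiplying *buried* accessible area in the desolvation term.  The shipped
  set is an Eisenberg/McLachlan-style transfer set re-signed for this
  package's convention (negative = burial favourable: aliphatic/aromatic C
  −0.016, amide/ring N and carbonyl O +0.006, charged N +0.050, charged O
  +0.024, S −0.021).  Nucleotide-only atom types (N\*, NC, CK, CQ, CM, OS, P)
  are mapped to the chemically nearest protein type in `nucmap.dat` — e.g.
  N\*→N, OS→OH, P→S — because no published nucleotide-specific ASP set is
  adopted here.  All four tables are plain text and swappable without code
  changes; solvation parameters for nucleic acids are an open research
  question and the default set makes no claim of being optimal.

Atoms without a template entry (terminal OXT, unusual names, residues outside
the 24 templates) get zero charge, element-default vdW radii, ASP 0, and are
logged — never fatal.  Terminal residues use the internal-residue template;
5′-terminal nucleotides simply lack the phosphate atoms.

## Canonical B-DNA builder

Unbound DNA is modelled as a straight-fiber B-form duplex: base pair *i* is a
template rotated by (i−1)·twist about the z axis and translated (i−1)·rise
along it, with defaults **twist 36.0°/bp** and **rise 3.38 Å/bp** (the
canonical B-form fiber values; one full turn per 10 bp).  Strand 2 is
generated by the pair dyad (180° about the frame x axis) applied to the
complementary base template, giving an antiparallel strand whose 5′→3′
sequence is the reverse complement of the input.

The per-nucleotide templates (`bdna_template.dat`) are idealized: base
geometry from chemical-component ideal coordinates, placed with C1′–C1′
10.4 Å, glycosidic angle λ = 54.5°, C1′ radius 5.9 Å; one common
sugar-phosphate moiety (anti glycosidic conformation, chosen for maximal
steric clearance in assembled duplexes; phosphate radius 8.4 Å) is grafted
onto all four bases, as in fiber models.  Consequences to keep in mind:
Watson–Crick N1···N3 distances come out at 2.6 Å (canonical ≈ 2.8–2.9 Å) and
O3′(i)–P(i+1) backbone connectivity between steps is approximate.  For rigid
docking — where the duplex contributes shape, charge and solvation surface,
not covalent geometry — this is immaterial, and the template file can be
replaced wholesale with exact fiber-diffraction coordinates (e.g. 3DNA fiber
output) if desired.  No sugar-pucker, groove-width or sequence-dependent
refinements: strictly straight, strictly canonical.

## FFT sampling

The molecule with the longer maximal atom-pair distance is the fixed
**receptor**; the other is the mobile **ligand** (tie → first argument).
Both are discretised on a cubic grid, default **cell 0.7 Å**: a cell is
occupied when its center lies within an atom's vdW radius.  Receptor cells
are **surface** (+1) if within the **surface thickness (1.3 Å)** of an empty
cell, otherwise **core** (−15, the steric penalty); ligand cells are all +1.
The grid score of a translation is Σ receptor·ligand over cells — surface
overlap rewarded, core penetration penalised — evaluated for *all*
translations at once as a circular cross-correlation via forward/inverse
FFT, rounded to the nearest integer (the grids are integer-valued, so
rounding removes FFT float noise exactly; equivalence with direct-space
summation is asserted in the tests).

Orientations come from a z–y–z Euler lattice at the default **12° step**
(φ, ψ over [0, 360), θ over [0, 180]) with duplicate orientations removed by
matrix comparison — 12,660 unique rotations at 12°.  For each rotation the
ligand is rotated about its centroid, re-discretised, correlated, and the
best **3 translations per rotation** are kept; the pooled candidates are
ranked by grid score (ties: rotation index, then translation lexicographic)
and the top **10,000** become docking poses.  A pose is stored as intrinsic
z-y-z Euler angles plus the ligand-centroid translation, so transform tables
regenerate model coordinates exactly.

Grid dimensions are the smallest 2/3/5-smooth integer covering the two
molecular spans plus twice (margin 1.0 Å + largest vdW radius + surface
thickness), which both maximises FFT efficiency and guarantees the circular
correlation has no wrap-around contamination: the radius/surface inflation is
included because the occupied extent of a molecule exceeds its atom-center
span by exactly that much.

## Scoring

Each pose is rescored in continuous space:

    total = w_ele·E_ele + w_desolv·E_desolv + w_vdw·E_vdw + E_restraint

* **Electrostatics** — Coulomb with distance-dependent dielectric ε(r) = 4r:
  E = Σ 332.0·q_iq_j / (4r²) kcal/mol over inter-molecular pairs, each pair
  clamped to ±1.0 kcal/mol.  The clamp caps the error made by scoring
  unrefined rigid-body contacts.
* **van der Waals** — AMBER 6-12 with Lorentz–Berthelot combination, each
  pair clamped at +1.0 kcal/mol (no lower clamp).
* **Desolvation** — Σ ASP_i·ΔSASA_i over the atoms of both molecules, where
  ΔSASA_i ≥ 0 is the accessible area buried on complexation.  SASA is
  Shrake–Rupley with a deterministic generalized-spiral point set
  (default 960 points/atom), probe 1.4 Å, radii = vdW r\*.  Only atoms whose
  neighbour set changes on complexation are recomputed — identical to a full
  recomputation, just cheaper, and free-molecule areas are pose-invariant and
  cached.

Named weighting schemes: `default` (1, 1, 0.1), `no_desolv` (1, 0, 0.1),
`vdw1` (vdW weight raised to 1.0) and `ele_only` (1, 0, 0).  When a term's
weight is zero it is not evaluated (its column reads 0).  Pair distances are
floored at 1.0 Å and cut off at 12 Å by default (beyond which the clamped
forms are negligible); `--no-cutoff` exists for oracle comparisons.  Poses
are ranked ascending by total (lower = better), ties by pose id.

Numerical note: electrostatics and vdW are exactly invariant under joint
rigid motion of the system, but the desolvation term is invariant only up to
the SASA quadrature resolution (~1% per atom at 960 points), because the
spiral point set is fixed in the lab frame.  Raising `n_points` tightens
this at linear cost.

## Restraints

A restraint names one protein residue and one nucleotide and is satisfied
when their minimum heavy-atom distance is ≤ cutoff (default 6.5 Å,
inclusive).  Each satisfied restraint adds −weight (default 1.0 kcal/mol) to
the total — a transparent linear reward; per-restraint cutoffs and weights
let users emulate other normalisations.  Restraints never alter the physical
terms, only the restraint column and the total.

## Multi-run merging and GROMOS clustering

Grid discretisation makes FFT docking mildly orientation-dependent, so
benchmark-style execution repeats the run (default 10×) from different
random initial rotations of the inputs (one master seed expands to per-run
seeds; each run's rotation is recorded).  Every run's **top 100** poses are
merged into one pool, mapped to a common receptor frame by inverting the
initial rotations.  Pairwise ligand RMSD (all ligand heavy atoms, receptors
already superposed) feeds GROMOS clustering at **4.0 Å**: repeatedly extract
the pose with the most neighbours within the cutoff (inclusive; ties → lower
score, then lower index) together with those neighbours; the lowest-scoring
member represents each cluster.  Representatives ranked by total score are
the final models.  The tie-break convention is this package's own choice
(needed for determinism); it does not affect pools without exact ties.

## Evaluation

Model quality vs a reference complex is **L-RMSD**: superpose the model
receptor onto the reference receptor (Kabsch least-squares over shared heavy
atoms, matched by chain/residue/atom name), apply that transform to the model
ligand, report the ligand RMSD.  **Near-native** means L-RMSD ≤ 10 Å; the
**top-N success rate** of a case set is the percentage of cases with a
near-native model at rank ≤ N.  Flexibility classes from unbound↔bound RMSD:
protein low < 1 Å ≤ medium < 3 Å ≤ high; DNA low < 3 Å ≤ medium < 5 Å ≤ high.
L-RMSD uses all shared ligand heavy atoms by default; `backbone_only`
restricts to CA (protein) and P/C1′ (DNA) for reduced-atom comparisons.

## Synthetic fixtures: what they show and what they do not

All tests run on generated inputs: ideal poly-alanine α-helices (5 heavy
atoms/residue; 1.5 Å rise, 100°/residue), canonical B-DNA duplexes, planted
complexes and Gaussian pose clouds.  Problem sizes are kept small on
purpose — the standing end-to-end check is a 4-residue helix docked to a
5-bp duplex, which exercises the full default protocol (0.7 Å cell, 12°
sweep, 3 kept/rotation, 10,000 poses) in a few minutes on one core.

Two fixture subtleties worth knowing:

* `planted_complex` places the ligand at a controlled minimum
  inter-molecular distance (default 3.0 Å, vdW touching).  For rod-shaped toy
  molecules such a contact is *not* in general the global
  shape-complementarity optimum (slid or deeper placements can score
  higher), so pose-recovery tests instead use `planted_optimal_complex`,
  which plants the ligand at the identity-rotation correlation optimum.
  Recovery then verifies the sampler's grid↔Å transform bookkeeping; the
  correlation itself is validated independently against exhaustive
  direct-space summation.
* Passing on these fixtures demonstrates correctness of the machinery —
  exact FFT/brute-force agreement, oracle-identical energies and clustering,
  deterministic end-to-end runs — not predictive performance on real
  protein–DNA complexes, which depends on conformational flexibility of the
  partners and on solvation parameters that remain unoptimised for
  nucleotides.

## Defaults at a glance

| parameter | default | where |
|---|---|---|
| grid cell | 0.7 Å | sampling |
| surface thickness | 1.3 Å | sampling |
| core penalty | −15 | sampling |
| rotation step | 12° | sampling |
| kept per rotation / total | 3 / 10,000 | sampling |
| Coulomb constant / dielectric | 332.0 / ε = 4r | scoring |
| per-pair clamps (ele, vdW) | ±1.0 / +1.0 kcal/mol | scoring |
| pair cutoff / distance floor | 12 Å / 1.0 Å | scoring |
| SASA points / probe | 960 / 1.4 Å | scoring |
| vdW weight (default scheme) | 0.1 | scoring |
| restraint cutoff / weight | 6.5 Å / 1.0 | restraints |
| runs merged / top per run | 10 / 100 | clustering |
| cluster cutoff | 4.0 Å L-RMSD | clustering |
| near-native threshold | 10 Å L-RMSD | evaluation |
| B-DNA twist / rise | 36.0° / 3.38 Å per bp | builder |

## Known limitations

* Rigid-body only: no side-chain rebuilding, minimisation or flexible
  refinement; highly flexible partners will not be modelled well.
* The ASP set is not nucleotide-optimised; the `no_desolv` scheme exists
  precisely because desolvation can hurt protein–DNA ranking.
* The B-DNA templates are idealized (see above); A-/Z-form, bent DNA,
  single strands, mismatches and modified bases are out of scope.
* No hetero ligands, ions, or mmCIF input; protonation states are not
  predicted.
* Euler-lattice rotation sampling is denser near the poles of θ than a
  spherically uniform sweep at the same nominal step.
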