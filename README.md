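# dnadock

Energy-based rigid-body **protein–DNA docking**: given a protein structure
and a DNA structure (or just a DNA sequence, modelled as canonical B-DNA),
`dnadock` generates candidate complexes by FFT shape-complementarity search
and re-ranks them with an electrostatics + desolvation + van der Waals
scoring function parameterised for nucleotides.  It is aimed at structural
bioinformaticians modelling transcription-factor/DNA and enzyme/DNA
complexes when no experimental complex structure exists, and at docking
methods developers who need a reproducible, fully scriptable protein–DNA
pipeline with benchmark-style evaluation built in.

## Method

1. **Sampling.** The molecule with the longer maximal atom-pair distance is
   held fixed (receptor).  Both molecules are discretised on a 0.7 Å cubic
   grid — receptor cells marked surface (+1) or core (−15), ligand cells +1 —
   and for every ligand orientation on a deduplicated 12° z-y-z Euler sweep
   the overlap score of *all* translations is computed at once by FFT
   cross-correlation.  The best 3 translations per rotation are pooled and
   the top 10,000 by grid score become docking poses.
2. **Scoring.** Each pose is rescored in continuous space:

   `total = w_ele·E_ele + w_desolv·E_desolv + w_vdw·E_vdw + E_restraint`

   with Coulomb electrostatics under a distance-dependent dielectric
   (ε = 4r, per-pair clamp ±1 kcal/mol), AMBER 6-12 van der Waals (clamp
   +1 kcal/mol), and desolvation as Σ ASPᵢ·ΔSASAᵢ over buried accessible
   area (Shrake–Rupley).  Default weights (1, 1, 0.1); published variants
   `no_desolv`, `vdw1` and `ele_only` are selectable, and residue–nucleotide
   distance restraints add −weight per satisfied restraint.
3. **Clustering.** Multiple runs from random initial rotations are merged
   (top 100 each) and redundancy is removed by GROMOS clustering on pairwise
   ligand-RMSD at 4.0 Å; the lowest-energy member represents each cluster.
4. **Evaluation.** Models are compared to a reference complex by L-RMSD
   (receptor superposed, ligand RMSD); a model within 10 Å is near-native,
   and top-N success rates summarise case sets.

Charges and vdW parameters are AMBER94-derived; nucleotide atom types are
mapped onto protein atom types for solvation lookup through a plain-text,
user-editable table.  See `docs/methods.md` for the full model description,
defaults and limitations.

## Worked example

Dock an 8-residue helical peptide against a 10-bp B-DNA duplex built from
sequence, using a coarse 45° sweep so it runs in seconds:

```bash
dnadock build-dna --seq ACGTACGTAC --out dna.pdb
dnadock fixture --kind toy_protein --size 8 --out protein.pdb
dnadock sample --receptor dna.pdb --ligand protein.pdb \
               --rot-step 45 --keep 500 --out poses.tsv
dnadock score --receptor dna.pdb --ligand protein.pdb \
              --poses poses.tsv --scheme no_desolv --out scored.tsv
```

which prints

```
wrote 404-atom duplex (10 bp) to dna.pdb
wrote toy_protein fixture to protein.pdb
wrote 500 poses to poses.tsv
scored 500 poses (no_desolv) -> scored.tsv
```

`poses.tsv` holds one row per pose — Euler angles (degrees), ligand-centroid
translation (Å) and integer grid score — enough to regenerate every model
exactly.  `scored.tsv` adds the energy breakdown and rank; its best row here
is

```
1 343 -7.107815 0.000000 -9.264765 0.000000 -8.034292 1
```

i.e. pose 343 ranks first with total −8.03 kcal/mol = electrostatics −7.11
plus 0.1 × van der Waals −9.26 (desolvation column is 0 under the
`no_desolv` scheme; the restraint column is 0 because none were supplied).
Negative totals are favourable; for this polyanionic receptor the
electrostatic term dominates, as expected for protein–DNA interfaces.

The full protocol (sampling at 12°, 10,000 poses, scoring, and for
`--n-runs 10` the merge + 4.0 Å clustering step) runs as:

```bash
dnadock run --protein protein.pdb --dna dna.pdb --n-runs 10 --seed 1 \
            --outdir out/
```

writing `out/run_<k>/poses.tsv`, `out/run_<k>/scored.tsv`,
`out/merged/clusters.tsv` and the top-ranked models as
`out/merged/top100/model_<rank>.pdb`.  Library use mirrors the CLI
(`dnadock.sample`, `dnadock.score_poses`, `dnadock.gromos_cluster`,
`dnadock.lrmsd_vs_reference`, ...).

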