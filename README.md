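# nodkey

Lock-and-key analysis of Nod factor recognition by the pea LykX–Sym10
receptor heterodimer.

## The problem

Rhizobia initiate symbiosis with legumes by secreting Nod factors (NFs) —
lipochitooligosaccharides of 3–5 β-(1,4)-linked N-acetylglucosamines carrying
a fatty-acyl tail and small decorations such as an O-acetyl group.  Pea
(*Pisum sativum*) accessions differ sharply in which NFs they accept:
European genotypes nodulate with strains producing acetylated and
non-acetylated NFs, while the Afghanistan phenotype (Afghan and Tajik
*LykX* alleles) demands acetylation.  The candidate receptor is a heterodimer
of two LysM receptor-like kinases, LykX (the *Sym2* candidate) and Sym10.

`nodkey` implements, as a tested pipeline, the decision logic that connects
allele sequence variation to NF specificity:

1. **Allele polymorphism analysis** (`nodkey.alignment`) — polymorphic
   columns of a grouped amino-acid alignment, the subset segregating
   *between* allele groups, mean pairwise differences, and each group's
   modal sequence.
2. **Docking-pose clustering** (`nodkey.posecluster`) — heterodimer poses
   are superposed on the LykX subunit by Procrustes analysis (proper
   rotation + shift, no scaling); two poses are similar when the angle at
   the LykX centroid between their Sym10 centroids is < 45° *and* the
   minimal per-axis Pearson correlation of Sym10 coordinates is > 0.5;
   groups of ≥ 4 pairwise-similar poses (maximal cliques) are merged until
   disjoint, and a random representative is drawn per cluster.
3. **Geometric recognition** (`nodkey.recognition`) — an NF is recognized
   when its fatty-acyl tail occupies the hydrophobic pocket at the
   subunit interface (Val37–Leu43, Tyr119, Ala121 of LykX; Val217, Phe218 of
   Sym10): ≥ 3 tail heavy atoms within 4.5 Å of pocket heavy atoms.
   Hydrogen bonds (N/O pairs ≤ 3.5 Å, D–H···A ≥ 120° when hydrogens exist)
   and contact residues are reported as diagnostics.
4. **Thermochemical feasibility** (`nodkey.thermo`) — per-complex ΔG per NF
   state (stable / active, gas and solvated) is the lowest conformer energy;
   ΔΔG is taken against the *stable solvated* reference, and
   `bonded = ΔΔG(active_solvated) + E_dock`.  Only `bonded < 0` complexes
   are feasible.
5. **Verdict composition** (`nodkey.pipeline`) — per (allele, NF type) pair,
   `final = docking ∧ MD-stability ∧ thermo`.  MD stability enters as an
   external per-complex label.

External engines (homology modelling, docking, MD, quantum chemistry) are
out of scope; their outputs enter as tables, labels, or synthetic data with
planted ground truth (`nodkey.simulate`).

## Worked example

```python
import nodkey as nk

# polymorphism analysis on a synthetic allele set shaped like the real one
aln, truth = nk.gen_alignment(nk.AlignmentSpec(seed=1))
print(len(nk.polymorphic_sites(aln)), len(nk.between_group_sites(aln)))
# 23 4        (23 polymorphic columns, 4 segregating between alleles)

# cluster a planted pose family
poses, labels = nk.gen_dimer_poses(nk.PoseFamilySpec(
    n_clusters=2, poses_per_cluster=5, n_singletons=3,
    atoms_per_subunit=10, noise_sd=0.0, seed=2))
cs, table, _ = nk.cluster_poses(poses, seed=0)
print(len(cs.clusters), len(cs.unclustered))
# 2 3          (both planted clusters recovered; singletons unclustered)

# compose the published per-stage outcomes into the final verdict table
from nodkey.studydata import load_study_labels
verdicts = nk.compose_verdicts(*load_study_labels())
print(nk.summarize(verdicts))
# {'total': 12, 'docking_passed': 8, 'md_passed': 7,
#  'thermo_passed': 6, 'final_passed': 5}
```

The final five complexes are A-NF5Ac, T-NF5Ac, T-NF4Ac, E-NF5Ac and
E-NF4NonAc: every dimer accepts the five-sugar acetylated NF, the European
dimer additionally accepts a non-acetylated NF — matching the known pea
phenotypes.

The same stages are scriptable from a shell:

```bash
nodkey simulate alignment --seed 1 --out work/aln
nodkey seqpoly --alignment work/aln/alignment.fasta \
    --groups work/aln/alignment_groups.tsv --out work/report
nodkey cluster-poses --poses work/poses --min-group 4 --seed 0 --out work/clu
nodkey pipeline --config config.yaml --out work/run
```

## Layout

- `src/nodkey/` — library modules (`simulate`, `alignment`, `posecluster`,
  `recognition`, `thermo`, `pipeline`, `io`, `studydata`, `cli`)
- `tests/` — pytest suite, including planted-truth and oracle-agreement
  acceptance checks
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and limitations
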