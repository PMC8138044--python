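# Methods

## Scope and model

`nodkey` re-implements the *decision* layer of a structural study of Nod
factor (NF) specificity in pea: which of twelve candidate ligand–receptor
combinations (three *LykX* alleles × four NF types) survive three
independent filters — geometric docking recognition, molecular-dynamics
stability, and thermochemical feasibility.  The physics engines that
produce structures, trajectories and energies are not emulated; the package
operates on their outputs (coordinate files, energy tables, pass/fail
labels) and on synthetic stand-ins with planted ground truth.

## Sequence polymorphism

An allele alignment is a set of equal-length amino-acid sequences with one
group label each.  A column is *polymorphic* when it carries ≥ 2 distinct
symbols; the gap character `-` counts as a 21st symbol (the simplest
consistent rule; polymorphism and Hamming counts use the same alphabet).
A column is a *between-group* site when the per-group consensus residues
(modal residue; ties resolved alphabetically, never an error) are not all
identical — within-group minority variation therefore never creates a
between-group site.  Columns are numbered 1-based so results read directly
against residue labels such as #44.  The numbering frame is that of the
provided alignment; mapping to a precursor or mature-peptide frame is the
caller's responsibility.  Mean pairwise difference is the average Hamming
distance over all unordered pairs.  Modal sequences are whole-sequence
modes with first-occurrence tie-breaking, making the result independent of
how ties are ordered internally.  Upstream multiple alignment is consumed,
not computed.

## Pose clustering

Docking poses of the Sym10 ectodomain against a fixed LykX ectodomain are
reduced to distinct binding modes in four steps.

**Superposition.**  Each pose is rigidly mapped (Kabsch algorithm: SVD of
the cross-covariance of centered point sets) so its LykX atoms best fit a
chosen reference pose; the same map carries the Sym10 atoms.  The rotation
is forced proper (det = +1) by sign-correcting the smallest singular
direction — a reflection is not a rigid motion of a protein.  If the second
singular value falls below 1e-8 of the largest, the reference atoms are
(nearly) collinear and the superposition refuses with an explicit error
rather than returning an arbitrary in-plane rotation.

**Measures.**  For a pose pair: (i) the angle at the LykX centroid between
the vectors to the two Sym10 centroids, in degrees; (ii) the minimum over
X/Y/Z of the Pearson correlation between corresponding Sym10 atom
coordinates.  Centroids and correlations use all supplied subunit atoms;
callers choosing a Cα-only representation get Cα-based measures.  The angle
is frame-free; the per-axis correlations are defined in the frame of the
reference pose, so they change if the entire input is pre-rotated.  The
similarity *verdicts* are nevertheless stable on well-separated families,
and the test suite asserts exactly that invariance.  A zero-variance axis
has no Pearson correlation; it contributes 1 if both poses are constant and
equal on that axis, else 0, with a warning — this keeps degenerate toy
inputs classifiable without dividing by zero.

**Similarity.**  Two poses are similar iff angle < 45° and minimal
correlation > 0.5, read as strict inequalities.  The 45 threshold is taken
as degrees (45 radians would be meaningless).

**Clustering.**  Groups are maximal cliques of the similarity graph
(pairwise similarity required) with ≥ 4 members, enumerated with networkx;
cliques sharing any pose are merged transitively until the clusters are
disjoint.  Remaining poses stay unclustered.  One representative per
cluster is drawn uniformly with a caller-supplied seed; members are sorted
before drawing so the choice depends only on the seed, not on set-iteration
order.  The implementation is checked against a brute-force oracle
(exhaustive subset enumeration plus fixed-point merging) on a thousand
random instances of ≤ 12 poses.

## Geometric recognition

Recognition asks whether the NF fatty-acyl tail sits in the hydrophobic
pocket at the LykX–Sym10 interface.  Ligand atoms carry explicit part
labels (core / tail / acetyl) from an annotation table — NFs are
non-standard heteromolecules, and guessing chemistry from a PDB file is
deliberately avoided.  The default pocket is the published interface set
(Val37, Met38, Pro39, Ala40, Phe41, Leu42, Leu43, Tyr119, Ala121 of LykX;
Val217, Phe218 of Sym10).  Defaults, all configurable:

| parameter | default | rationale |
|---|---|---|
| tail contact cutoff | 4.5 Å heavy–heavy | upper van-der-Waals contact range |
| min tail contacts | 3 | several tail atoms, not a grazing touch |
| H-bond distance | ≤ 3.5 Å (N/O pairs) | common geometric definition |
| H-bond angle | D–H···A ≥ 120°, only with explicit H | same |
| min H-bonds | 0 | pocket occupancy alone decides |

The source study states the pocket criterion qualitatively; the numeric
thresholds here are this package's declared operationalization, not values
inferred from it.  Hydrogen-bond counts are diagnostics by default
(`min_hbonds=0`) because one complex was accepted at the docking stage with
only three bonds; callers can make the bond count a gate.  Contact residues
are reported with per-residue heavy-atom contact counts at a 4.0 Å cutoff.
All outputs are invariant under global rigid motion of the complex, and the
contact/H-bond counts are monotone in their cutoffs (both tested).

## Thermochemical ledger

Four NF states are tracked per complex: `stable` and `active` (gas phase)
plus their solvated counterparts.  ΔG per state is the *lowest* conformer
energy (no Boltzmann averaging — the single-minimum reading; averaging
would be a straightforward extension).  ΔΔG is referenced to
`stable_solvated`, so ΔΔG(reference) ≡ 0, and
`bonded = ΔΔG(active_solvated) + E_dock` with the docking energy taken as
an opaque supplied number in kcal/mol.  Feasible ⇔ bonded < 0; bonded = 0
is classified infeasible (only strictly negative values indicate a
potentially active molecule — the conservative boundary).  ΔΔG and bonded
are invariant to any per-complex constant shift of state energies and to
adding dominated conformers; both invariances are tested exhaustively on
small cases.  Conformer selection (`select_conformers`) returns the k
lowest energies ascending with ties broken toward the lower conformer id,
mirroring the 100-of-search and 15-into-docking thinning steps.

## Verdict composition

The final table holds one row per (allele, NF type).  MD stability and —
when not recomputed from an energy table — thermochemistry enter as labels
covering exactly the docking-passed pairs; missing coverage is an error
listing the gaps, and docking-failed rows carry null MD/thermo fields.
`final = docking ∧ md ∧ thermo`.  The packaged fixture
(`nodkey/data/reported_outcomes.tsv`) encodes the published stage outcomes:
acetylated NFs dock into all three dimers, NF5NonAc only into Tajik,
NF4NonAc only into European (8 of 12); thermochemistry rejects E-NF4Ac and
A-NF4Ac (6 remain); MD rejects T-NF5NonAc (5 final — European 2, Tajik 2,
Afghan 1).

## Synthetic data

Each generator plants the truth it returns and is byte-deterministic given
its integer seed; independent named sub-streams (via `SeedSequence`) keep
positions, residues and noise separately reproducible.

**Alignments.**  Defaults emulate the real allele panel: groups of 5/2/85
sequences (Afghan/Tajik/European), 212 columns, 4 between-group + 19
within-group planted sites (23 polymorphic columns).  Between-group sites
get one distinct consensus residue per group with no within-group noise;
within-group sites mutate a strict minority (< half) of one group with ≥ 3
members, so no group consensus can flip and planted classes are recovered
exactly.  What this does *not* emulate: indel patterns, phylogenetic
correlation between sites, and within-noise *at* between-group sites — so
exact-recovery results bound the clean-signal case only.

**Pose families.**  A shared LykX cloud and Sym10 cloud (Gaussian, ~6 Å
scale) are placed at 18–22 Å in directions drawn by sequential rejection
sampling with pairwise separation > 55° (the 45° similarity threshold plus
a 10° margin, guaranteeing separability); cluster members add isotropic
per-atom Gaussian noise (default 0.3 Å), and every pose is scrambled by its
own random rigid motion that superposition must undo.  Defaults (3 clusters
× 6 poses + 12 singletons = 30 poses, 60 atoms per subunit) mirror one
allele's docking run at Cα-like resolution.  Real docking decoys are not
i.i.d. Gaussian clouds; recovery rates here demonstrate correctness of the
clustering logic, not expected performance on real decoy distributions.

**Toy complexes.**  Pocket residues form a ring (default radius 3.5 Å) in
the xy-plane around the origin with backbone N/C/O placed outward; the
carbon tail runs along the ring axis at 1.5 Å spacing, so with the default
4.5 Å cutoff at least three tail atoms are guaranteed in contact (the spec
ring radius is capped at 3.8 Å to preserve that guarantee, since the
third-nearest tail atom sits up to 2.25 Å off-plane).  Hydrogen-bond pairs
are planted as ligand oxygens 2.9 Å inward of anchor-residue nitrogens on a
wider elevated ring, with all other polar–polar distances kept > 3.5 Å by
construction, so the planted count is exact.  Geometry, not chemistry: bond
lengths and sterics are not realistic beyond what the measures read.

**Energy tables.**  State energies are drawn with realistic orderings
(solvation lowers, strain raises) and the docking energy is back-solved so
the bonded energy hits a drawn magnitude (0.5–9.5 kcal/mol) with the
planted sign — the feasible fraction is exact by construction, defaulting
to 6 of 8 complexes.

## Numerical conventions

- Coordinates in Å, energies in kcal/mol; PDB output rounds to the format's
  3-decimal precision, and generators pre-round so file round-trips are
  lossless.
- Angle computation clips cosines to [−1, 1]; self-angles are zero only to
  arccos precision (~1e-4 degrees).
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  cluster-representative draws sort members first for order independence.
- Degenerate inputs fail loudly: collinear superposition references, empty
  clusters, missing reference states, uncovered verdict pairs.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances — pose families of ≤ 30 poses with ≤ 60 atoms per subunit,
alignments of ≤ 92 × 212, oracle comparisons on ≤ 12-pose graphs (1000
trials) — chosen so the full suite completes in seconds while still
exercising every code path and exactly recovering all planted truths.

## Limitations

- The pipeline validates decision logic; it cannot validate the upstream
  physics (docking scores, MD stability calls, QM energies) it consumes.
- Per-axis correlation is frame-dependent by construction (see above);
  published threshold values implicitly assume the docking frame.
- MD stability is a supplied boolean per complex; no trajectory analysis.
- The between-group site rule tolerates minority within-group variation;
  a perfectly-segregating-only rule would be stricter and is not offered.
- Boltzmann-averaged state energies are not implemented.
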