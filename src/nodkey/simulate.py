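"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to the analysis — allele alignments, rigid-body docking poses,
ligand–dimer complexes, and quantum-chemistry energy tables — come from
external engines.  These generators emulate each input's *shape* with the
truth planted and returned, so every downstream module can be tested for
exact recovery:

* :func:`gen_alignment` — allele-grouped alignments with planted
  between-group diagnostic columns and within-group minority variants;
  defaults mirror a three-allele set (5/2/85 sequences, 212 columns,
  4 between + 19 within polymorphic sites).
* :func:`gen_dimer_poses` — pose families whose mobile (Sym10) subunits form
  planted clusters around well-separated placements (pairwise centroid
  angles > 55°), each pose scrambled by a random global rigid motion.
* :func:`gen_toy_complex` — alanine-like pseudo-residue pockets with a
  carbon tail threaded through (or displaced far from) the pocket and an
  exact planted number of hydrogen-bond pairs.
* :func:`gen_energy_table` — four-state conformer energy tables whose
  bonded-energy signs are constructed, not sampled, so the feasible fraction
  is exact.

All generators are fully deterministic given their integer seed; independent
sub-streams are derived per concern so e.g. planted site positions can be
held fixed while residue draws vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .alignment import AMINO_ACIDS, AlleleAlignment
from .posecluster import DimerPose
from .recognition import ComplexStructure, DEFAULT_POCKET_RESIDUES
from .thermo import STATES, BOUND_STATE, REFERENCE_STATE, ConformerEnergyTable

DEFAULT_GROUP_NAMES = ("Afghan", "Tajik", "European")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic sub-stream `stream` of master seed `seed`."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSpec:
    """Planted-polymorphism alignment parameters.

    Defaults emulate the deposited LykX ectodomain set: three allele groups
    of 5/2/85 sequences, 212 aligned columns, 4 group-diagnostic sites and 19
    within-group variable sites (23 polymorphic columns in total).
    `position_seed` lets the planted column positions be pinned while residue
    draws vary with `seed`; it defaults to `seed`.
    """

    n_groups: int = 3
    seqs_per_group: int | Sequence[int] = (5, 2, 85)
    length: int = 212
    n_between_sites: int = 4
    n_within_sites: int = 19
    seed: int = 0
    position_seed: int | None = None

    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.seqs_per_group, int):
            return (self.seqs_per_group,) * self.n_groups
        sizes = tuple(int(s) for s in self.seqs_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("seqs_per_group length must equal n_groups")
        return sizes

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if self.n_between_sites + self.n_within_sites > self.length:
            raise ValueError("planted site counts exceed alignment length")
        if self.n_between_sites > 0 and self.n_groups < 2:
            raise ValueError("between-group sites require >= 2 groups")
        if self.n_groups > len(AMINO_ACIDS):
            raise ValueError("more groups than residues to make them distinct")
        sizes = self.group_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("every group needs at least one sequence")
        if self.n_within_sites > 0 and max(sizes) < 3:
            raise ValueError(
                "within-group variable sites need a group of >= 3 sequences "
                "(a minority variant must not flip the group consensus)"
            )


@dataclass(frozen=True)
class PlantedAlignmentTruth:
    between_sites: tuple[int, ...]  # 1-based
    within_sites: tuple[int, ...]   # 1-based
    group_consensus: dict[str, str]


def gen_alignment(spec: AlignmentSpec) -> tuple[AlleleAlignment, PlantedAlignmentTruth]:
    """Alignment with planted between/within polymorphic columns.

    Between-group sites are fully segregating: every group gets a distinct
    consensus residue with no within-group noise.  Within-group sites give a
    strict minority of one large group a variant residue, so no group
    consensus moves.  All remaining columns are monomorphic.
    """
    rng_pos = _rng(
        spec.seed if spec.position_seed is None else spec.position_seed, 0
    )
    rng_res = _rng(spec.seed, 1)
    sizes = spec.group_sizes()
    groups = (DEFAULT_GROUP_NAMES if spec.n_groups == 3
              else tuple(f"G{i + 1}" for i in range(spec.n_groups)))

    n_planted = spec.n_between_sites + spec.n_within_sites
    planted = rng_pos.choice(spec.length, size=n_planted, replace=False)
    between = np.sort(planted[: spec.n_between_sites]) + 1
    within = np.sort(planted[spec.n_between_sites:]) + 1

    alphabet = np.array(list(AMINO_ACIDS))
    base = rng_res.choice(alphabet, size=spec.length)
    rows = {g: np.tile(base, (s, 1)).astype("<U1") for g, s in zip(groups, sizes)}

    for site in between:
        residues = rng_res.choice(alphabet, size=spec.n_groups, replace=False)
        for g, r in zip(groups, residues):
            rows[g][:, site - 1] = r

    big_groups = [g for g, s in zip(groups, sizes) if s >= 3]
    for site in within:
        g = big_groups[int(rng_res.integers(len(big_groups)))]
        block = rows[g]
        n = block.shape[0]
        n_var = int(rng_res.integers(1, max((n - 1) // 2, 1) + 1))
        who = rng_res.choice(n, size=n_var, replace=False)
        current = block[0, site - 1]
        variant = rng_res.choice([a for a in AMINO_ACIDS if a != current])
        block[who, site - 1] = variant

    ids, seqs, gmap = [], [], {}
    for g in groups:
        for k in range(rows[g].shape[0]):
            sid = f"{g}_{k:03d}"
            ids.append(sid)
            seqs.append("".join(rows[g][k]))
            gmap[sid] = g
    aln = AlleleAlignment(ids=tuple(ids), sequences=tuple(seqs), groups=gmap)
    truth = PlantedAlignmentTruth(
        between_sites=tuple(int(s) for s in between),
        within_sites=tuple(int(s) for s in within),
        group_consensus={g: "".join(rows[g][0]) for g in groups},
    )
    return aln, truth


# --------------------------------------------------------------------------
# dimer pose families
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseFamilySpec:
    """Planted-cluster pose-family parameters.

    Defaults emulate one allele's docking run: 30 poses (3 clusters of 6 plus
    12 unclustered singletons) with Cα-like subunits and sub-Ångström noise.
    """

    n_clusters: int = 3
    poses_per_cluster: int = 6
    n_singletons: int = 12
    atoms_per_subunit: int = 60
    noise_sd: float = 0.3
    seed: int = 0
    allele: str = "synthetic"

    def __post_init__(self) -> None:
        if self.atoms_per_subunit < 3:
            raise ValueError("atoms_per_subunit must be >= 3 for rigid superposition")
        if self.n_clusters < 0 or self.n_singletons < 0:
            raise ValueError("counts must be non-negative")
        if self.n_clusters > 0 and self.poses_per_cluster < 1:
            raise ValueError("poses_per_cluster must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


_MIN_SEPARATION_DEG = 55.0  # 45° similarity threshold plus a 10° margin


def _separated_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """`n` unit vectors with pairwise angles > 55°, by sequential rejection."""
    min_cos = np.cos(np.radians(_MIN_SEPARATION_DEG))
    for _restart in range(200):
        dirs: list[np.ndarray] = []
        attempts = 0
        while len(dirs) < n and attempts < 20000:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if all(v @ d < min_cos for d in dirs):
                dirs.append(v)
            attempts += 1
        if len(dirs) == n:
            return np.array(dirs)
    raise ValueError(
        f"cannot place {n} cluster/singleton directions with pairwise "
        f"separation > {_MIN_SEPARATION_DEG}°"
    )


def gen_dimer_poses(
    spec: PoseFamilySpec,
) -> tuple[list[DimerPose], list[int]]:
    """Pose family with planted clusters; returns (poses, truth labels).

    Truth labels give the planted cluster index per pose, −1 for singletons.
    Within a cluster, mobile subunits differ only by isotropic Gaussian noise
    about a shared rigid placement; placements (and singletons) point in
    directions separated pairwise by more than 55° as seen from the reference
    centroid.  Every pose is additionally scrambled by its own global rigid
    motion, which superposition on the reference subunit must undo.
    """
    rng_geom = _rng(spec.seed, 0)
    rng_noise = _rng(spec.seed, 1)
    rng_global = _rng(spec.seed, 2)

    n_a = spec.atoms_per_subunit
    ref_template = rng_geom.normal(scale=6.0, size=(n_a, 3))
    ref_template -= ref_template.mean(axis=0)
    mob_template = rng_geom.normal(scale=6.0, size=(n_a, 3))
    mob_template -= mob_template.mean(axis=0)

    n_place = spec.n_clusters + spec.n_singletons
    placements: list[tuple[np.ndarray, np.ndarray]] = []
    if n_place:
        dirs = _separated_directions(n_place, rng_geom)
        for k in range(n_place):
            dist = 18.0 + 4.0 * rng_geom.random()
            rot = Rotation.random(rng=rng_geom).as_matrix()
            placements.append((rot, dirs[k] * dist))

    poses: list[DimerPose] = []
    labels: list[int] = []
    idx = 0

    def _emit(placement: tuple[np.ndarray, np.ndarray], label: int) -> None:
        nonlocal idx
        rot, shift = placement
        mob = mob_template @ rot.T + shift
        if spec.noise_sd > 0:
            mob = mob + rng_noise.normal(scale=spec.noise_sd, size=mob.shape)
        g_rot = Rotation.random(rng=rng_global).as_matrix()
        g_shift = rng_global.normal(scale=15.0, size=3)
        poses.append(
            DimerPose(
                pose_id=f"pose_{idx:03d}",
                allele=spec.allele,
                ref_atoms=ref_template @ g_rot.T + g_shift,
                mob_atoms=mob @ g_rot.T + g_shift,
            )
        )
        labels.append(label)
        idx += 1

    for c in range(spec.n_clusters):
        for _ in range(spec.poses_per_cluster):
            _emit(placements[c], c)
    for s in range(spec.n_singletons):
        _emit(placements[spec.n_clusters + s], -1)
    return poses, labels


# --------------------------------------------------------------------------
# toy ligand–dimer complexes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Toy pocket/ligand geometry parameters.

    The pocket is a ring of pseudo-residues (backbone N, CA, C, O only) of
    radius `pocket_radius` around the origin, named after the interface
    pocket of the pea receptor pair.  When `tail_in_pocket`, the carbon tail
    is threaded along the ring axis so that at least three tail atoms sit
    within van-der-Waals contact of the ring; otherwise the tail is displaced
    30 Å away.  Exactly `n_hbond_pairs` ligand oxygens are planted 2.9 Å from
    anchor-residue nitrogens, and no other polar pair comes within hydrogen-
    bond range.
    """

    pocket_radius: float = 3.5
    tail_in_pocket: bool = True
    n_tail_atoms: int = 8
    n_hbond_pairs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pocket_radius <= 0:
            raise ValueError("pocket_radius must be positive")
        if not 3 <= self.n_tail_atoms:
            raise ValueError("need at least 3 tail atoms")
        if not 0 <= self.n_hbond_pairs <= 12:
            raise ValueError("n_hbond_pairs must be within 0..12")
        # tail atoms sit 1.5 Å apart on the ring axis; the third-nearest one
        # is at most 2.25 Å off-plane, so guaranteeing three contacts at the
        # default 4.5 Å cutoff needs sqrt(r² + 2.25²) + jitter <= 4.5
        if self.pocket_radius > 3.8:
            raise ValueError(
                "pocket_radius > 3.8 Å cannot guarantee 3 tail contacts at "
                "the default 4.5 Å cutoff"
            )


def gen_toy_complex(spec: ToyComplexSpec) -> ComplexStructure:
    """Toy complex with planted pocket occupancy and hydrogen bonds."""
    rng = _rng(spec.seed, 0)
    prot_rows = []

    def _residue(chain: str, num: int, name: str, ca: np.ndarray,
                 n_dir: np.ndarray, o_dir: np.ndarray) -> None:
        jitter = rng.normal(scale=0.03, size=3)
        prot_rows.append((chain, num, name, "N", "N", *(ca + 1.45 * n_dir)))
        prot_rows.append((chain, num, name, "CA", "C", *(ca + jitter)))
        prot_rows.append((chain, num, name, "C", "C", *(ca + 1.52 * _ortho(n_dir))))
        prot_rows.append((chain, num, name, "O", "O", *(ca + 2.4 * o_dir)))

    def _ortho(v: np.ndarray) -> np.ndarray:
        w = np.cross(v, [0.0, 0.0, 1.0])
        n = np.linalg.norm(w)
        if n < 1e-6:
            w = np.cross(v, [0.0, 1.0, 0.0])
            n = np.linalg.norm(w)
        return w / n

    # pocket ring in the xy-plane; backbone N/O pushed radially outward so
    # they stay far from all ligand polar atoms
    n_pocket = len(DEFAULT_POCKET_RESIDUES)
    for k, (chain, num, name) in enumerate(DEFAULT_POCKET_RESIDUES):
        theta = 2.0 * np.pi * k / n_pocket
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = spec.pocket_radius * radial
        _residue(chain, num, name, ca, n_dir=radial, o_dir=radial)

    # hydrogen-bond anchor residues on a wider ring above the pocket plane
    anchor_r = 6.0
    anchor_z = 6.0
    anchor_nitrogens = []
    for k in range(spec.n_hbond_pairs):
        theta = 2.0 * np.pi * k / max(spec.n_hbond_pairs, 1)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = (anchor_r + 0.8) * radial + np.array([0.0, 0.0, anchor_z + 0.8])
        num = 44 + k  # arbitrary surface residues distinct from the pocket
        jitter = rng.normal(scale=0.03, size=3)
        prot_rows.append(("A", num, "ASN", "CA", "C", *(ca + jitter)))
        n_pos = anchor_r * radial + np.array([0.0, 0.0, anchor_z])
        prot_rows.append(("A", num, "ASN", "ND2", "N", *n_pos))
        o_pos = (anchor_r + 1.3) * radial + np.array([0.0, 0.0, anchor_z])
        prot_rows.append(("A", num, "ASN", "OD1", "O", *o_pos))
        anchor_nitrogens.append((num, n_pos, radial))

    protein = pd.DataFrame(
        prot_rows,
        columns=["chain", "res_number", "res_name", "atom_name", "element",
                 "x", "y", "z"],
    )

    lig_rows = []
    tail_shift = np.zeros(3) if spec.tail_in_pocket else np.array([30.0, 0.0, 0.0])
    for k in range(spec.n_tail_atoms):
        z = 1.5 * (k - (spec.n_tail_atoms - 1) / 2.0)
        pos = np.array([0.0, 0.0, z]) + tail_shift
        lig_rows.append((f"CT{k + 1}", "C", "tail", *pos))
    for k, (num, n_pos, radial) in enumerate(anchor_nitrogens):
        o_pos = n_pos - 2.9 * radial  # 2.9 Å inward from the anchor nitrogen
        lig_rows.append((f"OH{k + 1}", "O", "core", *o_pos))
    # a short non-polar core linker and an acetyl stub, well away from donors
    for k in range(3):
        lig_rows.append((f"CC{k + 1}", "C", "core",
                         0.0, 0.0, anchor_z + 3.0 + 1.5 * k))
    for k in range(2):
        lig_rows.append((f"CA{k + 1}", "C", "acetyl",
                         1.4 * (k + 1), 0.0, anchor_z + 3.0))

    ligand = pd.DataFrame(
        lig_rows, columns=["atom_id", "element", "part", "x", "y", "z"]
    )
    # keep coordinates at PDB precision so file round-trips are lossless
    for df in (protein, ligand):
        df[["x", "y", "z"]] = df[["x", "y", "z"]].round(3)
    return ComplexStructure(protein=protein, ligand=ligand)


# --------------------------------------------------------------------------
# energy tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyTableSpec:
    """Planted-feasibility energy-table parameters.

    Defaults emulate the study's thermochemical stage: 8 docking-passed
    complexes, 15 conformers each, three-quarters feasible.  `feasible_mask`
    optionally fixes feasibility complex-by-complex (overriding
    `fraction_feasible`), and `complex_ids` names the complexes.
    """

    n_complexes: int = 8
    n_conformers: int = 15
    fraction_feasible: float = 0.75
    seed: int = 0
    complex_ids: tuple[str, ...] | None = None
    feasible_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_complexes < 1 or self.n_conformers < 1:
            raise ValueError("need at least one complex and one conformer")
        if not 0.0 <= self.fraction_feasible <= 1.0:
            raise ValueError("fraction_feasible must be within [0, 1]")
        if self.complex_ids is not None and len(self.complex_ids) != self.n_complexes:
            raise ValueError("complex_ids length must equal n_complexes")
        if self.feasible_mask is not None and len(self.feasible_mask) != self.n_complexes:
            raise ValueError("feasible_mask length must equal n_complexes")


def gen_energy_table(
    spec: EnergyTableSpec,
) -> tuple[ConformerEnergyTable, dict[str, bool]]:
    """Energy table whose bonded-energy signs are constructed exactly.

    For each complex the docking energy is back-solved so that
    bonded = ΔΔG(active_solvated) + e_dock hits a drawn magnitude with the
    planted sign; the realized feasible set therefore equals the planted
    assignment exactly.  Returns (table, truth map complex_id -> feasible).
    """
    rng = _rng(spec.seed, 0)
    ids = (list(spec.complex_ids) if spec.complex_ids is not None
           else [f"complex_{k + 1:02d}" for k in range(spec.n_complexes)])
    if spec.feasible_mask is not None:
        mask = np.array(spec.feasible_mask, dtype=bool)
    else:
        n_feasible = int(round(spec.fraction_feasible * spec.n_complexes))
        mask = np.zeros(spec.n_complexes, dtype=bool)
        which = rng.choice(spec.n_complexes, size=n_feasible, replace=False)
        mask[which] = True

    rows = []
    e_dock: dict[str, float] = {}
    for cid, feas in zip(ids, mask):
        base = rng.normal(loc=-120.0, scale=20.0)
        per_state: dict[str, np.ndarray] = {}
        for state in STATES:
            offset = {"stable": 0.0, "active": rng.uniform(2.0, 8.0),
                      REFERENCE_STATE: -rng.uniform(8.0, 15.0),
                      BOUND_STATE: -rng.uniform(3.0, 12.0)}[state]
            noise = rng.uniform(0.0, 6.0, size=spec.n_conformers)
            noise[int(rng.integers(spec.n_conformers))] = 0.0  # the minimum
            per_state[state] = base + offset + noise
        for state in STATES:
            for j in range(spec.n_conformers):
                rows.append((cid, f"conf_{j + 1:03d}", state,
                             round(float(per_state[state][j]), 4)))
        ddg_bound = per_state[BOUND_STATE].min() - per_state[REFERENCE_STATE].min()
        magnitude = rng.uniform(0.5, 9.5)
        target = -magnitude if feas else magnitude
        e_dock[cid] = round(float(target - ddg_bound), 4)

    table = ConformerEnergyTable(
        energies=pd.DataFrame(
            rows, columns=["complex_id", "conformer_id", "state",
                           "energy_kcal_mol"]
        ),
        e_dock=e_dock,
    )
    return table, dict(zip(ids, (bool(m) for m in mask)))
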