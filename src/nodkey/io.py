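"""File formats: aligned FASTA, pose and complex PDB, TSV tables.

All structural I/O goes through biotite's PDB reader/writer; sequences go
through Biopython.  Poses are stored one per file with the reference (LykX)
subunit as chain A and the mobile (Sym10) subunit as chain B (chain ids
configurable); complexes add the ligand as HETATM chain X plus a two-column
annotation TSV mapping ligand atom ids to their part (core / tail / acetyl).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io import pdb as bpdb

from .alignment import AlleleAlignment
from .posecluster import DimerPose
from .recognition import ComplexStructure
from .thermo import ConformerEnergyTable


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

def write_alignment(
    aln: AlleleAlignment, fasta_path: str | Path, groups_path: str | Path
) -> None:
    """Write an aligned FASTA plus the (sequence_id, group) TSV."""
    with open(fasta_path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")
    with open(groups_path, "w") as fh:
        fh.write("sequence_id\tgroup\n")
        for sid in aln.ids:
            fh.write(f"{sid}\t{aln.groups[sid]}\n")


# --------------------------------------------------------------------------
# dimer poses
# --------------------------------------------------------------------------

def _points_to_atoms(
    xyz: np.ndarray, chain: str, start_res: int = 1
) -> struc.AtomArray:
    n = xyz.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(xyz, dtype=np.float32)
    arr.chain_id = np.full(n, chain)
    arr.res_id = np.arange(start_res, start_res + n)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    return arr


def write_pose_pdb(
    pose: DimerPose,
    path: str | Path,
    ref_chain: str = "A",
    mob_chain: str = "B",
) -> None:
    """Write one pose as a two-chain Cα-trace PDB file."""
    arr = _points_to_atoms(pose.ref_atoms, ref_chain) + _points_to_atoms(
        pose.mob_atoms, mob_chain
    )
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def read_pose_pdb(
    path: str | Path,
    allele: str = "unknown",
    ref_chain: str = "A",
    mob_chain: str = "B",
) -> DimerPose:
    """Read one pose from a two-chain PDB file; pose_id is the file stem."""
    arr = bpdb.PDBFile.read(str(path)).get_structure(model=1)
    ref = arr.coord[arr.chain_id == ref_chain]
    mob = arr.coord[arr.chain_id == mob_chain]
    if len(ref) == 0 or len(mob) == 0:
        raise ValueError(
            f"{path}: missing chain {ref_chain!r} or {mob_chain!r}"
        )
    return DimerPose(
        pose_id=Path(path).stem,
        allele=allele,
        ref_atoms=np.asarray(ref, dtype=float),
        mob_atoms=np.asarray(mob, dtype=float),
    )


def write_poses(
    poses: Iterable[DimerPose],
    out_dir: str | Path,
    ref_chain: str = "A",
    mob_chain: str = "B",
) -> list[Path]:
    """Write poses one PDB per file, named after their pose ids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for pose in poses:
        p = out / f"{pose.pose_id}.pdb"
        write_pose_pdb(pose, p, ref_chain, mob_chain)
        paths.append(p)
    return paths


def read_poses(
    pose_dir: str | Path,
    allele: str = "unknown",
    ref_chain: str = "A",
    mob_chain: str = "B",
) -> list[DimerPose]:
    """Read every ``*.pdb`` in a directory as one pose each, sorted by name."""
    paths = sorted(Path(pose_dir).glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no PDB files in {pose_dir}")
    return [read_pose_pdb(p, allele, ref_chain, mob_chain) for p in paths]


# --------------------------------------------------------------------------
# ligand–dimer complexes
# --------------------------------------------------------------------------

def write_complex(
    cx: ComplexStructure,
    pdb_path: str | Path,
    annot_path: str | Path,
    ligand_chain: str = "X",
) -> None:
    """Write a complex as PDB (ligand as HETATM) plus the part-annotation TSV."""
    prot = cx.protein
    n_p = len(prot)
    n_l = len(cx.ligand)
    arr = struc.AtomArray(n_p + n_l)
    arr.coord = np.concatenate(
        [prot[["x", "y", "z"]].to_numpy(dtype=np.float32),
         cx.ligand[["x", "y", "z"]].to_numpy(dtype=np.float32)]
    )
    arr.chain_id = np.concatenate(
        [prot["chain"].to_numpy(dtype="<U4"), np.full(n_l, ligand_chain)]
    )
    arr.res_id = np.concatenate(
        [prot["res_number"].to_numpy(dtype=int), np.full(n_l, 1)]
    )
    arr.res_name = np.concatenate(
        [prot["res_name"].to_numpy(dtype="<U5"), np.full(n_l, "NFX")]
    )
    arr.atom_name = np.concatenate(
        [prot["atom_name"].to_numpy(dtype="<U6"),
         cx.ligand["atom_id"].to_numpy(dtype="<U6")]
    )
    arr.element = np.concatenate(
        [prot["element"].to_numpy(dtype="<U2"),
         cx.ligand["element"].to_numpy(dtype="<U2")]
    )
    arr.hetero = np.concatenate([np.full(n_p, False), np.full(n_l, True)])
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(pdb_path))

    cx.ligand[["atom_id", "part"]].to_csv(annot_path, sep="\t", index=False)


def read_complex(
    pdb_path: str | Path,
    annot_path: str | Path,
    ligand_chain: str = "X",
) -> ComplexStructure:
    """Read a complex PDB plus its ligand annotation TSV.

    Every HETATM ligand atom must be annotated with exactly one part;
    unannotated or duplicate atoms raise with the offending atom id.
    """
    arr = bpdb.PDBFile.read(str(pdb_path)).get_structure(model=1)
    is_lig = (arr.chain_id == ligand_chain) & arr.hetero
    lig = arr[is_lig]
    prot = arr[~is_lig]
    if len(lig) == 0:
        raise ValueError(f"{pdb_path}: no HETATM ligand on chain {ligand_chain!r}")

    annot = pd.read_csv(annot_path, sep="\t", dtype=str)
    if not {"atom_id", "part"} <= set(annot.columns):
        raise ValueError(f"{annot_path}: need columns atom_id and part")
    if annot["atom_id"].duplicated().any():
        dup = annot.loc[annot["atom_id"].duplicated(), "atom_id"].tolist()
        raise ValueError(f"duplicate atom ids in annotation: {dup}")
    parts = dict(zip(annot["atom_id"], annot["part"]))
    missing = [a for a in lig.atom_name if a not in parts]
    if missing:
        raise ValueError(f"ligand atoms without a part annotation: {missing}")

    protein = pd.DataFrame(
        {
            "chain": prot.chain_id,
            "res_number": prot.res_id.astype(int),
            "res_name": prot.res_name,
            "atom_name": prot.atom_name,
            "element": prot.element,
            "x": prot.coord[:, 0].astype(float),
            "y": prot.coord[:, 1].astype(float),
            "z": prot.coord[:, 2].astype(float),
        }
    )
    ligand = pd.DataFrame(
        {
            "atom_id": lig.atom_name,
            "element": lig.element,
            "part": [parts[a] for a in lig.atom_name],
            "x": lig.coord[:, 0].astype(float),
            "y": lig.coord[:, 1].astype(float),
            "z": lig.coord[:, 2].astype(float),
        }
    )
    return ComplexStructure(protein=protein, ligand=ligand)


# --------------------------------------------------------------------------
# energy tables
# --------------------------------------------------------------------------

def write_energy_table(
    table: ConformerEnergyTable,
    energies_path: str | Path,
    dock_path: str | Path,
) -> None:
    """Write the per-conformer energy TSV and the docking-energy TSV."""
    table.energies.to_csv(energies_path, sep="\t", index=False)
    dock = pd.DataFrame(
        sorted(table.e_dock.items()), columns=["complex_id", "e_dock_kcal_mol"]
    )
    dock.to_csv(dock_path, sep="\t", index=False)


def write_truth_tsv(truth: Mapping[str, object], path: str | Path) -> None:
    """Write a flat key/value truth record as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in truth.items():
            fh.write(f"{k}\t{v}\n")
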