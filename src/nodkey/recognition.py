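"""Geometric Nod-factor recognition criterion for receptor heterodimers.

A Nod factor (NF) is counted as *recognized* by a LykX–Sym10 heterodimer when
its fatty-acyl tail sits inside the hydrophobic pocket formed at the
subunit–subunit interface — operationally, when at least ``min_tail_contacts``
tail heavy atoms lie within a van-der-Waals contact cutoff of the pocket
residues.  Hydrogen bonds between the NF and the dimer, and the full list of
contact residues, are reported as diagnostics.

The default pocket is the interface cavity described for the pea receptor
pair: Val37, Met38, Pro39, Ala40, Phe41, Leu42, Leu43, Tyr119 and Ala121 of
LykX (chain A) plus Val217 and Phe218 of Sym10 (chain B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

LIGAND_PARTS = ("core", "tail", "acetyl")

#: Interface pocket residues: (chain, residue number, residue name).
DEFAULT_POCKET_RESIDUES: tuple[tuple[str, int, str], ...] = (
    ("A", 37, "VAL"), ("A", 38, "MET"), ("A", 39, "PRO"), ("A", 40, "ALA"),
    ("A", 41, "PHE"), ("A", 42, "LEU"), ("A", 43, "LEU"), ("A", 119, "TYR"),
    ("A", 121, "ALA"),
    ("B", 217, "VAL"), ("B", 218, "PHE"),
)

_POLAR = {"N", "O"}
_HYDROGEN = {"H", "D"}


@dataclass(frozen=True)
class ComplexStructure:
    """A dimer plus an annotated ligand in one coordinate frame.

    `protein` columns: chain, res_number, res_name, atom_name, element, x, y, z.
    `ligand` columns: atom_id, element, part, x, y, z with part in
    {core, tail, acetyl}.
    """

    protein: pd.DataFrame
    ligand: pd.DataFrame

    def __post_init__(self) -> None:
        need_p = {"chain", "res_number", "res_name", "atom_name",
                  "element", "x", "y", "z"}
        need_l = {"atom_id", "element", "part", "x", "y", "z"}
        if not need_p <= set(self.protein.columns):
            raise ValueError(f"protein table missing {need_p - set(self.protein.columns)}")
        if not need_l <= set(self.ligand.columns):
            raise ValueError(f"ligand table missing {need_l - set(self.ligand.columns)}")
        bad = set(self.ligand["part"]) - set(LIGAND_PARTS)
        if bad:
            raise ValueError(f"unknown ligand part labels: {sorted(bad)}")
        if self.ligand["atom_id"].duplicated().any():
            dups = self.ligand.loc[self.ligand["atom_id"].duplicated(), "atom_id"]
            raise ValueError(f"duplicated ligand atom ids: {sorted(set(dups))}")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ComplexStructure":
        """Apply the rigid map ``x -> R x + t`` to every atom."""
        prot = self.protein.copy()
        lig = self.ligand.copy()
        for df in (prot, lig):
            xyz = df[["x", "y", "z"]].to_numpy() @ np.asarray(R).T + np.asarray(t)
            df[["x", "y", "z"]] = xyz
        return ComplexStructure(protein=prot, ligand=lig)


@dataclass(frozen=True)
class PocketDefinition:
    """Residues forming the tail-binding pocket plus the contact rule."""

    residues: tuple[tuple[str, int, str], ...] = DEFAULT_POCKET_RESIDUES
    cutoff: float = 4.5  # Å, heavy-atom/heavy-atom
    min_tail_contacts: int = 3

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("pocket must contain at least one residue")
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class RecognitionResult:
    recognized: bool
    tail_contacts: int
    hbond_count: int
    contact_residues: pd.DataFrame = field(repr=False, default=None)


def _heavy(df: pd.DataFrame) -> pd.DataFrame:
    return df[~df["element"].str.upper().isin(_HYDROGEN)]


def tail_pocket_contacts(cx: ComplexStructure, pocket: PocketDefinition) -> int:
    """Number of tail heavy atoms within the cutoff of any pocket heavy atom."""
    keys = {(c, n) for c, n, _ in pocket.residues}
    prot = _heavy(cx.protein)
    mask = [
        (row.chain, row.res_number) in keys for row in prot.itertuples()
    ]
    pocket_atoms = prot[mask]
    present = {(row.chain, row.res_number) for row in pocket_atoms.itertuples()}
    missing = sorted(keys - present)
    if missing:
        raise ValueError(f"pocket residues absent from structure: {missing}")

    tail = _heavy(cx.ligand[cx.ligand["part"] == "tail"])
    if tail.empty or pocket_atoms.empty:
        return 0
    d = cdist(tail[["x", "y", "z"]], pocket_atoms[["x", "y", "z"]])
    return int((d.min(axis=1) <= pocket.cutoff).sum())


def count_hydrogen_bonds(
    cx: ComplexStructure, d_max: float = 3.5, angle_min: float = 120.0
) -> int:
    """Protein–ligand hydrogen bonds by a geometric criterion.

    A donor–acceptor pair is two polar heavy atoms (N or O), one on each
    side, with heavy-atom distance <= `d_max` Å.  When explicit hydrogens are
    present on the donor side, the D–H···A angle must also reach `angle_min`
    degrees; without hydrogens the distance criterion alone is used — the
    common situation for docking poses stripped of protons.
    """
    prot = cx.protein[cx.protein["element"].str.upper().isin(_POLAR)]
    lig = cx.ligand[cx.ligand["element"].str.upper().isin(_POLAR)]
    if prot.empty or lig.empty:
        return 0
    pxyz = prot[["x", "y", "z"]].to_numpy()
    lxyz = lig[["x", "y", "z"]].to_numpy()
    d = cdist(pxyz, lxyz)
    pairs = np.argwhere(d <= d_max)
    if pairs.size == 0:
        return 0

    hydro = cx.protein[cx.protein["element"].str.upper().isin(_HYDROGEN)]
    if hydro.empty:
        return int(len(pairs))

    hxyz = hydro[["x", "y", "z"]].to_numpy()
    count = 0
    for pi, li in pairs:
        dvec = pxyz[pi]
        avec = lxyz[li]
        # hydrogens covalently bound to the protein donor (within 1.25 Å)
        dh = np.linalg.norm(hxyz - dvec, axis=1)
        bound = hxyz[dh <= 1.25]
        if bound.size == 0:
            count += 1  # donor may be the ligand side; fall back to distance
            continue
        ok = False
        for h in bound:
            u = dvec - h
            v = avec - h
            cosang = u @ v / max(np.linalg.norm(u) * np.linalg.norm(v), 1e-12)
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                ok = True
                break
        count += int(ok)
    return count


def contact_residues(cx: ComplexStructure, cutoff: float = 4.0) -> pd.DataFrame:
    """Residues with >= 1 heavy atom within `cutoff` Å of any ligand heavy atom.

    Returns a table (chain, res_number, res_name, n_contacts) sorted by chain
    then residue number; n_contacts counts protein heavy atoms in contact.
    """
    prot = _heavy(cx.protein)
    lig = _heavy(cx.ligand)
    cols = ["chain", "res_number", "res_name", "n_contacts"]
    if prot.empty or lig.empty:
        return pd.DataFrame(columns=cols)
    d = cdist(prot[["x", "y", "z"]], lig[["x", "y", "z"]])
    in_contact = (d.min(axis=1) <= cutoff)
    hits = prot[in_contact]
    if hits.empty:
        return pd.DataFrame(columns=cols)
    out = (
        hits.groupby(["chain", "res_number", "res_name"], as_index=False)
        .size()
        .rename(columns={"size": "n_contacts"})
        .sort_values(["chain", "res_number"], ignore_index=True)
    )
    return out[cols]


def recognize(
    cx: ComplexStructure,
    pocket: PocketDefinition | None = None,
    min_tail_contacts: int | None = None,
    min_hbonds: int = 0,
) -> RecognitionResult:
    """Apply the pocket-occupancy recognition criterion with diagnostics.

    Recognition requires the fatty tail in the pocket (tail contacts >=
    `min_tail_contacts`, defaulting to the pocket definition's own minimum)
    and, optionally, at least `min_hbonds` protein–ligand hydrogen bonds
    (0 by default: pocket occupancy alone decides).
    """
    pocket = pocket or PocketDefinition()
    if min_tail_contacts is None:
        min_tail_contacts = pocket.min_tail_contacts
    tc = tail_pocket_contacts(cx, pocket)
    hb = count_hydrogen_bonds(cx)
    return RecognitionResult(
        recognized=(tc >= min_tail_contacts) and (hb >= min_hbonds),
        tail_contacts=tc,
        hbond_count=hb,
        contact_residues=contact_residues(cx),
    )
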