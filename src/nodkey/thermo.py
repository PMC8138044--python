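"""Conformer selection and thermodynamic-cycle bookkeeping for NF states.

A Nod factor changes conformation between its free solvated state and the
receptor-bound pose.  Feasibility of a complex is judged from a four-state
thermodynamic cycle over per-conformer energies:

* ``stable`` — lowest-energy free conformation (gas phase),
* ``active`` — the bound-pose conformation re-optimised free (gas phase),
* ``stable_solvated`` / ``active_solvated`` — the same with solvent
  corrections.

Per state, ΔG is the lowest conformer energy.  All states are referenced to
``stable_solvated`` (ΔΔG = ΔG(state) − ΔG(reference)), and the *bonded*
energy is ΔΔG(active_solvated) plus the docking energy of the complex.  A
strictly negative bonded energy marks a thermodynamically feasible complex;
zero or positive bonded energy is infeasible.

Energies are carried in kcal/mol throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

STATES = ("stable", "active", "stable_solvated", "active_solvated")
REFERENCE_STATE = "stable_solvated"
BOUND_STATE = "active_solvated"


@dataclass(frozen=True)
class ConformerEnergyTable:
    """Per-conformer, per-state energies plus a docking energy per complex.

    `energies` columns: complex_id, conformer_id, state, energy_kcal_mol.
    `e_dock` maps complex_id -> docking energy (kcal/mol).
    """

    energies: pd.DataFrame
    e_dock: Mapping[str, float]

    def __post_init__(self) -> None:
        need = {"complex_id", "conformer_id", "state", "energy_kcal_mol"}
        if not need <= set(self.energies.columns):
            raise ValueError(f"energy table missing columns {need - set(self.energies.columns)}")
        bad_states = set(self.energies["state"]) - set(STATES)
        if bad_states:
            raise ValueError(f"unknown states: {sorted(bad_states)}")
        key = self.energies[["complex_id", "conformer_id", "state"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate energy entry for {tuple(dup)}")
        has_bound = set(
            self.energies.loc[self.energies["state"] == BOUND_STATE, "complex_id"]
        )
        missing_dock = sorted(has_bound - set(self.e_dock))
        if missing_dock:
            raise ValueError(f"complexes missing a docking energy: {missing_dock}")


@dataclass(frozen=True)
class StateLedger:
    """Per-complex ΔG/ΔΔG per state plus the bonded-energy verdict.

    `states` columns: complex_id, state, dG, ddG.
    `complexes` columns: complex_id, e_dock, bonded, feasible.
    """

    states: pd.DataFrame
    complexes: pd.DataFrame
    reference: str = REFERENCE_STATE


def select_conformers(energies: Mapping[str, float] | pd.Series, k: int) -> list[str]:
    """Ids of the min(k, n) lowest-energy conformers, ascending.

    Ties at equal energy are broken toward the lexicographically lower id —
    the rule used both when thinning a conformer search to its best 100 and
    when picking the 15 taken into docking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = list(pd.Series(energies).items())
    if not items:
        raise ValueError("empty conformer energy table")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    return [cid for cid, _ in items[:k]]


def build_ledger(
    table: ConformerEnergyTable, reference: str = REFERENCE_STATE
) -> StateLedger:
    """Lowest-conformer ΔG per state, ΔΔG vs the reference, bonded energy.

    bonded = ΔΔG(active_solvated) + e_dock; adding a constant to every state
    energy of a complex leaves ΔΔG and bonded unchanged.
    """
    if reference not in STATES:
        raise ValueError(f"unknown reference state {reference!r}")
    dg = (
        table.energies.groupby(["complex_id", "state"], as_index=False)
        ["energy_kcal_mol"].min()
        .rename(columns={"energy_kcal_mol": "dG"})
    )
    ref = dg[dg["state"] == reference].set_index("complex_id")["dG"]
    all_complexes = sorted(set(dg["complex_id"]))
    missing_ref = sorted(set(all_complexes) - set(ref.index))
    if missing_ref:
        raise ValueError(
            f"complexes missing the reference state {reference!r}: {missing_ref}"
        )
    dg["ddG"] = dg["dG"] - dg["complex_id"].map(ref)

    rows = []
    bound = dg[dg["state"] == BOUND_STATE].set_index("complex_id")["ddG"]
    for cid in all_complexes:
        if cid not in bound.index:
            raise ValueError(f"complex {cid!r} has no {BOUND_STATE!r} energy")
        if cid not in table.e_dock:
            raise ValueError(f"complex {cid!r} has no docking energy")
        e_dock = float(table.e_dock[cid])
        bonded = float(bound[cid]) + e_dock
        rows.append((cid, e_dock, bonded, bonded < 0.0))
    complexes = pd.DataFrame(
        rows, columns=["complex_id", "e_dock", "bonded", "feasible"]
    )
    dg = dg.sort_values(["complex_id", "state"], ignore_index=True)
    return StateLedger(states=dg, complexes=complexes, reference=reference)


def thermo_verdict(ledger: StateLedger) -> dict[str, bool]:
    """Feasible ⇔ bonded < 0 (bonded == 0 counts as infeasible)."""
    return dict(
        zip(ledger.complexes["complex_id"], ledger.complexes["feasible"])
    )


def read_energy_table(
    energies_path: str | Path, dock_path: str | Path
) -> ConformerEnergyTable:
    """Read the TSV energy table and TSV docking-energy table."""
    energies = pd.read_csv(energies_path, sep="\t", dtype={"complex_id": str,
                                                           "conformer_id": str})
    dock = pd.read_csv(dock_path, sep="\t", dtype={"complex_id": str})
    if not {"complex_id", "e_dock_kcal_mol"} <= set(dock.columns):
        raise ValueError("docking table needs complex_id and e_dock_kcal_mol")
    e_dock = dict(zip(dock["complex_id"], dock["e_dock_kcal_mol"].astype(float)))
    return ConformerEnergyTable(energies=energies, e_dock=e_dock)


def write_ledger(ledger: StateLedger, path: str | Path) -> None:
    """Write the ledger as one TSV: complex_id, state, dG, ddG, bonded, feasible."""
    merged = ledger.states.merge(
        ledger.complexes[["complex_id", "e_dock", "bonded", "feasible"]],
        on="complex_id",
    )
    with open(path, "w") as fh:
        fh.write("# energies in kcal/mol; reference state = "
                 f"{ledger.reference}\n")
        merged.to_csv(fh, sep="\t", index=False)
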