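"""Verdict composition and end-to-end orchestration.

The analysis asks, per (allele, NF type) pair, three independent questions —
does the NF dock with its tail in the inter-subunit pocket, is the complex
stable along an MD trajectory, and is the bound state thermodynamically
reachable?  The final verdict is their conjunction.  MD and thermochemistry
only ever ran on docking-passed complexes, so those fields are null for
docking-failed pairs.

:func:`run_pipeline` drives all stages from a YAML config whose stage blocks
either point at input files or at `simulate:` specs for the synthetic
generators, and writes TSV tables, a JSON summary and a parameter log.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import alignment as aln_mod
from . import io as nio
from . import simulate as sim
from . import thermo as thermo_mod
from .posecluster import cluster_poses
from .recognition import PocketDefinition, recognize
from .studydata import ALLELES, NF_TYPES, Pair, load_study_labels, parse_complex_id

ALL_PAIRS: tuple[Pair, ...] = tuple(
    (a, n) for a in ALLELES for n in NF_TYPES
)


def compose_verdicts(
    docking: Mapping[Pair, bool],
    md_labels: Mapping[Pair, bool],
    thermo: Mapping[Pair, bool],
    pairs: tuple[Pair, ...] = ALL_PAIRS,
    provenance: str = "labeled",
) -> pd.DataFrame:
    """Conjoin the three per-complex filters into the final verdict table.

    `docking` must cover every pair; `md_labels` and `thermo` must cover
    every docking-passed pair (they may cover more).  Docking-failed pairs
    get null md/thermo fields and a False final verdict.
    """
    missing_dock = [p for p in pairs if p not in docking]
    if missing_dock:
        raise ValueError(f"docking labels missing for pairs: {missing_dock}")
    passed = [p for p in pairs if docking[p]]
    gaps = [p for p in passed if p not in md_labels or p not in thermo]
    if gaps:
        raise ValueError(
            f"md/thermo labels missing for docking-passed pairs: {gaps}"
        )
    rows = []
    for allele, nf in pairs:
        d = bool(docking[(allele, nf)])
        m = bool(md_labels[(allele, nf)]) if d else pd.NA
        t = bool(thermo[(allele, nf)]) if d else pd.NA
        final = d and bool(m) and bool(t) if d else False
        rows.append((allele, nf, d, m, t, final, provenance))
    return pd.DataFrame(
        rows,
        columns=["allele", "nf_type", "docking_pass", "md_pass",
                 "thermo_pass", "final_pass", "provenance"],
    ).astype({"docking_pass": bool, "final_pass": bool})


def summarize(verdicts: pd.DataFrame) -> dict[str, int]:
    """Stage-by-stage pass counts over the verdict table."""
    return {
        "total": int(len(verdicts)),
        "docking_passed": int(verdicts["docking_pass"].sum()),
        "md_passed": int((verdicts["md_pass"] == True).sum()),  # noqa: E712
        "thermo_passed": int((verdicts["thermo_pass"] == True).sum()),  # noqa: E712
        "final_passed": int(verdicts["final_pass"].sum()),
    }


def final_by_allele(verdicts: pd.DataFrame) -> dict[str, int]:
    """Number of NF types each allele's dimer finally accepts."""
    out = {a: 0 for a in verdicts["allele"].unique()}
    for r in verdicts.itertuples():
        if r.final_pass:
            out[r.allele] += 1
    return out


# --------------------------------------------------------------------------
# config-driven orchestration
# --------------------------------------------------------------------------

def _labels_from_tsv(path: str | Path) -> dict[Pair, bool]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"allele", "nf_type", "pass"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: label table needs columns {sorted(need)}")
    return {
        (r.allele, r.nf_type): bool(int(getattr(r, "pass")))
        for r in df.itertuples()
    }


def _stage(config: dict, name: str) -> dict | None:
    block = config.get("stages", {}).get(name)
    if block is not None and not isinstance(block, dict):
        raise ValueError(f"stage {name!r}: expected a mapping")
    return block


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run all configured stages and write their outputs under `out_dir`.

    Stage blocks (all optional except `verdicts`): `alignment`, `poses`,
    `complexes`, `energies`, `verdicts`.  Each accepts either file inputs or
    a `simulate:` spec; `verdicts` composes docking/md/thermo labels that
    come from files, from the packaged study fixture (``labels: study``), or
    from the computed recognition/thermo stages.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("empty or invalid pipeline config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: list[str] = [f"seed\t{seed}"]
    summary: dict[str, object] = {}

    try:
        stage = "alignment"
        block = _stage(config, stage)
        if block:
            if "simulate" in block:
                spec = sim.AlignmentSpec(**{"seed": seed, **block["simulate"]})
                aln, truth = sim.gen_alignment(spec)
                nio.write_alignment(aln, out / "alignment.fasta",
                                    out / "alignment_groups.tsv")
                nio.write_truth_tsv(
                    {"between_sites": ",".join(map(str, truth.between_sites)),
                     "within_sites": ",".join(map(str, truth.within_sites))},
                    out / "alignment_truth.tsv",
                )
                log.append(f"alignment\tsimulated {spec}")
            else:
                aln = aln_mod.load_alignment(block["fasta"], block["groups"])
                log.append(f"alignment\tloaded {block['fasta']}")
            report = aln_mod.analyze(aln)
            aln_mod.write_report(report, out)
            summary["n_polymorphic_sites"] = len(report.polymorphic_sites)
            summary["n_between_group_sites"] = len(report.between_group_sites)
            summary["mean_pairwise_diff"] = round(report.mean_pairwise_diff, 6)

        stage = "poses"
        block = _stage(config, stage)
        if block:
            if "simulate" in block:
                spec = sim.PoseFamilySpec(**{"seed": seed, **block["simulate"]})
                poses, labels = sim.gen_dimer_poses(spec)
                nio.write_truth_tsv(
                    {p.pose_id: lab for p, lab in zip(poses, labels)},
                    out / "pose_truth.tsv",
                )
                log.append(f"poses\tsimulated {spec}")
            else:
                poses = nio.read_poses(
                    block["dir"],
                    ref_chain=block.get("ref_chain", "A"),
                    mob_chain=block.get("mob_chain", "B"),
                )
                log.append(f"poses\tloaded {block['dir']}")
            cs, table, _aligned = cluster_poses(
                poses,
                angle_max=float(block.get("angle_max", 45.0)),
                corr_min=float(block.get("corr_min", 0.5)),
                min_group=int(block.get("min_group", 4)),
                seed=seed,
            )
            table.to_csv(out / "pose_measures.tsv", sep="\t", index=False)
            with open(out / "pose_clusters.tsv", "w") as fh:
                fh.write("cluster\tpose_id\trepresentative\n")
                for k, cluster in enumerate(cs.clusters):
                    for pid in sorted(cluster):
                        fh.write(
                            f"{k}\t{pid}\t{int(pid == cs.representatives[k])}\n"
                        )
                for pid in sorted(cs.unclustered):
                    fh.write(f"unclustered\t{pid}\t0\n")
            summary["n_pose_clusters"] = len(cs.clusters)
            summary["n_unclustered_poses"] = len(cs.unclustered)

        stage = "complexes"
        block = _stage(config, stage)
        recognition_labels: dict[Pair, bool] = {}
        if block:
            specs = block.get("simulate")
            results = []
            if specs is not None:
                for entry in specs:
                    entry = dict(entry)
                    cid = entry.pop("complex_id")
                    spec = sim.ToyComplexSpec(**{"seed": seed, **entry})
                    cx = sim.gen_toy_complex(spec)
                    res = recognize(cx, PocketDefinition())
                    results.append((cid, res))
            else:
                for entry in block["files"]:
                    cid = entry["complex_id"]
                    cx = nio.read_complex(entry["pdb"], entry["annot"])
                    res = recognize(cx, PocketDefinition())
                    results.append((cid, res))
            with open(out / "recognition.tsv", "w") as fh:
                fh.write("complex_id\trecognized\ttail_contacts\thbond_count\n")
                for cid, res in results:
                    fh.write(f"{cid}\t{int(res.recognized)}"
                             f"\t{res.tail_contacts}\t{res.hbond_count}\n")
            for cid, res in results:
                recognition_labels[parse_complex_id(cid)] = res.recognized
            log.append(f"complexes\t{len(results)} structures scored")

        stage = "energies"
        block = _stage(config, stage)
        thermo_labels: dict[Pair, bool] = {}
        if block:
            if "simulate" in block:
                spec = sim.EnergyTableSpec(**{"seed": seed, **block["simulate"]})
                table, _truth = sim.gen_energy_table(spec)
                nio.write_energy_table(table, out / "energies.tsv",
                                       out / "dock_energies.tsv")
                log.append(f"energies\tsimulated {spec}")
            else:
                table = thermo_mod.read_energy_table(block["energies"],
                                                     block["dock"])
                log.append(f"energies\tloaded {block['energies']}")
            ledger = thermo_mod.build_ledger(
                table, block.get("reference", thermo_mod.REFERENCE_STATE)
            )
            thermo_mod.write_ledger(ledger, out / "thermo_ledger.tsv")
            for cid, ok in thermo_mod.thermo_verdict(ledger).items():
                try:
                    thermo_labels[parse_complex_id(cid)] = ok
                except ValueError:
                    pass  # synthetic complex ids need not map to study pairs
            summary["n_thermo_feasible"] = int(
                ledger.complexes["feasible"].sum()
            )

        stage = "verdicts"
        block = _stage(config, stage)
        if block:
            def _resolve(which: str, computed: dict[Pair, bool]) -> dict[Pair, bool]:
                sub = block.get(which, {})
                if sub.get("labels") == "study":
                    idx = {"docking": 0, "md": 1, "thermo": 2}[which]
                    return load_study_labels()[idx]
                if "labels" in sub:
                    return _labels_from_tsv(sub["labels"])
                if sub.get("from") == "computed":
                    return computed
                raise ValueError(
                    f"verdicts.{which}: need labels: <path>|study or "
                    "from: computed"
                )

            docking = _resolve("docking", recognition_labels)
            md = _resolve("md", {})
            thermo = _resolve("thermo", thermo_labels)
            verdicts = compose_verdicts(docking, md, thermo)
            verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
            summary.update(summarize(verdicts))
            summary["final_by_allele"] = final_by_allele(verdicts)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return out
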