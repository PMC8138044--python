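"""Published per-complex stage outcomes for the pea receptor study system.

The structural stages behind these labels (docking, MD, quantum-chemical
thermochemistry) run on external engines; their published pass/fail outcomes
per (allele, NF type) pair ship here as a small fixture table so the verdict
composition can be exercised end-to-end without any structure computation.

The encoded observations: acetylated NFs (NF5Ac, NF4Ac) dock successfully
into all three dimers; NF5NonAc docks only into the Tajik dimer and NF4NonAc
only into the European one (8 successes of 12).  Thermochemistry rejects the
two four-sugar acetylated complexes E-NF4Ac and A-NF4Ac (6 remain), and MD
rejects T-NF5NonAc, whose tail leaves the pocket (5 final).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

ALLELES = ("Afghan", "Tajik", "European")
NF_TYPES = ("NF5Ac", "NF4Ac", "NF5NonAc", "NF4NonAc")

_ALLELE_PREFIX = {"Afghan": "A", "Tajik": "T", "European": "E"}
_PREFIX_ALLELE = {v: k for k, v in _ALLELE_PREFIX.items()}

Pair = tuple[str, str]


def complex_id(allele: str, nf_type: str) -> str:
    """Short complex name, e.g. ``("European", "NF4Ac") -> "E-NF4Ac"``."""
    return f"{_ALLELE_PREFIX[allele]}-{nf_type}"


def parse_complex_id(cid: str) -> Pair:
    """Inverse of :func:`complex_id`; accepts full allele prefixes too."""
    prefix, _, nf = cid.partition("-")
    allele = _PREFIX_ALLELE.get(prefix, prefix)
    if allele not in ALLELES:
        raise ValueError(f"cannot parse allele from complex id {cid!r}")
    if nf not in NF_TYPES:
        raise ValueError(f"cannot parse NF type from complex id {cid!r}")
    return allele, nf


def _fixture_path() -> Path:
    return Path(str(resources.files("nodkey").joinpath("data/reported_outcomes.tsv")))


def load_study_labels(
    path: str | Path | None = None,
) -> tuple[dict[Pair, bool], dict[Pair, bool], dict[Pair, bool]]:
    """Load (docking, md, thermo) pass/fail maps keyed by (allele, nf_type).

    md and thermo maps contain only the docking-passed pairs, mirroring the
    study's workflow where the later stages ran on surviving complexes only.
    """
    df = load_study_table(path)
    docking = {
        (r.allele, r.nf_type): bool(int(r.docking_pass)) for r in df.itertuples()
    }
    md, thermo = {}, {}
    for r in df.itertuples():
        if int(r.docking_pass):
            md[(r.allele, r.nf_type)] = bool(int(r.md_pass))
            thermo[(r.allele, r.nf_type)] = bool(int(r.thermo_pass))
    return docking, md, thermo


def load_study_table(path: str | Path | None = None) -> pd.DataFrame:
    """The raw fixture table (one row per allele × NF type)."""
    df = pd.read_csv(path or _fixture_path(), sep="\t", dtype=str)
    need = {"allele", "nf_type", "docking_pass", "md_pass", "thermo_pass"}
    if not need <= set(df.columns):
        raise ValueError(f"label table missing columns {need - set(df.columns)}")
    return df
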