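"""Polymorphism analysis of allele-grouped amino-acid alignments.

The pea *Sym2* candidate gene *LykX* carries allele variants (Afghan, Tajik,
European) that differ at a handful of amino-acid positions.  This module finds
the polymorphic columns of a pre-aligned set of sequences, separates the
columns that segregate *between* allele groups from within-group noise,
computes the mean pairwise difference, and picks each group's modal (most
frequent) sequence — the representative used for structural modelling.

Columns are reported 1-based so site numbers can be read directly against
residue labels such as #44.  The gap character ``-`` is treated as a 21st
symbol in both polymorphism and Hamming counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AlleleAlignment:
    """Equal-length amino-acid sequences with a group label per sequence.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, in input order.
    sequences:
        Aligned sequences (same order as `ids`), all of equal length.
    groups:
        Map from sequence id to allele-group label (e.g. ``"Afghan"``).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        if len(self.ids) == 0:
            raise ValueError("alignment is empty")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i, c in Counter(self.ids).items() if c > 1]
            raise ValueError(f"duplicated sequence ids: {dup}")
        length = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise ValueError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
        missing = [sid for sid in self.ids if sid not in self.groups]
        if missing:
            raise ValueError(f"sequence ids without a group label: {missing}")
        unknown = [sid for sid in self.groups if sid not in set(self.ids)]
        if unknown:
            raise ValueError(f"group table ids absent from alignment: {unknown}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def group_names(self) -> tuple[str, ...]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.ids:
            seen.setdefault(self.groups[sid], None)
        return tuple(seen)

    def sequences_in(self, group: str) -> tuple[str, ...]:
        if group not in self.group_names:
            raise KeyError(f"unknown group {group!r}")
        return tuple(
            seq for sid, seq in zip(self.ids, self.sequences)
            if self.groups[sid] == group
        )

    def column(self, site: int) -> tuple[str, ...]:
        """Residues of 1-based column `site`, in sequence order."""
        if not 1 <= site <= self.length:
            raise IndexError(f"site {site} outside 1..{self.length}")
        return tuple(seq[site - 1] for seq in self.sequences)


@dataclass(frozen=True)
class PolymorphismReport:
    polymorphic_sites: tuple[int, ...]
    between_group_sites: tuple[int, ...]
    mean_pairwise_diff: float
    modal_sequences: Mapping[str, str] = field(default_factory=dict)


def load_alignment(fasta_path: str | Path, groups_path: str | Path) -> AlleleAlignment:
    """Read an aligned FASTA plus a two-column TSV (sequence_id, group)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)

    groups: dict[str, str] = {}
    with open(groups_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("sequence_id", "id"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{groups_path}:{lineno}: expected 2 columns")
            sid, grp = parts[0], parts[1]
            if sid in groups:
                raise ValueError(f"duplicated id {sid!r} in group table")
            groups[sid] = grp
    return AlleleAlignment(ids=ids, sequences=seqs, groups=groups)


def polymorphic_sites(aln: AlleleAlignment) -> list[int]:
    """1-based columns with at least two distinct symbols (gap included)."""
    return [
        i + 1
        for i in range(aln.length)
        if len({seq[i] for seq in aln.sequences}) >= 2
    ]


def _column_consensus(residues: Sequence[str]) -> str:
    """Modal residue of a column slice; ties broken alphabetically."""
    counts = Counter(residues)
    best = max(counts.values())
    return min(r for r, c in counts.items() if c == best)


def between_group_sites(aln: AlleleAlignment) -> list[int]:
    """Columns where the per-group consensus residues are not all identical."""
    groups = aln.group_names
    if len(groups) < 2:
        return []
    group_seqs = {g: aln.sequences_in(g) for g in groups}
    sites = []
    for i in range(aln.length):
        consensus = {_column_consensus([s[i] for s in group_seqs[g]]) for g in groups}
        if len(consensus) > 1:
            sites.append(i + 1)
    return sites


def mean_pairwise_difference(aln: AlleleAlignment) -> float:
    """Average Hamming distance over all unordered sequence pairs."""
    if len(aln.sequences) < 2:
        raise ValueError("need at least two sequences")
    total = 0
    npairs = 0
    for a, b in combinations(aln.sequences, 2):
        total += sum(x != y for x, y in zip(a, b))
        npairs += 1
    return total / npairs


def modal_sequence(aln: AlleleAlignment, group: str) -> str:
    """Most frequent full-length sequence in `group`; ties -> first occurrence."""
    seqs = aln.sequences_in(group)
    counts = Counter(seqs)
    best = max(counts.values())
    for seq in seqs:  # first-occurrence tie break
        if counts[seq] == best:
            return seq
    raise AssertionError("unreachable")


def analyze(aln: AlleleAlignment) -> PolymorphismReport:
    """Full per-alignment report: site lists, diversity, modal sequences."""
    return PolymorphismReport(
        polymorphic_sites=tuple(polymorphic_sites(aln)),
        between_group_sites=tuple(between_group_sites(aln)),
        mean_pairwise_diff=(
            mean_pairwise_difference(aln) if len(aln.sequences) >= 2 else 0.0
        ),
        modal_sequences={g: modal_sequence(aln, g) for g in aln.group_names},
    )


def write_report(report: PolymorphismReport, out_dir: str | Path) -> None:
    """Write a TSV report plus per-group modal sequences as FASTA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "polymorphism_report.tsv", "w") as fh:
        fh.write("section\tvalue\n")
        fh.write(
            "polymorphic_sites\t"
            + ",".join(map(str, report.polymorphic_sites)) + "\n"
        )
        fh.write(
            "between_group_sites\t"
            + ",".join(map(str, report.between_group_sites)) + "\n"
        )
        fh.write(f"n_polymorphic_sites\t{len(report.polymorphic_sites)}\n")
        fh.write(f"n_between_group_sites\t{len(report.between_group_sites)}\n")
        fh.write(f"mean_pairwise_diff\t{report.mean_pairwise_diff:.6g}\n")
    with open(out / "modal_sequences.fasta", "w") as fh:
        for group, seq in report.modal_sequences.items():
            fh.write(f">{group}\n{seq}\n")
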