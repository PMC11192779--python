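"""Ragged-end inference of exopeptidase trimming.

Aminopeptidases remove one residue at a time from a peptide's N-terminus,
dipeptidyl peptidases remove two; both leave ladders of peptides that are
identical except for one or two missing N-terminal residues. A peptide is
annotated as a trimming product when an identified parent peptide exists
that shares its last five residues and is longer by exactly one
(aminopeptidase) or two (dipeptidase) residues on the N-terminal side —
i.e. the peptide is a proper suffix of the parent.

When both a 1-residue and a 2-residue parent exist, the closest (1-residue)
parent wins; among parents at equal distance the lexicographically smallest
is chosen, so the output is deterministic and independent of input order.
The reported ``round`` is the trimming-chain depth: products of unannotated
(root) parents are round 1, products of round-r parents are round r+1 —
annotated peptides act as parents for the next round until no ragged-end
pattern remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger("terminome")

MIN_LENGTH = 5  # "share the last five residues" needs at least five


@dataclass(frozen=True)
class TrimAnnotation:
    peptide: str
    parent: str
    kind: str  # aminopeptidase (parent longer by 1) | dipeptidase (by 2)
    round: int

    def __post_init__(self) -> None:
        diff = len(self.parent) - len(self.peptide)
        expected = {"aminopeptidase": 1, "dipeptidase": 2}[self.kind]
        if diff != expected or not self.parent.endswith(self.peptide):
            raise ValueError("inconsistent trim annotation")


def infer_trimming(peptides: list[str]) -> list[TrimAnnotation]:
    """Annotate aminopeptidase/dipeptidase trimming products.

    Operates on stripped sequences (modifications are ignored). Sequences
    shorter than five residues do not participate. Output is sorted by
    (length, sequence) and independent of input order.
    """
    unique = sorted(set(peptides), key=lambda s: (len(s), s))
    short = [p for p in unique if len(p) < MIN_LENGTH]
    if short:
        logger.info("exopeptidase: skipping %d peptides shorter than %d "
                    "residues", len(short), MIN_LENGTH)
    eligible = [p for p in unique if len(p) >= MIN_LENGTH]
    pool = set(eligible)

    parent_of: dict[str, str] = {}
    for pep in eligible:
        chosen = None
        for diff in (1, 2):  # closest-parent rule: 1-residue first
            candidates = sorted(
                q for q in pool
                if len(q) == len(pep) + diff and q.endswith(pep)
            )
            if candidates:
                chosen = candidates[0]
                break
        if chosen is not None:
            parent_of[pep] = chosen

    # Chain depth: root parents (not themselves annotated) start round 1.
    depth: dict[str, int] = {}

    def _round(pep: str) -> int:
        if pep not in depth:
            parent = parent_of[pep]
            depth[pep] = 1 + (_round(parent) if parent in parent_of else 0)
        return depth[pep]

    annotations = [
        TrimAnnotation(
            peptide=pep, parent=parent,
            kind="aminopeptidase" if len(parent) - len(pep) == 1
            else "dipeptidase",
            round=_round(pep),
        )
        for pep, parent in parent_of.items()
    ]
    annotations.sort(key=lambda a: (len(a.peptide), a.peptide))
    return annotations


def annotate_trimming(table, sequence_column: str = "__sequence__",
                      accession_column: str | None = None):
    """Append exopeptidase columns to an annotated table (in place).

    Peptides are only matched against peptides sharing the same anchor
    accession when ``accession_column`` is given — ragged ends across
    different proteins are chance suffix matches, not trimming.
    """
    import pandas as pd  # local import keeps module usable without pandas

    table["exopeptidase_kind"] = None
    table["exopeptidase_parent"] = None
    table["exopeptidase_round"] = None
    if accession_column is not None:
        groups = table.groupby(accession_column, dropna=True).groups.items()
    else:
        groups = [(None, table.index)]
    for _, idx in groups:
        seqs = table.loc[idx, sequence_column].dropna().tolist()
        by_pep = {a.peptide: a for a in infer_trimming(seqs)}
        for i in idx:
            ann = by_pep.get(table.at[i, sequence_column])
            if ann is not None:
                table.at[i, "exopeptidase_kind"] = ann.kind
                table.at[i, "exopeptidase_parent"] = ann.parent
                table.at[i, "exopeptidase_round"] = ann.round
    return table
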