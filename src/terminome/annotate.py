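"""Positional annotation of peptides against protein entries.

Maps each peptide to coordinates in its anchor protein (the first listed
accession), extracts the P4–P4' cleavage environment around the N-terminal
scissile bond, classifies the N-terminus (Met-intact, Met-removed, known
processing event, or internal neo-N-terminus), detects the N-terminal label
state from the modification tokens, and reports proteoform certainty (1/N
over the proteins containing the peptide).

Classification precedence (fixed so the categories partition):
start = 1 → met_intact; start = 2 → met_removed; start = feature.end + 1
for a signal/transit/propeptide feature → known_processing; else internal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .alphabet import DEFAULT_N_NONPRIME, DEFAULT_N_PRIME, PAD
from .ingest import Dialect, PeptideRecord
from .knowledgebase import ProteinEntry, lookup_known_cleavage

logger = logging.getLogger("terminome")

CATEGORIES = ("met_intact", "met_removed", "known_processing", "internal")
LABEL_STATES = ("labeled", "acetylated", "free")

#: Annotation columns appended to the input table, in order.
ANNOTATION_COLUMNS = [
    "annot_status", "anchor_accession", "start", "end", "occurrences", "p1",
    "cleavage_window",
    "category", "processing_kind", "label_state", "proteoform_certainty",
    "known_proteases", "gene", "description", "protein_length",
]


@dataclass(frozen=True)
class CleavageSite:
    accession: str
    p1: int
    window: str


def map_peptide(entry: ProteinEntry, sequence: str) -> tuple[int, int, int]:
    """Locate a peptide in a protein sequence (1-based inclusive coords).

    Returns (start, end, occurrences) for the first (lowest-start)
    occurrence; raises if the peptide is not a substring.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    idx = entry.sequence.find(sequence)
    if idx < 0:
        raise ValueError(
            f"peptide {sequence!r} not found in {entry.accession}")
    occurrences = len(re.findall(f"(?={re.escape(sequence)})", entry.sequence))
    start = idx + 1
    return start, start + len(sequence) - 1, occurrences


def extract_environment(
    entry: ProteinEntry,
    p1: int,
    n_nonprime: int = DEFAULT_N_NONPRIME,
    n_prime: int = DEFAULT_N_PRIME,
) -> CleavageSite:
    """Extract the P<n>..P1 | P1'..P<n'>' window around the scissile bond.

    Positions outside [1, length] are padded with '-'.
    """
    if not 1 <= p1 < entry.length:
        raise ValueError(
            f"{entry.accession}: p1={p1} out of range [1, {entry.length})")
    seq = entry.sequence
    chars = []
    for pos in range(p1 - n_nonprime + 1, p1 + n_prime + 1):
        chars.append(seq[pos - 1] if 1 <= pos <= entry.length else PAD)
    return CleavageSite(entry.accession, p1, "".join(chars))


def classify_terminus(start: int,
                      entry: ProteinEntry) -> tuple[str, str | None]:
    """Classify an N-terminus by its start position.

    Returns (category, processing_kind); processing_kind is set only for
    known_processing.
    """
    if not 1 <= start <= entry.length:
        raise ValueError(f"start={start} outside [1, {entry.length}]")
    if start == 1:
        return "met_intact", None
    if start == 2:
        return "met_removed", None
    for feat in entry.features:
        if start == feat.end + 1:
            return "known_processing", feat.kind
    return "internal", None


def detect_label_state(modifications: list[tuple[str, str]],
                       dialect: Dialect) -> str:
    """Classify the peptide N-terminus as labeled, acetylated or free.

    Patterns come from the dialect config, so other labeling chemistries
    (e.g. iTRAQ) can be supported by editing the config.
    """
    text = "; ".join(f"{name} [{site}]" for name, site in modifications)
    patterns = dialect.modification_patterns
    label_pat = patterns.get("nterm_label")
    acetyl_pat = patterns.get("acetyl")
    if label_pat and re.search(label_pat, text):
        return "labeled"
    if acetyl_pat and re.search(acetyl_pat, text):
        return "acetylated"
    return "free"


def proteoform_certainty(n_accessions: int) -> float:
    """Certainty of the proteoform assignment: 1/N over listed proteins."""
    if n_accessions < 1:
        raise ValueError("peptide must map to at least one accession")
    return float(Fraction(1, n_accessions))


def is_nterm_row(label_state: str, start: int | None) -> bool:
    """Whether a row represents a protein N-terminus.

    A peptide counts as an N-terminus when its alpha-amine is blocked
    (labeled or acetylated — the enrichment chemistry marks free N-termini)
    or when it starts at the natural terminus (position 1 or 2).
    """
    if label_state in ("labeled", "acetylated"):
        return True
    return start is not None and start <= 2


def annotate_table(
    records: list[PeptideRecord],
    table: pd.DataFrame,
    proteome: dict[str, ProteinEntry],
    dialect: Dialect,
    n_nonprime: int = DEFAULT_N_NONPRIME,
    n_prime: int = DEFAULT_N_PRIME,
    nterm_only: bool = False,
) -> pd.DataFrame:
    """Append annotation columns to the input table.

    Original columns are untouched and keep their order; one output row per
    kept record. Per-row failures (accession not in the proteome, peptide
    not found in the protein) are recorded in ``annot_status`` with empty
    positional columns, never raised.

    With ``nterm_only``, rows that are not N-termini (free alpha-amine and
    start > 2) are dropped after positional mapping, mirroring the option
    to skip non-terminal peptides for faster turnover.
    """
    rows = []
    for rec in records:
        ann: dict[str, object] = {c: None for c in ANNOTATION_COLUMNS}
        ann["label_state"] = detect_label_state(rec.modifications, dialect)
        ann["proteoform_certainty"] = proteoform_certainty(len(rec.accessions))
        anchor = rec.accessions[0]
        ann["anchor_accession"] = anchor
        entry = proteome.get(anchor)
        if entry is None:
            ann["annot_status"] = "accession_not_found"
            rows.append((rec, ann))
            continue
        ann["gene"] = entry.gene
        ann["description"] = entry.description
        ann["protein_length"] = entry.length
        try:
            start, end, occurrences = map_peptide(entry, rec.raw_sequence)
        except ValueError:
            ann["annot_status"] = "peptide_not_in_protein"
            rows.append((rec, ann))
            continue
        ann["annot_status"] = "ok"
        ann["start"], ann["end"], ann["occurrences"] = start, end, occurrences
        category, kind = classify_terminus(start, entry)
        ann["category"], ann["processing_kind"] = category, kind
        if start > 1:
            p1 = start - 1
            ann["p1"] = p1
            ann["cleavage_window"] = extract_environment(
                entry, p1, n_nonprime, n_prime).window
            known = lookup_known_cleavage(entry, p1)
            ann["known_proteases"] = "; ".join(
                f"{c.protease_name}({c.merops_id or c.source})" for c in known
            ) or None
        rows.append((rec, ann))

    if nterm_only:
        before = len(rows)
        rows = [(rec, ann) for rec, ann in rows
                if is_nterm_row(ann["label_state"], ann["start"])]
        logger.info("nterm_only: kept %d/%d rows", len(rows), before)

    out = table.iloc[[rec.source_row - 1 for rec, _ in rows]].reset_index(drop=True)
    for col in ANNOTATION_COLUMNS:
        out[col] = [ann[col] for _, ann in rows]
    atlas_keys = sorted({k for e in proteome.values() for k in e.atlas})
    if atlas_keys:
        for key in atlas_keys:
            out[f"atlas_{key}"] = [
                proteome[rec.accessions[0]].atlas.get(key)
                if rec.accessions[0] in proteome else None
                for rec, _ in rows]
    return out
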