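"""Reading and validation of peptide reports, condition files and protease lists.

Peptide reports are tab- or comma-separated exports from proteomics search
engines. Each supported engine is a *dialect*: a mapping from the semantic
fields the pipeline needs (sequence, modifications, accessions) to that
engine's column names, plus the modification-string patterns used to detect
N-terminal labels. Dialect vocabularies live in ``data/dialects.yaml`` and
are data, not code, so new engines can be added by editing the config.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .alphabet import AA_SET

logger = logging.getLogger("terminome")

MEROPS_ID_RE = re.compile(r"^[A-Za-z]\d+\.\d+$")

# "1xTMTpro [N-Term]; 2xCarbamidomethyl [C3; C8]" -> (name, [sites...])
_MOD_TOKEN_RE = re.compile(r"(?:\d+x)?([A-Za-z][\w+\-]*)\s*\[([^\]]*)\]")

SEMANTIC_FIELDS = ("sequence", "modifications", "accessions")


@dataclass(frozen=True)
class Dialect:
    """Column vocabulary and modification patterns of one search engine."""

    name: str
    column_map: dict[str, str]
    modification_patterns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in SEMANTIC_FIELDS if f not in self.column_map]
        if missing:
            raise ValueError(
                f"dialect {self.name!r} column_map missing semantic fields: {missing}"
            )


@dataclass
class PeptideRecord:
    """One identified peptide row from a search-engine report."""

    raw_sequence: str
    modifications: list[tuple[str, str]]
    accessions: list[str]
    quant: dict[str, object]
    source_row: int  # 1-based row in the input table


@dataclass
class ConditionDesign:
    """Condition names mapped to quant-column substrings, then to columns."""

    conditions: dict[str, list[str]]
    resolved: dict[str, list[str]] = field(default_factory=dict)


def load_dialects(path: str | Path | None = None) -> dict[str, Dialect]:
    """Load dialect definitions from YAML (bundled config by default)."""
    if path is None:
        text = (resources.files("terminome") / "data" / "dialects.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    dialects = {}
    for name, entry in raw.items():
        dialects[name] = Dialect(
            name=name,
            column_map=dict(entry["columns"]),
            modification_patterns=dict(entry.get("patterns", {})),
        )
    return dialects


def parse_modifications(cell: object) -> list[tuple[str, str]]:
    """Parse a modification string into (name, site) tokens.

    Handles the common "1xTMTpro [N-Term]; 2xCarbamidomethyl [C3; C8]"
    convention; each site inside a bracket group yields its own token.
    """
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell)
    tokens: list[tuple[str, str]] = []
    for m in _MOD_TOKEN_RE.finditer(text):
        name, sites = m.group(1), m.group(2)
        for site in sites.split(";"):
            tokens.append((name, site.strip()))
    return tokens


def split_accessions(cell: object) -> list[str]:
    """Split a multi-accession cell on ';' preserving order."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    return [a.strip() for a in str(cell).split(";") if a.strip()]


def _sniff_delimiter(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "\t"
    if suffix == ".csv":
        return ","
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide report table with delimiter sniffing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peptide report not found: {path}")
    sep = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), [])
    seen: set[str] = set()
    dupes = sorted({c for c in header if c in seen or seen.add(c)})
    if dupes:
        raise ValueError(f"duplicate header names in {path}: {dupes}")
    return pd.read_csv(path, sep=sep, dtype=str,
                       keep_default_na=True, na_values=[""])


def infer_dialect(columns: list[str],
                  dialects: dict[str, Dialect] | None = None) -> Dialect:
    """Infer the search-engine dialect from which column-name set is present."""
    dialects = dialects or load_dialects()
    colset = set(columns)
    matches = [d for d in dialects.values()
               if all(c in colset for c in d.column_map.values())]
    if not matches:
        # Report, for the closest dialect, which semantic columns are missing.
        best = max(dialects.values(),
                   key=lambda d: sum(c in colset for c in d.column_map.values()))
        missing = [sem for sem, c in best.column_map.items() if c not in colset]
        raise ValueError(
            "no known dialect matches the table header; closest is "
            f"{best.name!r}, missing semantic columns: {missing}"
        )
    if len(matches) > 1:
        logger.warning("multiple dialects match (%s); using %s",
                       [d.name for d in matches], matches[0].name)
    logger.info("inferred dialect: %s", matches[0].name)
    return matches[0]


def read_peptide_report(
    path: str | Path,
    dialect: Dialect | str | None = None,
    dialects: dict[str, Dialect] | None = None,
) -> tuple[list[PeptideRecord], Dialect, pd.DataFrame]:
    """Read a peptide report into records.

    Returns the records, the (possibly inferred) dialect, and the raw table
    so downstream stages can append annotation columns in place.
    """
    dialects = dialects or load_dialects()
    df = read_table(path)
    if dialect is None or dialect == "auto":
        dialect = infer_dialect(list(df.columns), dialects)
    elif isinstance(dialect, str):
        if dialect not in dialects:
            raise ValueError(f"unknown dialect {dialect!r}; "
                             f"known: {sorted(dialects)}")
        dialect = dialects[dialect]
    missing = [c for c in dialect.column_map.values() if c not in df.columns]
    if missing:
        raise ValueError(f"dialect {dialect.name!r} expects columns {missing} "
                         "absent from the table")

    seq_col = dialect.column_map["sequence"]
    mod_col = dialect.column_map["modifications"]
    acc_col = dialect.column_map["accessions"]
    semantic = {seq_col, mod_col, acc_col}
    other_cols = [c for c in df.columns if c not in semantic]

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        seq = row_d.get(seq_col)
        records.append(PeptideRecord(
            raw_sequence="" if pd.isna(seq) else str(seq).strip(),
            modifications=parse_modifications(row_d.get(mod_col)),
            accessions=split_accessions(row_d.get(acc_col)),
            quant={c: row_d[c] for c in other_cols},
            source_row=i,
        ))
    logger.info("read %d peptide rows from %s (dialect %s)",
                len(records), path, dialect.name)
    return records, dialect, df


def validate_records(
    records: list[PeptideRecord],
) -> tuple[list[PeptideRecord], list[tuple[int, str]]]:
    """Partition records into kept and dropped-with-reason.

    Rows with an empty sequence, empty accession list, or sequence
    characters outside the 20-letter alphabet are dropped, never raised on.
    """
    kept: list[PeptideRecord] = []
    dropped: list[tuple[int, str]] = []
    for rec in records:
        if not rec.raw_sequence:
            dropped.append((rec.source_row, "empty_sequence"))
        elif not rec.accessions:
            dropped.append((rec.source_row, "empty_accession"))
        elif not set(rec.raw_sequence) <= AA_SET:
            dropped.append((rec.source_row, "invalid_alphabet"))
        else:
            kept.append(rec)
    if dropped:
        logger.info("validation dropped %d/%d rows", len(dropped), len(records))
    return kept, dropped


def read_condition_file(path: str | Path) -> ConditionDesign:
    """Parse a condition file: one condition per line, name then substrings."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"condition file not found: {path}")
    conditions: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        name, substrings = parts[0], parts[1:]
        if not substrings:
            raise ValueError(
                f"{path}:{lineno}: condition {name!r} has no column substrings")
        if name in conditions:
            raise ValueError(f"{path}:{lineno}: duplicate condition {name!r}")
        conditions[name] = substrings
    if not conditions:
        raise ValueError(f"condition file {path} has no conditions")
    return ConditionDesign(conditions=conditions)


def match_quant_columns(design: ConditionDesign,
                        columns: list[str]) -> ConditionDesign:
    """Resolve each condition's substrings to concrete quant column names.

    Matching is plain substring containment (not regex). A substring must
    match at least one column, and no column may be claimed by two
    conditions. Resolution is independent of input column order (columns
    are reported in their table order, but the assignment itself depends
    only on the column names).
    """
    claimed: dict[str, str] = {}
    resolved: dict[str, list[str]] = {}
    for cond, substrings in design.conditions.items():
        cols: list[str] = []
        for sub in substrings:
            hits = [c for c in columns if sub in c]
            if not hits:
                raise ValueError(
                    f"condition {cond!r}: substring {sub!r} matches no column")
            for c in hits:
                if claimed.get(c, cond) != cond:
                    raise ValueError(
                        f"column {c!r} claimed by both {claimed[c]!r} and "
                        f"{cond!r} (ambiguous substring {sub!r})")
                claimed[c] = cond
                if c not in cols:
                    cols.append(c)
        resolved[cond] = cols
    logger.info("resolved quant columns: %s",
                {k: len(v) for k, v in resolved.items()})
    return ConditionDesign(conditions=dict(design.conditions), resolved=resolved)


def read_protease_list(path: str | Path) -> list[str]:
    """Read a protease list: one MEROPS identifier (e.g. M10.004) per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"protease list not found: {path}")
    ids = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        if not MEROPS_ID_RE.match(token):
            raise ValueError(
                f"{path}:{lineno}: malformed MEROPS identifier {token!r}")
        ids.append(token)
    return ids
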