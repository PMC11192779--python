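"""Offline, file-backed protein knowledgebase.

Replaces live database querying with local snapshot files:

* protein sequences — FASTA (UniProt-style ``sp|ACC|NAME`` or bare headers);
* processing features (signal/transit/propeptide) — TSV
  ``accession  kind  start  end`` (1-based inclusive);
* known cleavage events — TSV
  ``accession  p1  protease_name  merops_id  source``;
* tissue/ontology annotation (atlas-like) — optional TSV keyed by accession;
* MEROPS substrate windows — TSV ``merops_id  window  [substrate_accession]``;
* amino-acid background frequencies — TSV ``amino_acid  frequency``.

A live-API client could be plugged in behind :func:`load_proteome`'s return
contract (a mapping accession → :class:`ProteinEntry`); nothing downstream
knows where entries came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alphabet import AA_SET, PAD

logger = logging.getLogger("terminome")

FEATURE_KINDS = ("signal_peptide", "transit_peptide", "propeptide")


@dataclass(frozen=True)
class ProcessingFeature:
    kind: str  # signal_peptide | transit_peptide | propeptide
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature bounds {self.start}..{self.end}")


@dataclass(frozen=True)
class KnownCleavage:
    p1: int
    protease_name: str
    source: str  # uniprot | merops
    merops_id: str | None = None


@dataclass
class ProteinEntry:
    accession: str
    sequence: str
    gene: str = ""
    description: str = ""
    features: list[ProcessingFeature] = field(default_factory=list)
    known_cleavages: list[KnownCleavage] = field(default_factory=list)
    atlas: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SubstrateWindow:
    """A MEROPS substrate cleavage window centered on the scissile bond."""

    merops_id: str
    window: str
    substrate_accession: str | None = None


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background amino-acid distribution q_a used for log-odds weights."""

    freq: dict[str, float]
    source_tag: str = "unspecified"

    def __post_init__(self) -> None:
        if set(self.freq) != AA_SET:
            raise ValueError("background must cover exactly the 20 amino acids")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(v <= 0 for v in self.freq.values()):
            raise ValueError("background frequencies must all be > 0")

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(freq={aa: 1 / 20 for aa in AA_SET}, source_tag="uniform")


def _parse_fasta_accession(header_id: str) -> str:
    # UniProt convention sp|P12345|NAME; otherwise the bare id.
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return parts[0]


def load_proteome(
    fasta_path: str | Path,
    features_path: str | Path | None = None,
    cleavages_path: str | Path | None = None,
    atlas_path: str | Path | None = None,
) -> dict[str, ProteinEntry]:
    """Load a proteome snapshot into accession-keyed entries.

    Feature bounds are validated against sequence length; a feature
    referencing an unknown accession or exceeding the sequence is an error
    (reported with the accession). Entries without features get empty lists.
    """
    entries: dict[str, ProteinEntry] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = _parse_fasta_accession(rec.id)
        if acc in entries:
            raise ValueError(f"accession collision in FASTA: {acc}")
        desc_parts = rec.description.split(maxsplit=1)
        description = desc_parts[1] if len(desc_parts) > 1 else ""
        gene = ""
        if "GN=" in description:
            gene = description.split("GN=")[1].split()[0]
        entries[acc] = ProteinEntry(
            accession=acc, sequence=str(rec.seq).upper(),
            gene=gene, description=description,
        )

    if features_path is not None:
        feats = pd.read_csv(features_path, sep="\t", dtype=str)
        for row in feats.itertuples(index=False):
            acc = row.accession
            if acc not in entries:
                raise ValueError(f"features file references unknown accession {acc}")
            start, end = int(row.start), int(row.end)
            entry = entries[acc]
            if not 1 <= start <= end <= entry.length:
                raise ValueError(
                    f"{acc}: feature {row.kind} {start}..{end} out_of_bounds "
                    f"for length {entry.length}")
            entry.features.append(ProcessingFeature(row.kind, start, end))

    if cleavages_path is not None:
        clv = pd.read_csv(cleavages_path, sep="\t", dtype=str)
        for row in clv.itertuples(index=False):
            acc = row.accession
            if acc not in entries:
                raise ValueError(f"cleavage file references unknown accession {acc}")
            p1 = int(row.p1)
            entry = entries[acc]
            if not 1 <= p1 < entry.length:
                raise ValueError(f"{acc}: cleavage p1={p1} out_of_bounds")
            merops_id = getattr(row, "merops_id", None)
            if merops_id is not None and pd.isna(merops_id):
                merops_id = None
            entry.known_cleavages.append(KnownCleavage(
                p1=p1, protease_name=row.protease_name,
                source=row.source, merops_id=merops_id))

    if atlas_path is not None:
        atlas = pd.read_csv(atlas_path, sep="\t", dtype=str)
        for row in atlas.itertuples(index=False):
            d = row._asdict()
            acc = d.pop("accession")
            if acc in entries:
                entries[acc].atlas = {k: v for k, v in d.items()
                                      if not pd.isna(v)}

    logger.info("loaded proteome: %d entries from %s", len(entries), fasta_path)
    return entries


def load_merops_substrates(
    path: str | Path,
    protease_ids: list[str],
    window_length: int = 8,
) -> dict[str, list[SubstrateWindow]]:
    """Load substrate windows for the requested proteases only.

    Windows are uppercased; windows of the wrong length or with characters
    outside the alphabet (plus '-' padding) are dropped with a log message.
    A requested protease with zero usable windows yields an empty list and
    a warning — it is later skipped from scoring.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    wanted = set(protease_ids)
    out: dict[str, list[SubstrateWindow]] = {pid: [] for pid in protease_ids}
    allowed = AA_SET | {PAD}
    for row in df.itertuples(index=False):
        pid = row.merops_id
        if pid not in wanted:
            continue
        window = str(row.window).upper()
        if len(window) != window_length:
            logger.info("dropping %s window %r: wrong length (%d != %d)",
                        pid, window, len(window), window_length)
            continue
        if not set(window) <= allowed:
            logger.info("dropping %s window %r: invalid characters", pid, window)
            continue
        sub_acc = getattr(row, "substrate_accession", None)
        if sub_acc is not None and pd.isna(sub_acc):
            sub_acc = None
        out[pid].append(SubstrateWindow(pid, window, sub_acc))
    for pid, windows in out.items():
        if not windows:
            logger.warning("protease %s has no usable substrate windows; "
                           "it will be skipped from scoring", pid)
    return out


def lookup_known_cleavage(entry: ProteinEntry, p1: int) -> list[KnownCleavage]:
    """All known cleavage records at exactly this P1 position."""
    if not 1 <= p1 < entry.length:
        raise ValueError(
            f"{entry.accession}: p1={p1} out of range [1, {entry.length})")
    return [c for c in entry.known_cleavages if c.p1 == p1]


def load_background_frequencies(
    path: str | Path | None = None,
    source_tag: str | None = None,
) -> BackgroundFrequencies:
    """Load a background-frequency table (bundled snapshot by default).

    The bundled table is a stand-in snapshot of the average amino-acid
    composition of a large sequence database; frequencies are renormalized
    to sum to exactly 1 before validation.
    """
    if path is None:
        with resources.as_file(
            resources.files("terminome") / "data" / "background_frequencies.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
        tag = source_tag or "bundled-database-composition-snapshot"
    else:
        df = pd.read_csv(path, sep="\t")
        tag = source_tag or str(path)
    freq = {str(r.amino_acid): float(r.frequency)
            for r in df.itertuples(index=False)}
    total = sum(freq.values())
    if not 0.9 < total < 1.1:
        raise ValueError(f"background frequencies sum to {total}; not a "
                         "probability distribution")
    freq = {aa: v / total for aa, v in freq.items()}
    return BackgroundFrequencies(freq=freq, source_tag=tag)
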