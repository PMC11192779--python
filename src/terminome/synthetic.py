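"""Synthetic terminomics experiment generator.

Produces a complete, fully specified experiment — proteome FASTA,
processing-feature and known-cleavage tables, MEROPS-style substrate
windows, a quantified peptide report in a chosen search-engine dialect, a
condition file, and a ground-truth manifest — so the entire pipeline is
testable offline.

The default spec emulates a protease-treatment experiment: a protease with
a defined specificity motif cleaves a set of substrate proteins; the
resulting labeled neo-N-terminal peptides are more abundant in the treated
condition by a configurable log2 fold change, on top of multiplicative
(log-normal) replicate noise, which mirrors how reporter-ion and precursor
intensities behave. Background peptides (natural N-termini, known
processing products and unaffected internal peptides) carry no effect.

The manifest records every row's true coordinates, category, label state
and substrate status, making it the oracle for annotation round-trips,
category pie counts, and substrate-recovery checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS
from .ingest import load_dialects
from .knowledgebase import load_background_frequencies

logger = logging.getLogger("terminome")

WINDOW_POSITIONS = ["P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'"]

#: Default protease specificity motif: strong Pro preference in P3 and a
#: small-hydrophobic preference in P1', with background elsewhere —
#: the classic matrix-metalloproteinase-like cleavage signature.
DEFAULT_MOTIF: dict[str, dict[str, float]] = {
    "P3": {"P": 0.70},
    "P1": {"A": 0.25, "G": 0.20},
    "P1'": {"L": 0.45, "I": 0.20, "V": 0.15},
    "P2'": {"L": 0.15, "I": 0.15},
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic experiment (the study conditions)."""

    seed: int = 0
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (150, 400)
    protease_motif: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIF.items()})
    merops_id: str = "M10.004"
    protease_name: str = "synthetic-MMP-like"
    n_true_cleavages: int = 30
    n_background_peptides: int = 200
    n_merops_substrates: int = 40
    n_known_true_cleavages: int = 0  # true sites pre-attributed to the protease
    conditions: dict[str, int] = field(
        default_factory=lambda: {"treat": 5, "ctrl": 5})
    effect_log2fc: float = 2.0
    noise_sd: float = 0.3        # log2-scale replicate sd
    missing_rate: float = 0.02
    label: str = "tmt"           # tmt | dimethyl
    dialect: str = "proteome_discoverer"
    peptide_length_range: tuple[int, int] = (8, 18)
    signal_peptide_fraction: float = 0.3

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.conditions.values()):
            raise ValueError("every condition needs at least 2 replicates")
        for pos, dist in self.protease_motif.items():
            if pos not in WINDOW_POSITIONS:
                raise ValueError(f"unknown motif position {pos!r}")
            if not 0 <= sum(dist.values()) <= 1 + 1e-9:
                raise ValueError(f"motif at {pos} has probabilities "
                                 "summing above 1")


@dataclass
class Fixture:
    """Paths of the generated files plus the in-memory ground truth."""

    directory: Path
    proteome_fasta: Path
    features_tsv: Path
    cleavages_tsv: Path
    merops_tsv: Path
    report: Path
    condition_file: Path
    manifest_path: Path
    manifest: dict


def motif_matrix(spec: FixtureSpec,
                 background: dict[str, float]) -> np.ndarray:
    """(8, 20) per-position residue distribution of the true motif.

    Positions absent from the motif use the background; at motif positions
    the remaining mass is distributed over unnamed residues
    proportionally to the background.
    """
    q = np.array([background[a] for a in AMINO_ACIDS])
    mat = np.tile(q, (len(WINDOW_POSITIONS), 1))
    for i, pos in enumerate(WINDOW_POSITIONS):
        dist = spec.protease_motif.get(pos)
        if not dist:
            continue
        row = np.zeros(20)
        named = 0.0
        for aa, p in dist.items():
            row[AMINO_ACIDS.index(aa)] = p
            named += p
        rest_idx = [j for j, aa in enumerate(AMINO_ACIDS) if aa not in dist]
        rest_q = q[rest_idx]
        row[rest_idx] = (1.0 - named) * rest_q / rest_q.sum()
        mat[i] = row
    return mat / mat.sum(axis=1, keepdims=True)


def _sample_window(rng: np.random.Generator, motif: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[rng.choice(20, p=motif[i])]
                   for i in range(motif.shape[0]))


def _label_mods(spec: FixtureSpec, state: str, rng: np.random.Generator,
                sequence: str) -> str:
    name = "TMTpro" if spec.label == "tmt" else "Dimethyl"
    if state == "labeled":
        mods = [f"1x{name} [N-Term]"]
        k_pos = [i + 1 for i, aa in enumerate(sequence) if aa == "K"]
        if k_pos:
            mods.append(f"1x{name} [K{k_pos[0]}]")
        return "; ".join(mods)
    if state == "acetylated":
        return "1xAcetyl [N-Term]"
    c_pos = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    if c_pos and rng.random() < 0.5:
        return f"1xCarbamidomethyl [C{c_pos[0]}]"
    return ""


def generate_experiment(spec: FixtureSpec,
                        outdir: str | Path) -> Fixture:
    """Generate and write a complete synthetic experiment.

    Deterministic in ``spec.seed``: identical specs produce byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    background = load_background_frequencies().freq
    q = np.array([background[a] for a in AMINO_ACIDS])
    motif = motif_matrix(spec, background)

    # --- proteome -----------------------------------------------------
    proteins: dict[str, list[str]] = {}
    features: list[dict] = []
    lo, hi = spec.protein_length_range
    for k in range(spec.n_proteins):
        acc = f"P{k + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = ["M"] + [AMINO_ACIDS[i]
                       for i in rng.choice(20, size=length - 1, p=q)]
        proteins[acc] = seq
        if rng.random() < spec.signal_peptide_fraction:
            features.append({"accession": acc, "kind": "signal_peptide",
                             "start": 1, "end": 22})
    accessions = list(proteins)
    sp_end = {f["accession"]: f["end"] for f in features}

    # --- true cleavage sites ------------------------------------------
    # Motif windows are embedded into the protein sequence at the chosen
    # P1 so that the emitted neo-N-terminal peptide is a genuine substring.
    used: dict[str, list[int]] = {acc: [] for acc in accessions}
    true_sites: list[tuple[str, int]] = []
    while len(true_sites) < spec.n_true_cleavages:
        acc = accessions[rng.integers(len(accessions))]
        seq = proteins[acc]
        if len(seq) < 80:
            continue
        p1 = int(rng.integers(30, len(seq) - 30))
        if any(abs(p1 - other) < 30 for other in used[acc]):
            continue
        window = _sample_window(rng, motif)
        for offset, ch in enumerate(window):        # P4..P4' = p1-3 .. p1+4
            seq[p1 - 4 + offset] = ch
        used[acc].append(p1)
        true_sites.append((acc, p1))

    sequences = {acc: "".join(seq) for acc, seq in proteins.items()}

    plen_lo, plen_hi = spec.peptide_length_range
    rows: list[dict] = []

    def add_row(acc, start, length, state, is_true, extra_accs=()):
        seq = sequences[acc]
        pep = seq[start - 1:start - 1 + length]
        actual_start = seq.find(pep) + 1  # first occurrence is what the
        p1 = actual_start - 1 if actual_start > 1 else None  # pipeline reports
        if actual_start == 1:
            category = "met_intact"
        elif actual_start == 2:
            category = "met_removed"
        elif sp_end.get(acc) is not None and actual_start == sp_end[acc] + 1:
            category = "known_processing"
        else:
            category = "internal"
        rows.append({
            "sequence": pep,
            "accession_list": [acc, *extra_accs],
            "label_state": state,
            "start": actual_start,
            "end": actual_start + length - 1,
            "p1": p1,
            "category": category,
            "is_true_substrate": bool(is_true),
        })

    for acc, p1 in true_sites:
        length = int(rng.integers(plen_lo, plen_hi + 1))
        length = min(length, len(sequences[acc]) - p1)
        add_row(acc, p1 + 1, length, "labeled", True)

    # --- background peptides ------------------------------------------
    kinds = rng.choice(
        ["met_intact", "met_removed", "signal", "internal_labeled",
         "internal_free", "acetylated_nterm"],
        size=spec.n_background_peptides,
        p=[0.08, 0.08, 0.10, 0.24, 0.42, 0.08])
    sp_accessions = sorted(sp_end)
    for kind in kinds:
        length = int(rng.integers(plen_lo, plen_hi + 1))
        if kind == "signal" and not sp_accessions:
            kind = "internal_free"
        if kind in ("met_intact", "met_removed", "acetylated_nterm", "signal"):
            if kind == "signal":
                acc = sp_accessions[int(rng.integers(len(sp_accessions)))]
                start, state = sp_end[acc] + 1, "labeled"
            else:
                acc = accessions[int(rng.integers(len(accessions)))]
                start = 2 if kind == "met_removed" else 1
                state = "acetylated" if kind == "acetylated_nterm" else "labeled"
            add_row(acc, start, length, state, False)
            continue
        # internal background peptide away from any embedded true site
        while True:
            acc = accessions[int(rng.integers(len(accessions)))]
            seq = sequences[acc]
            start = int(rng.integers(30, len(seq) - plen_hi))
            if not any(abs(start - 1 - p) < 30 for p in used[acc]):
                break
        state = "labeled" if kind == "internal_labeled" else "free"
        extra = ()
        if kind == "internal_free" and rng.random() < 0.1:
            extra = (accessions[int(rng.integers(len(accessions)))],)
        add_row(acc, start, length, state, False, extra)

    # --- quantification ------------------------------------------------
    cond_names = list(spec.conditions)
    quant_cols = [f"Abundance {c}_{r + 1}"
                  for c in cond_names for r in range(spec.conditions[c])]
    effect_cond = cond_names[0]  # first-listed condition carries the effect
    for row in rows:
        base = rng.normal(20.0, 1.5)
        values = {}
        for c in cond_names:
            shift = spec.effect_log2fc if (
                row["is_true_substrate"] and c == effect_cond) else 0.0
            for r in range(spec.conditions[c]):
                col = f"Abundance {c}_{r + 1}"
                if rng.random() < spec.missing_rate:
                    values[col] = ""
                else:
                    values[col] = f"{2 ** (base + shift + rng.normal(0, spec.noise_sd)):.1f}"
        row["quant"] = values

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    # --- write files ----------------------------------------------------
    fasta = outdir / "proteome.fasta"
    with open(fasta, "w") as fh:
        for i, (acc, seq) in enumerate(sequences.items(), start=1):
            fh.write(f">sp|{acc}|SYN{i} Synthetic protein {i} GN=SYNG{i}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")

    features_tsv = outdir / "features.tsv"
    pd.DataFrame(features, columns=["accession", "kind", "start", "end"]) \
        .to_csv(features_tsv, sep="\t", index=False)

    known = []
    for acc, p1 in true_sites[:spec.n_known_true_cleavages]:
        known.append({"accession": acc, "p1": p1,
                      "protease_name": spec.protease_name,
                      "merops_id": spec.merops_id, "source": "merops"})
    cleavages_tsv = outdir / "known_cleavages.tsv"
    pd.DataFrame(known, columns=["accession", "p1", "protease_name",
                                 "merops_id", "source"]) \
        .to_csv(cleavages_tsv, sep="\t", index=False)

    merops_tsv = outdir / "merops_substrates.tsv"
    pd.DataFrame({
        "merops_id": spec.merops_id,
        "window": [_sample_window(rng, motif)
                   for _ in range(spec.n_merops_substrates)],
        "substrate_accession": [f"Q{j + 1:05d}"
                                for j in range(spec.n_merops_substrates)],
    }).to_csv(merops_tsv, sep="\t", index=False)

    dialect = load_dialects()[spec.dialect]
    seq_col = dialect.column_map["sequence"]
    mod_col = dialect.column_map["modifications"]
    acc_col = dialect.column_map["accessions"]
    report_rows = []
    for row in rows:
        report_rows.append({
            seq_col: row["sequence"],
            mod_col: _label_mods(spec, row["label_state"], rng,
                                 row["sequence"]),
            acc_col: "; ".join(row["accession_list"]),
            **row["quant"],
        })
    report = outdir / "peptide_report.tsv"
    pd.DataFrame(report_rows, columns=[seq_col, mod_col, acc_col,
                                       *quant_cols]) \
        .to_csv(report, sep="\t", index=False)

    condition_file = outdir / "conditions.txt"
    with open(condition_file, "w") as fh:
        for c in cond_names:
            subs = " ".join(f"{c}_{r + 1}" for r in range(spec.conditions[c]))
            fh.write(f"{c} {subs}\n")

    manifest = {
        "spec": {**asdict(spec),
                 "protein_length_range": list(spec.protein_length_range),
                 "peptide_length_range": list(spec.peptide_length_range)},
        "quant_columns": {c: [f"Abundance {c}_{r + 1}"
                              for r in range(spec.conditions[c])]
                          for c in cond_names},
        "n_rows": len(rows),
        "true_sites": [{"accession": a, "p1": p} for a, p in true_sites],
        "known_true_sites": [{"accession": a, "p1": p}
                             for a, p in true_sites[:spec.n_known_true_cleavages]],
        "rows": [{k: v for k, v in row.items() if k != "quant"}
                 for row in rows],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    logger.info("generated fixture: %d proteins, %d rows (%d true substrates)",
                spec.n_proteins, len(rows), spec.n_true_cleavages)
    return Fixture(outdir, fasta, features_tsv, cleavages_tsv, merops_tsv,
                   report, condition_file, manifest_path, manifest)
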