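"""End-to-end pipeline: ingest → annotate → trim inference → specificity →
statistics → logos and figures → annotated output table.

Stages degrade gracefully: statistics and differential figures need a
condition file, specificity scoring needs a protease list plus a substrate
snapshot, structural annotation needs a model folder — each stage that
lacks its inputs is skipped with a logged reason, and the run still
produces the annotated table.

Determinism contract: identical config + inputs give a byte-identical
``annotated.tsv`` (all stochastic steps take the config seed; worker count
only parallelizes pure per-row maps and never changes output).
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotate as annotate_mod
from . import report_viz, stats
from .exopeptidase import annotate_trimming
from .ingest import (ConditionDesign, match_quant_columns, read_condition_file,
                     read_peptide_report, read_protease_list, validate_records)
from .knowledgebase import (load_background_frequencies, load_merops_substrates,
                            load_proteome)
from .logos import build_logo_matrices, matrices_to_tsv, render_logo
from .specificity import build_pssm, score_table
from .structure import BiotiteBackend, annotate_structure, find_model

logger = logging.getLogger("terminome")


@dataclass
class RunConfig:
    """All pipeline options (CLI flags override these defaults)."""

    input: str
    proteome_fasta: str
    outdir: str
    dialect: str | None = None            # None/auto -> infer
    features: str | None = None
    known_cleavages: str | None = None
    atlas: str | None = None
    conditions: str | None = None
    proteases: str | None = None
    merops_substrates: str | None = None
    background_frequencies: str | None = None
    structures: str | None = None
    n_nonprime: int = 4
    n_prime: int = 4
    nterm_only: bool = False
    test_method: str = "auto"             # ttest | anova | pairwise_ttest
    mt_method: str = "fdr_bh"
    alpha: float = 0.05
    p_cutoff: float = 0.05
    log2fc_cutoff: float = 1.0
    tail_fraction: float = 0.05
    fill_missing: str | None = None       # "drop" or a numeric string
    pseudocounts: bool = False
    pseudocount_weight: float = 5.0
    figures: bool = True
    logo_kinds: tuple[str, ...] = ("probability", "pssm", "shannon", "kl")
    figure_ext: str = "svg"
    seed: int = 0
    workers: int = 1


def _setup_logging(outdir: Path) -> None:
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in [h for h in logger.handlers
                    if isinstance(h, logging.FileHandler)]:
        handler.close()
        logger.removeHandler(handler)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("pipeline start: %s", config.input)

    records, dialect, table = read_peptide_report(
        config.input, dialect=config.dialect or "auto")
    kept, dropped = validate_records(records)
    if not kept:
        raise ValueError("no valid peptide rows after validation")
    for row, reason in dropped:
        logger.info("dropped row %d: %s", row, reason)

    proteome = load_proteome(config.proteome_fasta, config.features,
                             config.known_cleavages, config.atlas)
    annotated = annotate_mod.annotate_table(
        kept, table, proteome, dialect,
        n_nonprime=config.n_nonprime, n_prime=config.n_prime,
        nterm_only=config.nterm_only)
    logger.info("annotated %d rows (%d mapped)", len(annotated),
                int((annotated["annot_status"] == "ok").sum()))

    seq_col = dialect.column_map["sequence"]
    annotated = annotate_trimming(annotated, sequence_column=seq_col,
                                  accession_column="anchor_accession")

    background = load_background_frequencies(config.background_frequencies)

    models = []
    if config.proteases and config.merops_substrates:
        protease_ids = read_protease_list(config.proteases)
        window_length = config.n_nonprime + config.n_prime
        substrates = load_merops_substrates(
            config.merops_substrates, protease_ids,
            window_length=window_length)
        for pid, windows in substrates.items():
            if not windows:
                continue
            model = build_pssm(
                windows, background,
                pseudocount_weight=config.pseudocount_weight,
                use_blosum_pseudocounts=config.pseudocounts,
                merops_id=pid)
            model.to_tsv(outdir / f"pssm_{pid}.tsv")
            models.append(model)
        if models:
            annotated = score_table(models, annotated)
    elif config.proteases:
        logger.info("protease list given without a substrate snapshot; "
                    "specificity scoring skipped")

    design: ConditionDesign | None = None
    if config.conditions:
        design = read_condition_file(config.conditions)
        design = match_quant_columns(design, list(annotated.columns))
        annotated = stats.run_statistics(
            annotated, design,
            method=config.test_method, mt_method=config.mt_method,
            p_cutoff=config.p_cutoff, log2fc_cutoff=config.log2fc_cutoff,
            tail_fraction=config.tail_fraction,
            fill_policy=config.fill_missing)
    else:
        logger.info("no condition file: statistics and differential "
                    "figures skipped")

    if config.structures:
        annotated = _structure_stage(annotated, proteome, config)

    manifest = report_viz.FigureManifest()
    figdir = outdir / "figures"
    if config.figures:
        summary = report_viz.figure_counts_and_pies(
            annotated, dialect, figdir, manifest, ext=config.figure_ext)
        logger.info("dataset counts: %s", summary["counts"])
        if design is not None:
            report_viz.figure_differential(
                annotated, design, figdir, manifest,
                p_cutoff=config.p_cutoff, log2fc_cutoff=config.log2fc_cutoff,
                seed=config.seed, ext=config.figure_ext)
            pairs = stats.condition_pairs(design)
            fc_col = (f"log2_fc_{pairs[0][0]}_vs_{pairs[0][1]}"
                      if pairs else None)
            report_viz.figure_protein_views(
                annotated, proteome, figdir, manifest,
                fc_column=fc_col, ext=config.figure_ext)
            _logo_stage(annotated, design, background, figdir, manifest,
                        config)
            for pair in pairs:
                report_viz.export_enrichment_inputs(
                    annotated, pair, outdir,
                    p_cutoff=config.p_cutoff,
                    log2fc_cutoff=config.log2fc_cutoff)
        else:
            report_viz.figure_protein_views(
                annotated, proteome, figdir, manifest, ext=config.figure_ext)
            manifest.skip("volcano", "volcano", "no condition file")
    manifest.to_json(outdir / "manifest.json")

    out_tsv = outdir / "annotated.tsv"
    annotated.to_csv(out_tsv, sep="\t", index=False, float_format="%.6g")
    (outdir / "run_config.json").write_text(
        json.dumps(asdict(config), indent=1, default=str))
    logger.info("pipeline done: %s", out_tsv)
    return outdir


def _structure_stage(annotated: pd.DataFrame,
                     proteome, config: RunConfig) -> pd.DataFrame:
    """Optional structural annotation; pure per-row map, parallelizable."""
    backend = BiotiteBackend()

    def one(row_idx):
        row = annotated.loc[row_idx]
        acc, p1 = row["anchor_accession"], row["p1"]
        if pd.isna(p1) or acc not in proteome:
            return None
        model = find_model(config.structures, acc)
        if model is None:
            return None
        try:
            return annotate_structure(
                proteome[acc], int(p1), model, backend,
                n_nonprime=config.n_nonprime, n_prime=config.n_prime)
        except Exception as exc:
            logger.info("structure annotation failed for %s p1=%s: %s",
                        acc, p1, exc)
            return None

    indices = list(annotated.index)
    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(one, indices))
    else:
        results = [one(i) for i in indices]
    annotated["secondary_structure"] = [
        r.ss_string if r else None for r in results]
    annotated["p1_sasa"] = [r.sasa if r else None for r in results]
    n_done = sum(r is not None for r in results)
    logger.info("structural annotation: %d/%d sites", n_done, len(results))
    return annotated


def _logo_stage(annotated, design, background, figdir, manifest,
                config: RunConfig) -> None:
    """Logos from significant rows (volcano OR tail label) per pair."""
    for a, b in stats.condition_pairs(design):
        pair = f"{a}_vs_{b}"
        volcano_col = f"volcano_significant_{pair}"
        tail_col = f"tail_label_{pair}"
        mask = pd.Series(False, index=annotated.index)
        if volcano_col in annotated:
            mask |= annotated[volcano_col].fillna(False).astype(bool)
        if tail_col in annotated:
            mask |= annotated[tail_col].isin(
                ["significant_high", "significant_low"])
        windows = [w for w in annotated.loc[mask, "cleavage_window"]
                   if isinstance(w, str) and w]
        if not windows:
            for kind in config.logo_kinds:
                manifest.skip(f"logo_{kind}_{pair}", "logo",
                              "no significant cleavage windows")
            continue
        matrices = build_logo_matrices(
            windows, background,
            pseudocounts=config.pseudocounts,
            pseudocount_weight=config.pseudocount_weight,
            method_tag=f"{pair}, volcano|tail significant")
        for kind in config.logo_kinds:
            path = figdir / f"logo_{kind}_{pair}.{config.figure_ext}"
            render_logo(matrices, kind, path)
            matrices_to_tsv(matrices, kind,
                            figdir / f"logo_{kind}_{pair}.tsv")
            manifest.add(f"logo_{kind}_{pair}", "logo", path,
                         report_viz._hash_inputs(pair, kind, len(windows)))
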