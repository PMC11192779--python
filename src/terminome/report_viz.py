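"""Figure generation and the figure manifest.

Every figure derives only from columns of the annotated/statistics table
(plus the proteome snapshot for per-protein views), so re-runs on the same
table with fixed seeds are idempotent. Each requested figure either exists
on disk or appears in the manifest with a logged skip reason.

The enrichment/pathway adapter does not call any web service: it
serializes exactly the gene lists and fold changes an over-representation
or pathway API would receive, so that contract is testable offline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .annotate import CATEGORIES, is_nterm_row
from .ingest import ConditionDesign, Dialect
from .knowledgebase import ProteinEntry
from .stats import condition_pairs, volcano_flags

logger = logging.getLogger("terminome")

DEFAULT_FIGURE_EXT = "svg"
GALLERY_CAP = 20


def _hash_inputs(*parts: object) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
    return h.hexdigest()[:16]


class FigureManifest:
    """Collects produced figures and skip reasons for the run manifest."""

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def add(self, figure_id: str, kind: str, path: Path,
            inputs_hash: str) -> None:
        self.entries.append({"figure_id": figure_id, "kind": kind,
                             "path": str(path), "inputs_hash": inputs_hash})

    def skip(self, figure_id: str, kind: str, reason: str) -> None:
        logger.info("skipping figure %s: %s", figure_id, reason)
        self.entries.append({"figure_id": figure_id, "kind": kind,
                             "path": None, "skip_reason": reason})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"figures": self.entries}, indent=1))


def dataset_counts(table: pd.DataFrame, dialect: Dialect) -> dict[str, int]:
    """Headline dataset counts (proteins, peptides, N-termini, ...).

    Modified peptides count identical sequences with distinct modification
    strings separately, so modified >= peptides always.
    """
    seq_col = dialect.column_map["sequence"]
    mod_col = dialect.column_map["modifications"]
    nterm = table.apply(
        lambda r: is_nterm_row(r["label_state"], r["start"]), axis=1)
    return {
        "proteins": int(table["anchor_accession"].dropna().nunique()),
        "peptides": int(table[seq_col].nunique()),
        "n_termini": int(nterm.sum()),
        "modified_peptides": int(
            table[[seq_col, mod_col]].fillna("").drop_duplicates().shape[0]),
        "labeled_peptides": int((table["label_state"] == "labeled").sum()),
    }


def nterm_category_counts(table: pd.DataFrame) -> dict[str, int]:
    """Category partition of N-terminal rows; values sum to n_termini."""
    nterm = table[table.apply(
        lambda r: is_nterm_row(r["label_state"], r["start"]), axis=1)]
    counts = {c: int((nterm["category"] == c).sum()) for c in CATEGORIES}
    counts["unmapped"] = int(nterm["category"].isna().sum())
    return counts


def figure_counts_and_pies(table: pd.DataFrame, dialect: Dialect,
                           outdir: Path, manifest: FigureManifest,
                           ext: str = DEFAULT_FIGURE_EXT) -> dict:
    """Bar plot of dataset counts + pie charts of N-terminus categories."""
    outdir.mkdir(parents=True, exist_ok=True)
    counts = dataset_counts(table, dialect)
    fig, ax = plt.subplots(figsize=(6, 4))
    sns.barplot(x=list(counts), y=list(counts.values()), ax=ax,
                hue=list(counts), legend=False, palette="crest")
    ax.set_ylabel("count")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    path = outdir / f"counts_bar.{ext}"
    fig.savefig(path)
    plt.close(fig)
    manifest.add("counts_bar", "counts_bar", path, _hash_inputs(counts))

    cats = nterm_category_counts(table)
    pie_data = {k: v for k, v in cats.items() if v > 0 and k != "unmapped"}
    if not pie_data:
        manifest.skip("termini_pies", "termini_pies", "no N-termini in table")
    else:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.pie(list(pie_data.values()),
               labels=[f"{k} ({v})" for k, v in pie_data.items()],
               autopct="%1.0f%%")
        ax.set_title(f"N-termini (n={sum(pie_data.values())})")
        path = outdir / f"termini_pies.{ext}"
        fig.savefig(path)
        plt.close(fig)
        manifest.add("termini_pies", "termini_pies", path, _hash_inputs(cats))
    return {"counts": counts, "categories": cats}


def figure_differential(
    table: pd.DataFrame,
    design: ConditionDesign,
    outdir: Path,
    manifest: FigureManifest,
    p_cutoff: float = 0.05,
    log2fc_cutoff: float = 1.0,
    seed: int = 0,
    ext: str = DEFAULT_FIGURE_EXT,
) -> None:
    """Volcanoes, CV density, FC histogram, heatmap/clustermap, PCA, UMAP."""
    outdir.mkdir(parents=True, exist_ok=True)
    quant_cols = [c for cols in design.resolved.values() for c in cols]

    # CV density per condition
    fig, ax = plt.subplots(figsize=(5, 4))
    any_cv = False
    for cond in design.resolved:
        cv = pd.to_numeric(table.get(f"cv_{cond}"), errors="coerce").dropna()
        if len(cv) > 1:
            sns.kdeplot(cv, ax=ax, label=cond)
            any_cv = True
    if any_cv:
        ax.set_xlabel("coefficient of variation")
        ax.legend()
        fig.tight_layout()
        path = outdir / f"cv_density.{ext}"
        fig.savefig(path)
        manifest.add("cv_density", "cv_density", path,
                     _hash_inputs(tuple(design.resolved)))
    else:
        manifest.skip("cv_density", "cv_density", "no CV values")
    plt.close(fig)

    for a, b in condition_pairs(design):
        pair = f"{a}_vs_{b}"
        lfc = pd.to_numeric(table.get(f"log2_fc_{pair}"), errors="coerce")
        p = pd.to_numeric(table.get(f"p_value_{pair}"), errors="coerce")

        fig, ax = plt.subplots(figsize=(5, 4))
        sns.histplot(lfc.dropna(), kde=True, ax=ax)
        ax.set_xlabel(f"log2 FC {a}/{b}")
        fig.tight_layout()
        path = outdir / f"fc_histogram_{pair}.{ext}"
        fig.savefig(path)
        plt.close(fig)
        manifest.add(f"fc_histogram_{pair}", "fc_histogram", path,
                     _hash_inputs(pair, lfc.count()))

        if p is None or p.isna().all():
            manifest.skip(f"volcano_{pair}", "volcano", "no p-values")
            continue
        sig = volcano_flags(table, (a, b), p_cutoff, log2fc_cutoff)
        fig, ax = plt.subplots(figsize=(5, 4))
        with np.errstate(divide="ignore"):
            neglogp = -np.log10(p)
        ax.scatter(lfc[~sig], neglogp[~sig], s=8, c="grey", alpha=0.6)
        ax.scatter(lfc[sig], neglogp[sig], s=10, c="red")
        ax.axvline(log2fc_cutoff, ls="--", c="k", lw=0.5)
        ax.axvline(-log2fc_cutoff, ls="--", c="k", lw=0.5)
        ax.axhline(-np.log10(p_cutoff), ls="--", c="k", lw=0.5)
        ax.set_xlabel(f"log2 FC {a}/{b}")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{pair}: {int(sig.sum())} significant")
        fig.tight_layout()
        path = outdir / f"volcano_{pair}.{ext}"
        fig.savefig(path)
        plt.close(fig)
        manifest.add(f"volcano_{pair}", "volcano", path,
                     _hash_inputs(pair, int(sig.sum())))

    # replicate-level views
    quant = table[quant_cols].apply(pd.to_numeric, errors="coerce")
    complete = quant.dropna()
    if len(complete) >= 2:
        z = complete.sub(complete.mean(axis=1), axis=0) \
                    .div(complete.std(axis=1).replace(0, np.nan), axis=0) \
                    .dropna()
        fig, ax = plt.subplots(figsize=(6, 5))
        sns.heatmap(z, ax=ax, cmap="vlag", center=0,
                    yticklabels=False)
        fig.tight_layout()
        path = outdir / f"heatmap.{ext}"
        fig.savefig(path)
        plt.close(fig)
        manifest.add("heatmap", "heatmap", path, _hash_inputs(z.shape))

        cg = sns.clustermap(z, cmap="vlag", center=0, yticklabels=False,
                            figsize=(6, 6))
        path = outdir / f"clustermap.{ext}"
        cg.savefig(path)
        plt.close(cg.figure)
        manifest.add("clustermap", "clustermap", path, _hash_inputs(z.shape))
    else:
        manifest.skip("heatmap", "heatmap", "fewer than 2 complete rows")
        manifest.skip("clustermap", "clustermap", "fewer than 2 complete rows")

    if len(quant_cols) < 3:
        manifest.skip("pca", "pca", "fewer than 3 replicates")
        manifest.skip("umap", "umap", "fewer than 3 replicates")
        return
    samples = complete.T  # samples x peptides
    if samples.shape[1] < 2:
        manifest.skip("pca", "pca", "not enough complete rows")
        manifest.skip("umap", "umap", "not enough complete rows")
        return

    from sklearn.decomposition import PCA

    pca = PCA(n_components=2, random_state=seed)
    comps = pca.fit_transform(samples.to_numpy(float))
    colors = {c: i for i, c in enumerate(design.resolved)}
    sample_cond = {col: cond for cond, cols in design.resolved.items()
                   for col in cols}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond in design.resolved:
        idx = [i for i, col in enumerate(samples.index)
               if sample_cond[col] == cond]
        ax.scatter(comps[idx, 0], comps[idx, 1], label=cond)
    ax.set_xlabel(f"PC1 ({pca.explained_variance_ratio_[0]:.1%})")
    ax.set_ylabel(f"PC2 ({pca.explained_variance_ratio_[1]:.1%})")
    ax.legend()
    fig.tight_layout()
    path = outdir / f"pca.{ext}"
    fig.savefig(path)
    plt.close(fig)
    manifest.add("pca", "pca", path, _hash_inputs(samples.shape, seed))

    try:
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed,
                            n_neighbors=min(5, len(samples) - 1))
        emb = reducer.fit_transform(samples.to_numpy(float))
        fig, ax = plt.subplots(figsize=(5, 4))
        for cond in design.resolved:
            idx = [i for i, col in enumerate(samples.index)
                   if sample_cond[col] == cond]
            ax.scatter(emb[idx, 0], emb[idx, 1], label=cond)
        ax.legend()
        ax.set_xlabel("UMAP1")
        ax.set_ylabel("UMAP2")
        fig.tight_layout()
        path = outdir / f"umap.{ext}"
        fig.savefig(path)
        plt.close(fig)
        manifest.add("umap", "umap", path, _hash_inputs(samples.shape, seed))
    except Exception as exc:  # pragma: no cover - depends on sample count
        manifest.skip("umap", "umap", f"embedding failed: {exc}")


def figure_protein_views(
    table: pd.DataFrame,
    proteome: dict[str, ProteinEntry],
    outdir: Path,
    manifest: FigureManifest,
    fc_column: str | None = None,
    top_k: int = GALLERY_CAP,
    ext: str = DEFAULT_FIGURE_EXT,
) -> None:
    """Per-protein sequence tracks: peptide spans, features, known cleavages.

    Peptide spans are colored by per-protein normalized log2 fold change
    (max |log2FC| maps to the color-scale extreme); proteins without
    quantified peptides get uniform coloring. The gallery is capped at the
    ``top_k`` proteins with the largest |log2FC| (cap logged).
    """
    outdir.mkdir(parents=True, exist_ok=True)
    mapped = table[table["annot_status"] == "ok"]
    if mapped.empty:
        manifest.skip("protein_views", "protein_sequence_plot",
                      "no mapped peptides")
        return
    if fc_column is not None and fc_column in mapped:
        strength = mapped.groupby("anchor_accession")[fc_column] \
            .apply(lambda s: pd.to_numeric(s, errors="coerce").abs().max())
        chosen = strength.sort_values(ascending=False).head(top_k).index
    else:
        chosen = mapped["anchor_accession"].value_counts().head(top_k).index
    logger.info("protein gallery capped at %d proteins", top_k)

    cmap = plt.get_cmap("coolwarm")
    for acc in chosen:
        entry = proteome.get(acc)
        if entry is None:
            continue
        rows = mapped[mapped["anchor_accession"] == acc]
        fig, ax = plt.subplots(figsize=(8, 2.2))
        ax.broken_barh([(1, entry.length)], (0.0, 0.25), color="#dddddd")
        for feat in entry.features:
            ax.broken_barh([(feat.start, feat.end - feat.start + 1)],
                           (0.0, 0.25), color="#ffcc66")
            ax.text(feat.start, 0.30, feat.kind, fontsize=6)
        lfc = pd.to_numeric(rows.get(fc_column), errors="coerce") \
            if fc_column else None
        scale = np.nanmax(np.abs(lfc)) if lfc is not None and \
            np.isfinite(lfc).any() else None
        for i, (_, row) in enumerate(rows.iterrows()):
            if scale and np.isfinite(lfc.loc[row.name]) and scale > 0:
                color = cmap(0.5 + lfc.loc[row.name] / (2 * scale))
            else:
                color = "#4477aa"
            y = 0.45 + 0.18 * (i % 3)
            ax.broken_barh(
                [(row["start"], row["end"] - row["start"] + 1)],
                (y, 0.12), color=color)
        for clv in entry.known_cleavages:
            ax.axvline(clv.p1 + 0.5, color="red", lw=0.7, ls=":")
        ax.set_xlim(0, entry.length + 1)
        ax.set_ylim(0, 1.2)
        ax.set_yticks([])
        ax.set_xlabel("residue")
        ax.set_title(f"{acc} ({entry.gene}) — {len(rows)} peptides",
                     fontsize=9)
        fig.tight_layout()
        path = outdir / f"protein_{acc}.{ext}"
        fig.savefig(path)
        plt.close(fig)
        manifest.add(f"protein_{acc}", "protein_sequence_plot", path,
                     _hash_inputs(acc, len(rows)))


def export_enrichment_inputs(
    table: pd.DataFrame,
    pair: tuple[str, str],
    outdir: Path,
    p_cutoff: float = 0.05,
    log2fc_cutoff: float = 1.0,
    max_terms: int = 30,
) -> Path:
    """Serialize the gene lists + fold changes an enrichment API would get.

    The cap on reported terms per plot is kept as the adapter default for
    a downstream client to honor.
    """
    a, b = pair
    sig = volcano_flags(table, pair, p_cutoff, log2fc_cutoff)
    rows = table[sig]
    payload = {
        "comparison": f"{a}_vs_{b}",
        "max_terms_per_plot": max_terms,
        "genes": sorted(set(rows["gene"].dropna()) - {""}),
        "fold_changes": {
            str(r["gene"]): float(r[f"log2_fc_{a}_vs_{b}"])
            for _, r in rows.iterrows()
            if r.get("gene") and pd.notna(r.get(f"log2_fc_{a}_vs_{b}"))
        },
    }
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"enrichment_input_{a}_vs_{b}.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
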