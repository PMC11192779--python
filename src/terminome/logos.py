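"""Sequence-logo matrices and rendering for cleavage-site motifs.

From a set of aligned cleavage windows the module computes:

* counts and per-position frequencies p_a (padding excluded, columns
  renormalized over observed residues);
* log-odds weights w_a = 2*log2(p_a/q_a) against a background q_a;
* Shannon information: per position i, IC_i = log2(20) - H_i with
  H_i = -sum_a p_a log2 p_a (equal background assumed); residue letter
  height = p_a * IC_i, in bits;
* Kullback-Leibler information: D_i = sum_a p_a log2(p_a/q_a) against the
  bundled background table; residue height = p_a * D_i.

0*log(0) is taken as 0 throughout. Under a uniform background the KL
heights equal the Shannon heights (D_i = log2(20) - H_i identically).
Rendering draws the classic stacked-letter logo with matplotlib.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .alphabet import AMINO_ACIDS
from .knowledgebase import BackgroundFrequencies, SubstrateWindow
from .specificity import build_pssm

LOG2_20 = math.log2(20)

_AA_COLORS = {
    **{aa: "#2c7fb8" for aa in "AVLIMFWPG"},   # hydrophobic / special
    **{aa: "#31a354" for aa in "STYCNQ"},      # polar
    **{aa: "#de2d26" for aa in "DE"},          # acidic
    **{aa: "#756bb1" for aa in "KRH"},         # basic
}


@dataclass
class LogoMatrices:
    counts: np.ndarray        # (positions, 20)
    freq: np.ndarray          # p_a
    weights: np.ndarray       # w_a, Eq-style log odds
    info_shannon: np.ndarray  # residue heights, bits
    info_kl: np.ndarray       # residue heights, bits
    background: BackgroundFrequencies
    positions: list[str]
    n_sequences: int
    method_tag: str = ""


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def build_logo_matrices(
    windows: list[SubstrateWindow] | list[str],
    background: BackgroundFrequencies | None = None,
    pseudocounts: bool = False,
    pseudocount_weight: float = 5.0,
    method_tag: str = "",
) -> LogoMatrices:
    """Compute all logo matrices from aligned cleavage windows."""
    background = background or BackgroundFrequencies.uniform()
    model = build_pssm(
        windows, background,
        pseudocount_weight=pseudocount_weight if pseudocounts else 0.0,
        use_blosum_pseudocounts=pseudocounts,
    )
    p = model.freq
    q = np.array([background.freq[a] for a in AMINO_ACIDS])

    entropy = -_xlogx(p).sum(axis=1)                 # H_i, bits
    ic = LOG2_20 - entropy                           # Shannon IC per position
    info_shannon = p * ic[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / q, 1.0)
    kl = (np.where(p > 0, p, 0.0) * np.log2(ratio)).sum(axis=1)  # D_i
    info_kl = p * kl[:, None]

    return LogoMatrices(
        counts=model.counts, freq=p, weights=model.weights,
        info_shannon=info_shannon, info_kl=info_kl,
        background=background, positions=model.positions,
        n_sequences=model.n_substrates, method_tag=method_tag,
    )


_KIND_TO_MATRIX = {
    "probability": "freq",
    "pssm": "weights",
    "shannon": "info_shannon",
    "kl": "info_kl",
}


def _draw_letter(ax, letter: str, x: float, y: float, height: float,
                 width: float = 0.9) -> None:
    if height == 0:
        return
    font = FontProperties(family="DejaVu Sans", weight="bold")
    path = TextPath((0, 0), letter, size=1.0, prop=font)
    bbox = path.get_extents()
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(width / bbox.width, abs(height) / bbox.height)
        .translate(x - width / 2, min(y, y + height))
        + ax.transData
    )
    ax.add_patch(PathPatch(path, transform=transform, lw=0,
                           color=_AA_COLORS.get(letter, "black")))


def render_logo(matrices: LogoMatrices, kind: str,
                out: str | Path) -> Path:
    """Render a stacked-letter logo figure and write it to ``out``.

    The title carries the number of sequences and the method tag; stack
    heights equal the corresponding matrix column values (for the pssm
    kind, negative weights stack below the axis).
    """
    if kind not in _KIND_TO_MATRIX:
        raise ValueError(f"unknown logo kind {kind!r}")
    matrix = getattr(matrices, _KIND_TO_MATRIX[kind])
    n_pos = matrix.shape[0]

    fig, ax = plt.subplots(figsize=(max(4, 0.8 * n_pos), 3))
    for i in range(n_pos):
        col = matrix[i]
        pos_entries = sorted(
            ((col[j], AMINO_ACIDS[j]) for j in range(20) if col[j] > 0))
        y = 0.0
        for h, aa in pos_entries:
            _draw_letter(ax, aa, i, y, h)
            y += h
        if kind == "pssm":
            neg_entries = sorted(
                ((col[j], AMINO_ACIDS[j]) for j in range(20) if col[j] < 0),
                reverse=True)
            y = 0.0
            for h, aa in neg_entries:
                _draw_letter(ax, aa, i, y, h)
                y += h

    ax.set_xticks(range(n_pos))
    ax.set_xticklabels(matrices.positions)
    ax.set_xlim(-0.6, n_pos - 0.4)
    lo = min(0.0, float(matrix.min()) * 1.05)
    hi = max(float(matrix[matrix > 0].sum(axis=-1).max() if (matrix > 0).any()
                   else 1.0) * 1.05, 1e-6)
    ax.set_ylim(lo, hi)
    ylabels = {"probability": "probability", "pssm": "weight (half-bits)",
               "shannon": "bits", "kl": "bits"}
    ax.set_ylabel(ylabels[kind])
    tag = f" — {matrices.method_tag}" if matrices.method_tag else ""
    ax.set_title(f"{kind} logo, n={matrices.n_sequences}{tag}")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def matrices_to_tsv(matrices: LogoMatrices, kind: str,
                    path: str | Path) -> None:
    """Export one logo matrix as a position x residue TSV."""
    import pandas as pd

    matrix = getattr(matrices, _KIND_TO_MATRIX[kind])
    df = pd.DataFrame(matrix, index=matrices.positions,
                      columns=list(AMINO_ACIDS))
    df.index.name = "position"
    df.to_csv(path, sep="\t", float_format="%.6f")
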