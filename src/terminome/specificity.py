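"""Protease specificity models: PSSM construction and cleavage-site scoring.

For a protease with known substrate cleavage windows (P4..P1|P1'..P4' by
default), a position-specific scoring matrix is built from the per-position
amino-acid frequencies p_a and a background distribution q_a:

    w_a = 2 * log2(p_a / q_a)

The score of an observed cleavage window is the summed log-odds over its
positions; padding positions ('-') contribute zero, so partial windows at
protein termini are scored on the residues that exist.

Sparse substrate sets (common for less-studied proteases) can be smoothed
with substitution-matrix pseudocounts: the pseudo-frequency of residue a at
position i is sum_b f_ib * T(b, a), where T is the row-normalized
substitution-probability matrix derived from BLOSUM62 by 2**(S/2) scaling
of the half-bit scores, and the blended frequency is
(N * f_ia + beta * pseudo_ia) / (N + beta) with blend weight beta
(default 5). With beta = 0 the frequencies are the raw count proportions.

Without pseudocounts, residues never observed at a position get a finite
floor weight 2 * log2(eps / max(q)) with eps = 1 / (20 * (N + 1)), which is
monotone in the number of substrates N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .alphabet import AA_INDEX, AMINO_ACIDS, PAD, window_positions
from .knowledgebase import BackgroundFrequencies, SubstrateWindow

logger = logging.getLogger("terminome")

DEFAULT_PSEUDOCOUNT_WEIGHT = 5.0


@lru_cache(maxsize=1)
def blosum62_transition_matrix() -> np.ndarray:
    """Row-normalized substitution-probability matrix T from BLOSUM62.

    T[b, a] is the probability of substituting residue b by residue a,
    obtained by exponentiating the half-bit log-odds scores and
    normalizing each row.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    scores = np.empty((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = blosum[a, b]
    probs = np.power(2.0, scores / 2.0)
    return probs / probs.sum(axis=1, keepdims=True)


@dataclass
class SpecificityModel:
    """Per-position amino-acid count/frequency/weight matrices."""

    merops_id: str
    positions: list[str]
    counts: np.ndarray   # (n_positions, 20)
    freq: np.ndarray     # p_a, columns sum to 1 over counted residues
    background: BackgroundFrequencies
    weights: np.ndarray  # w_a = 2*log2(p_a/q_a), floored where p_a = 0
    pseudocount_weight: float
    n_substrates: int

    @property
    def window_length(self) -> int:
        return len(self.positions)

    def to_tsv(self, path: str | Path) -> None:
        """Export the weight matrix (position x residue) for inspection."""
        df = pd.DataFrame(self.weights, index=self.positions,
                          columns=list(AMINO_ACIDS))
        df.index.name = "position"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @staticmethod
    def weights_from_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
        df = pd.read_csv(path, sep="\t", index_col="position")
        return list(df.index), df[list(AMINO_ACIDS)].to_numpy(float)


def build_pssm(
    windows: list[SubstrateWindow] | list[str],
    background: BackgroundFrequencies,
    pseudocount_weight: float = 0.0,
    use_blosum_pseudocounts: bool = False,
    merops_id: str = "",
) -> SpecificityModel:
    """Build a specificity model from substrate cleavage windows.

    Padding characters are excluded from their position's count and the
    frequencies renormalized over observed residues, so partial windows
    contribute only where they have sequence.
    """
    seqs = [w.window if isinstance(w, SubstrateWindow) else str(w)
            for w in windows]
    if not seqs:
        raise ValueError("cannot build a PSSM from zero substrate windows")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("substrate windows have inconsistent lengths")
    if not merops_id and windows and isinstance(windows[0], SubstrateWindow):
        merops_id = windows[0].merops_id

    n_aa = len(AMINO_ACIDS)
    counts = np.zeros((length, n_aa))
    for s in seqs:
        for i, ch in enumerate(s.upper()):
            if ch == PAD:
                continue
            counts[i, AA_INDEX[ch]] += 1

    observed = counts.sum(axis=1)  # non-padding count per position
    if np.any(observed == 0):
        raise ValueError("a window position has only padding characters")
    freq = counts / observed[:, None]

    if use_blosum_pseudocounts and pseudocount_weight > 0:
        transition = blosum62_transition_matrix()
        pseudo = freq @ transition  # pseudo_ia = sum_b f_ib * T[b, a]
        beta = pseudocount_weight
        freq = (observed[:, None] * freq + beta * pseudo) / (
            observed[:, None] + beta)

    q = np.array([background.freq[a] for a in AMINO_ACIDS])
    n_sub = len(seqs)
    eps = 1.0 / (n_aa * (n_sub + 1))
    floor = 2.0 * math.log2(eps / q.max())
    with np.errstate(divide="ignore"):
        weights = np.where(freq > 0, 2.0 * np.log2(
            np.where(freq > 0, freq, 1.0) / q), floor)

    n_nonprime = length // 2
    return SpecificityModel(
        merops_id=merops_id,
        positions=window_positions(n_nonprime, length - n_nonprime),
        counts=counts, freq=freq, background=background, weights=weights,
        pseudocount_weight=pseudocount_weight if use_blosum_pseudocounts else 0.0,
        n_substrates=n_sub,
    )


def score_site(model: SpecificityModel, window: str) -> float:
    """Summed log-odds score of a cleavage window against the model."""
    if len(window) != model.window_length:
        raise ValueError(
            f"window length {len(window)} != model length {model.window_length}")
    total = 0.0
    for i, ch in enumerate(window.upper()):
        if ch == PAD:
            continue  # padding carries no evidence
        total += model.weights[i, AA_INDEX[ch]]
    return total


def score_table(
    models: list[SpecificityModel],
    table: pd.DataFrame,
    window_column: str = "cleavage_window",
) -> pd.DataFrame:
    """Append one ``pssm_score_<merops_id>`` column per model.

    Rows without an annotated cleavage window get an empty score.
    """
    for model in models:
        col = f"pssm_score_{model.merops_id}"
        table[col] = [
            score_site(model, w) if isinstance(w, str) and w else None
            for w in table[window_column]
        ]
        logger.info("scored %d sites against %s",
                    table[col].notna().sum(), model.merops_id)
    return table
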