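import math
import random

import numpy as np
import pandas as pd
import pytest

from terminome.alphabet import AMINO_ACIDS
from terminome.knowledgebase import BackgroundFrequencies
from terminome.specificity import (SpecificityModel, build_pssm, score_site,
                                   score_table)

UNIFORM = BackgroundFrequencies.uniform()
W_MAX = 2 * math.log2(20)  # weight of a fixed residue vs uniform background


def brute_force_score(windows, background, window):
    """Independent log-odds computation: count, normalize, 2*log2(p/q)."""
    length = len(windows[0])
    total = 0.0
    n = len(windows)
    eps = 1.0 / (20 * (n + 1))
    q_max = max(background.freq.values())
    for i, ch in enumerate(window):
        if ch == "-":
            continue
        count = sum(1 for w in windows if w[i] == ch)
        observed = sum(1 for w in windows if w[i] != "-")
        p = count / observed
        q = background.freq[ch]
        total += 2 * math.log2(p / q) if p > 0 else 2 * math.log2(eps / q_max)
    return total


class TestBuildPssm:
    def test_single_window_fixed_residue(self):
        model = build_pssm(["AAAAAAAA"], UNIFORM)
        a = AMINO_ACIDS.index("A")
        assert np.allclose(model.freq[:, a], 1.0)
        assert np.allclose(model.weights[:, a], W_MAX, atol=1e-9)

    def test_weight_zero_when_freq_equals_background(self):
        # each residue appears once per position -> p_a = 0.05 = q_a
        windows = [aa * 8 for aa in AMINO_ACIDS]
        model = build_pssm(windows, UNIFORM)
        assert np.allclose(model.weights, 0.0, atol=1e-9)

    def test_zero_pseudocount_gives_raw_proportions(self):
        rng = random.Random(2)
        windows = ["".join(rng.choice(AMINO_ACIDS) for _ in range(8))
                   for _ in range(10)]
        model = build_pssm(windows, UNIFORM, pseudocount_weight=0.0)
        for i in range(8):
            for j, aa in enumerate(AMINO_ACIDS):
                count = sum(1 for w in windows if w[i] == aa)
                assert model.freq[i, j] == pytest.approx(count / 10)

    def test_padding_excluded_and_renormalized(self):
        model = build_pssm(["AAAAAAAA", "----AAAA"], UNIFORM)
        a = AMINO_ACIDS.index("A")
        assert np.allclose(model.freq[:, a], 1.0)
        assert model.counts[0, a] == 1 and model.counts[4, a] == 2

    def test_pseudocounts_remove_zero_frequencies(self):
        model = build_pssm(["AAAAAAAA"], UNIFORM, pseudocount_weight=5.0,
                           use_blosum_pseudocounts=True)
        assert (model.freq > 0).all()
        assert np.allclose(model.freq.sum(axis=1), 1.0, atol=1e-9)

    def test_pseudocount_continuity_toward_raw(self):
        windows = ["PAALLAAG", "PAGLVAAG", "PASLLAAG"]
        raw = build_pssm(windows, UNIFORM).freq
        tiny = build_pssm(windows, UNIFORM, pseudocount_weight=1e-9,
                          use_blosum_pseudocounts=True).freq
        assert np.allclose(tiny, raw, atol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_pssm([], UNIFORM)
        with pytest.raises(ValueError):
            build_pssm(["AAAA", "AAAAAAAA"], UNIFORM)


class TestScoreSite:
    def test_modal_window_score(self):
        model = build_pssm(["AAAAAAAA"], UNIFORM)
        assert score_site(model, "AAAAAAAA") == pytest.approx(8 * W_MAX,
                                                              abs=1e-9)

    def test_padding_contributes_zero(self):
        model = build_pssm(["AAAAAAAA"], UNIFORM)
        assert score_site(model, "--AAAAAA") == pytest.approx(6 * W_MAX,
                                                              abs=1e-9)

    def test_background_window_scores_zero(self):
        windows = [aa * 8 for aa in AMINO_ACIDS]
        model = build_pssm(windows, UNIFORM)
        assert score_site(model, "ACDEFGHI") == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch(self):
        model = build_pssm(["AAAAAAAA"], UNIFORM)
        with pytest.raises(ValueError):
            score_site(model, "AAAA")

    def test_additivity(self):
        rng = random.Random(4)
        windows = ["".join(rng.choice(AMINO_ACIDS) for _ in range(8))
                   for _ in range(5)]
        model = build_pssm(windows, UNIFORM)
        window = "PAALLAAG"
        per_position = [
            model.weights[i, AMINO_ACIDS.index(ch)]
            for i, ch in enumerate(window)]
        assert score_site(model, window) == pytest.approx(sum(per_position),
                                                          abs=1e-12)

    @pytest.mark.parametrize("n_sub", [1, 3, 5])
    def test_matches_brute_force_oracle(self, n_sub):
        rng = random.Random(n_sub)
        windows = ["".join(rng.choice(AMINO_ACIDS) for _ in range(8))
                   for _ in range(n_sub)]
        model = build_pssm(windows, UNIFORM)
        for _ in range(100):
            query = "".join(rng.choice(AMINO_ACIDS + "-") for _ in range(8))
            assert score_site(model, query) == pytest.approx(
                brute_force_score(windows, UNIFORM, query), abs=1e-9)

    def test_modal_window_beats_background_expectation(self):
        rng = random.Random(8)
        windows = ["PAALLAAG"] * 6 + [
            "".join(rng.choice(AMINO_ACIDS) for _ in range(8))
            for _ in range(4)]
        model = build_pssm(windows, UNIFORM)
        modal = "".join(AMINO_ACIDS[j] for j in model.weights.argmax(axis=1))
        expected = float((model.weights * 0.05).sum())  # uniform draw
        assert score_site(model, modal) >= expected


class TestScoreTable:
    def test_one_column_per_model(self):
        models = [build_pssm(["AAAAAAAA"], UNIFORM, merops_id="M10.004"),
                  build_pssm(["PPPPPPPP"], UNIFORM, merops_id="C14.003")]
        table = pd.DataFrame({"cleavage_window": ["AAAAAAAA", None]})
        out = score_table(models, table)
        assert "pssm_score_M10.004" in out and "pssm_score_C14.003" in out
        assert out.loc[0, "pssm_score_M10.004"] == pytest.approx(8 * W_MAX)
        assert pd.isna(out.loc[1, "pssm_score_M10.004"])

    def test_true_motif_windows_outscore_shuffled_decoys(self,
                                                        default_fixture):
        from terminome.knowledgebase import (load_background_frequencies,
                                             load_merops_substrates)
        fx = default_fixture
        background = load_background_frequencies()
        windows = load_merops_substrates(fx.merops_tsv, ["M10.004"])["M10.004"]
        model = build_pssm(windows, background)
        rng = random.Random(0)
        true_scores, decoy_scores = [], []
        for w in windows:
            true_scores.append(score_site(model, w.window))
            shuffled = list(w.window)
            rng.shuffle(shuffled)
            decoy_scores.append(score_site(model, "".join(shuffled)))
        assert np.median(true_scores) > np.median(decoy_scores)

    def test_export_import_roundtrip(self, tmp_path):
        model = build_pssm(["PAALLAAG", "PAGLVAAG"], UNIFORM,
                           merops_id="M10.004")
        path = tmp_path / "m.tsv"
        model.to_tsv(path)
        positions, weights = SpecificityModel.weights_from_tsv(path)
        assert positions == model.positions
        assert np.allclose(weights, model.weights, atol=1e-6)
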