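# terminome

Offline analysis of **positional proteomics (degradomics)** experiments:
peptide-level annotation of protein termini, protease cleavage-site
scoring, and differential statistics across quantitative conditions.

In N-terminomics workflows (TAILS, HUNTER and related negative-enrichment
protocols), free protein N-termini are chemically labeled (TMT or
dimethylation) before digestion, so every labeled peptide marks a protein
terminus — either a natural one (initiator Met intact or removed, signal/
transit/propeptide maturation) or a **neo-N-terminus** created by a
protease. `terminome` takes a search-engine peptide report and turns it
into an annotated, statistically analyzed cleavage map, entirely from
local snapshot files: no web APIs, no network.

## What it computes

* **Positional annotation** — each peptide is located in its anchor
  protein (1-based coordinates); a peptide starting at position *s* > 1
  implies a scissile bond at P1 = *s* − 1 (Schechter–Berger convention),
  and the P4–P4′ cleavage environment is extracted with `-` padding at
  sequence ends. N-termini are classified as Met-intact (start 1),
  Met-removed (start 2), known processing (start = feature end + 1 for a
  signal/transit/propeptide) or internal neo-N-terminus. Proteoform
  certainty is 1/N over the N proteins containing the peptide.
* **Exopeptidase trimming** — ragged-end ladders (peptides identical
  except one or two missing N-terminal residues, sharing their last five
  residues) are annotated as aminopeptidase or dipeptidase products, with
  deterministic closest-parent tie-breaking.
* **Protease specificity (PSSM)** — from MEROPS-style substrate windows,
  per-position weights

  ```
  w_a = 2 · log2(p_a / q_a)
  ```

  where `p_a` is the observed residue frequency at a position and `q_a`
  the background frequency; a cleavage site's score is the summed
  log-odds over its window. Sparse substrate sets can be smoothed with
  BLOSUM62 substitution-matrix pseudocounts.
* **Statistics** — per-condition mean/sd/CV, fold changes
  (first-listed condition is the numerator), pooled two-sample *t* tests
  or one-way ANOVA, step-up FDR correction, empirical-quantile tail
  significance on the log2 FC distribution, and the substrate filter
  cascade (p < 0.01, FC > 3, labeled internal neo-N-terminus, optionally
  excluding cleavages already attributed to the protease).
* **Logos & figures** — probability, PSSM, Shannon-information
  (IC = log2 20 − H) and Kullback–Leibler (D = Σ p·log2 p/q) logo
  matrices and stacked-letter plots; QC and differential figures
  (counts, pies, CV density, volcano, heatmap/clustermap, PCA, UMAP,
  per-protein sequence tracks).
* **Structure adapter** — optional secondary-structure (L/H/S) and
  P1 solvent-accessibility annotation from predicted models, behind a
  pluggable backend (reference: biotite P-SEA + Shrake–Rupley SASA).
* **Synthetic experiments** — `terminome.synthetic` generates complete
  experiments (proteome, features, substrate windows, quantified report,
  condition file) with a ground-truth manifest, which is how everything
  above is tested.

## Worked example

```python
from terminome.synthetic import FixtureSpec, generate_experiment
from terminome.pipeline import RunConfig, run
from terminome.stats import substrate_filter
import pandas as pd

fx = generate_experiment(FixtureSpec(seed=1, n_known_true_cleavages=2),
                         "example")
out = run(RunConfig(
    input=str(fx.report), proteome_fasta=str(fx.proteome_fasta),
    outdir="example/out", features=str(fx.features_tsv),
    known_cleavages=str(fx.cleavages_tsv),
    conditions=str(fx.condition_file), figures=False, seed=1))
table = pd.read_csv(out / "annotated.tsv", sep="\t")
print(table["category"].value_counts().to_dict())
hits = substrate_filter(table, "p_value_treat_vs_ctrl",
                        "fold_change_treat_vs_ctrl",
                        p_cutoff=0.01, fc_cutoff=3.0)
print(len(hits), "putative substrates")
```

prints

```
{'internal': 158, 'met_intact': 39, 'known_processing': 18, 'met_removed': 15}
30 putative substrates
```

— the 230 peptides partition into natural N-termini (Met-intact,
Met-removed), known maturation products, and internal peptides, and the
filter cascade (significantly > 3-fold higher in the treated condition,
labeled, internal) returns exactly the 30 neo-N-terminal peptides the
generator spiked in. Passing
`exclude_known_merops_id="M10.004"` to the filter drops the two hits the
snapshot already attributes to that protease, leaving 28.

The same pipeline runs from the shell:

```bash
terminome --input report.tsv --proteome proteome.fasta \
          --features features.tsv --conditions conditions.txt \
          --proteases proteases.txt --merops-substrates merops.tsv \
          --outdir results/
```

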