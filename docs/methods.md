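# Methods

This note documents the models and procedures implemented in `terminome`,
the parameters that matter, the numerical conventions, and what the
synthetic experiments do and do not demonstrate.

## Coordinates and cleavage-site convention

All protein coordinates are 1-based inclusive. A peptide mapped to start
position *s* > 1 evidences a scissile bond between residues *s* − 1 and
*s*; P1 = *s* − 1 (Schechter–Berger). The cleavage environment is the
window P*n*…P1 | P1′…P*n*′ (default *n* = *n*′ = 4); positions outside
the sequence are padded with `-`. Peptides starting at position 1 have no
upstream bond and therefore no P1. When a peptide occurs more than once
in its protein, the first (lowest-start) occurrence is annotated and the
occurrence count is reported; first-match is an arbitrary but
deterministic choice. Multi-accession rows are annotated against the
first listed accession; the ambiguity is quantified separately by the
proteoform certainty 1/N.

## N-terminus classification

Precedence is fixed so that the categories partition: start 1 →
`met_intact`; start 2 → `met_removed` (this wins over any feature
coincidentally ending at position 1); start = feature end + 1 for a
signal-peptide, transit-peptide or propeptide feature →
`known_processing`; otherwise `internal`. Only those three feature kinds
count as known processing events. Label state (labeled / acetylated /
free) is detected from modification tokens with per-dialect regular
expressions, so other labeling chemistries can be added in the dialect
config. A row counts as an N-terminus when its alpha-amine is blocked
(labeled or acetylated) or it starts at position ≤ 2; classification is
by position only, with label state exposed as its own column.

## Exopeptidase (ragged-end) inference

Candidate trimming products must be ≥ 5 residues (the shared-suffix
length), be a proper suffix of an identified parent peptide, and be
shorter by exactly 1 (aminopeptidase) or 2 (dipeptidase) residues. When
both a 1- and a 2-residue parent exist the closest parent is chosen;
ties at equal distance break to the lexicographically smallest parent,
making the output independent of input order. The reported round is the
trimming-chain depth (products of unannotated parents are round 1;
products of round-*r* parents are round *r* + 1), so chains such as
full → −1 → −2 are visible. In table context peptides are only matched
within the same anchor protein, since cross-protein suffix identity is
coincidence, not trimming; the alternative (global matching) is a
one-line change in `annotate_trimming`.

## Specificity models

Counts come from substrate windows with `-` positions excluded and each
position renormalized over its observed residues, so partial windows
contribute only where they carry sequence. Weights are
w_a = 2·log2(p_a/q_a) (half-bit log odds); a site score is the sum over
window positions, with `-` contributing 0.

Pseudocounts (optional, for sparse substrate sets): the
substitution-probability matrix T is obtained from BLOSUM62 by
exponentiating the half-bit scores (2^(S/2)) and row-normalizing;
pseudo-frequencies are p̃_ia = Σ_b f_ib·T(b,a) and the blended frequency
is (N·f_ia + β·p̃_ia)/(N + β) with default blend weight β = 5. With
β → 0 the frequencies converge to raw proportions (tested). This is the
standard substitution-matrix pseudocount construction; it is a documented
choice, not a claim about any other tool's exact formula.

Without pseudocounts, a residue never observed at a position receives
the finite floor weight 2·log2(ε/q_max) with ε = 1/(20·(N+1)), which
decreases monotonically as the number of substrates N grows — absence
from a large substrate set is stronger evidence than absence from a
small one.

## Statistics

* Summaries: sample sd (n − 1); CV = sd/mean, undefined at mean 0.
* Fold change: mean of the first-listed condition over the second, per
  condition-file order; zero or negative means leave FC/log2FC empty (no
  epsilon inflation).
* Tests: pooled-variance two-sample *t* by default (Welch available via
  `equal_var=False`); one-way ANOVA for > 2 conditions, or all pairwise
  *t* tests on request. Rows with < 2 values in a group get empty
  p-values rather than errors.
* Multiple testing: Benjamini–Hochberg step-up FDR by default, applied
  across all emitted tests as one family (family size logged). Adjusted
  values are written to the output table but figure cutoffs use raw
  p-values.
* Tail significance is computed from empirical quantiles of the log2 FC
  distribution (default 5% per tail): deterministic and parameter-free,
  in place of a histogram-density estimate. Degenerate distributions
  (all values equal, or tail fraction 0) label nothing; below 20 finite
  values a warning is logged because quantile labels are unstable.
* Volcano significance: raw p < 0.05 and |log2FC| > 1 by default, both
  user-overridable.
* Substrate filter cascade: p < 0.01 and FC > 3 and (optionally) labeled
  internal neo-N-terminus, with optional exclusion of P1 positions
  already attributed to the protease under study in the knowledgebase.

## Logo matrices

Frequencies as in the specificity model (padding excluded, 0·log 0 = 0).
Shannon information per position: IC = log2 20 − H, assuming a uniform
residue background; letter height is p_a·IC. Kullback–Leibler
information: D = Σ_a p_a·log2(p_a/q_a) against the bundled background
table; under a uniform background KL heights equal Shannon heights
(identity tested to 1e−9). No small-sample IC bias correction is
applied. The bundled background table is a snapshot stand-in for a large
sequence-database composition (the widely used average amino-acid
frequencies); its provenance is recorded in `source_tag` and any TSV with
columns `amino_acid, frequency` can replace it.

## Structure backend

The reference backend assigns per-residue secondary structure with the
P-SEA CA-geometry algorithm (via biotite) collapsed to {H, S, L}, and
solvent accessibility with Shrake–Rupley (probe 1.4 Å, 100 sphere
points), summed per residue in Å². Model residue numbering is assumed to
equal protein positions, which holds for full-length predicted models.
The backend is an interface; outputs of other engines (e.g. DSSP-based
assignments) will differ in detail and no equivalence is promised. The
synthetic model builders (ideal helix/strand CA traces, cubic-lattice
globule) are labelled synthetic stand-ins used for tests and demos only.

## Synthetic experiments — what they show and don't

The generator embeds motif-drawn cleavage windows into random proteins
(sampled from the background composition), emits the downstream peptide
as a labeled neo-N-terminal row, applies a multiplicative abundance
effect in the first-listed condition, and adds log-normal replicate
noise — the standard behavior of reporter-ion/precursor intensities.
Defaults: 20 proteins (150–400 aa, 30% with a 1–22 signal peptide), 30
true cleavages, 200 background peptides, 40 substrate windows for the
PSSM, 2 conditions × 5 replicates, effect log2FC = 2, noise sd 0.3
(log2 scale), 2% missing cells, MMP-like motif (P3 Pro 0.70, P1′
small-hydrophobic). At these settings the closed-form power of the
pooled *t* test at α = 0.01 exceeds 0.99, so ≥ 95% recovery with the
margin absorbed by missingness is the expected behavior, and the type-I
error of the null simulation calibrates the test at nominal α.

Passing these tests shows the pipeline's logic is correct under clean,
generative conditions. It does **not** show robustness to what real
degradomics data adds: missed cleavages, co-eluting isobaric
interference, ratio compression in reporter-ion quantification,
non-log-normal missingness (censoring at the detection limit), shared
peptides across homologs, or search-engine FDR artifacts. Problem sizes
in tests and the acceptance script (230-row reports, 2000-row null
simulations, 100-set oracle comparisons) were chosen as the smallest
sizes at which the checked properties are statistically meaningful.

## Known limitations

* Only N-terminal ragged ends are inferred (no carboxypeptidase logic).
* PSSM scores are raw summed log odds, not calibrated to p-values.
* No isoform-level resolution beyond 1/N certainty.
* Enrichment/pathway analysis is an offline adapter that serializes the
  inputs a live service would receive; it performs no enrichment itself.
* Live database clients are intentionally absent; the knowledgebase is
  snapshot-file based with `load_proteome`'s return contract as the seam
  for plugging a client in.
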