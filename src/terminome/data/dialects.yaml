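# Search-engine dialect vocabularies.
#
# Each dialect maps the semantic fields the pipeline needs (sequence,
# modifications, accessions) to the column names the engine exports, and
# carries the modification-string patterns (regular expressions) used to
# classify the peptide N-terminal label state. Users add support for a new
# engine by adding an entry here (or renaming their table's columns to the
# generic dialect), no code changes required.

proteome_discoverer:
  columns:
    sequence: Sequence
    modifications: Modifications
    accessions: Master Protein Accessions
  patterns:
    nterm_label: '(TMT|Dimethyl)[^\[;]*\[N-Term\]'
    lysine_label: '(TMT|Dimethyl)[^\[;]*\[K'
    acetyl: 'Acetyl[^\[;]*\[N-Term\]'

spectronaut:
  columns:
    sequence: PEP.StrippedSequence
    modifications: EG.ModifiedSequence
    accessions: PG.ProteinAccessions
  patterns:
    nterm_label: '(TMT|Dimethyl)[^\[;]*\[N-Term\]'
    lysine_label: '(TMT|Dimethyl)[^\[;]*\[K'
    acetyl: 'Acetyl[^\[;]*\[N-Term\]'

spectromine:
  columns:
    sequence: PEP.StrippedSequence
    modifications: PEP.Modifications
    accessions: PEP.AllOccurringProteinAccessions
  patterns:
    nterm_label: '(TMT|Dimethyl)[^\[;]*\[N-Term\]'
    lysine_label: '(TMT|Dimethyl)[^\[;]*\[K'
    acetyl: 'Acetyl[^\[;]*\[N-Term\]'

generic:
  columns:
    sequence: sequence
    modifications: modifications
    accessions: accessions
  patterns:
    nterm_label: '(TMT|Dimethyl)[^\[;]*\[N-Term\]'
    lysine_label: '(TMT|Dimethyl)[^\[;]*\[K'
    acetyl: 'Acetyl[^\[;]*\[N-Term\]'
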