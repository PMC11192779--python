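"""Shared amino-acid alphabet constants.

Coordinates throughout the package are 1-based inclusive. Cleavage-site
positions follow the Schechter–Berger convention: P1 is the residue
immediately N-terminal to the scissile bond, P1' immediately C-terminal,
so a peptide starting at protein position ``start`` (> 1) reports a
cleavage at ``p1 = start - 1``.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Padding symbol used in cleavage windows for positions that fall outside
#: the protein sequence (and in substrate windows of partial length).
PAD = "-"

#: Default cleavage-environment size: 4 non-prime (P4..P1) + 4 prime
#: (P1'..P4') positions.
DEFAULT_N_NONPRIME = 4
DEFAULT_N_PRIME = 4


def window_positions(n_nonprime: int = DEFAULT_N_NONPRIME,
                     n_prime: int = DEFAULT_N_PRIME) -> list[str]:
    """Position labels P<n>..P1, P1'..P<n'>' for a cleavage window."""
    nonprime = [f"P{i}" for i in range(n_nonprime, 0, -1)]
    prime = [f"P{i}'" for i in range(1, n_prime + 1)]
    return nonprime + prime
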