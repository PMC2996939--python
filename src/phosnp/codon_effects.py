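"""Standard genetic code, codon-level substitution classification, and the
minimal nucleotide substitution-cost metric between amino acids.

The substitution cost between two amino acids is the minimum Hamming distance
between any codon of the first and any codon of the second.  It ranges 0-3 and
is the natural yardstick for how "easy" it is for point mutations to convert
one residue into another; costs of 2 or 3 require multiple independent DNA
changes and are correspondingly rare in natural variation.

The stop codon is treated as a first-class 21st symbol ('*') so that variants
hitting stop codons (premature stops, read-throughs) are representable.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"

#: Standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {}
_CODE_TABLE = (
    "TTT F|TTC F|TTA L|TTG L|CTT L|CTC L|CTA L|CTG L|"
    "ATT I|ATC I|ATA I|ATG M|GTT V|GTC V|GTA V|GTG V|"
    "TCT S|TCC S|TCA S|TCG S|CCT P|CCC P|CCA P|CCG P|"
    "ACT T|ACC T|ACA T|ACG T|GCT A|GCC A|GCA A|GCG A|"
    "TAT Y|TAC Y|TAA *|TAG *|CAT H|CAC H|CAA Q|CAG Q|"
    "AAT N|AAC N|AAA K|AAG K|GAT D|GAC D|GAA E|GAG E|"
    "TGT C|TGC C|TGA *|TGG W|CGT R|CGC R|CGA R|CGG R|"
    "AGT S|AGC S|AGA R|AGG R|GGT G|GGC G|GGA G|GGG G"
)
for _entry in _CODE_TABLE.split("|"):
    _codon, _aa = _entry.split()
    GENETIC_CODE[_codon] = _aa

#: The 20 amino acids plus stop, in a fixed order used by the cost matrix.
SYMBOLS = "ACDEFGHIKLMNPQRSTVWY*"

#: Codons encoding each symbol.
CODONS_OF: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c, a in GENETIC_CODE.items() if a == aa) for aa in SYMBOLS
}


class CodonError(ValueError):
    """Raised for codons outside {A,C,G,T}^3 or unknown residue symbols."""


def translate_codon(codon: str) -> str:
    """Translate a single codon under the standard genetic code.

    Returns the one-letter amino acid, or '*' for a stop codon.  Ambiguous
    bases (e.g. N) are rejected: the analysis operates on resolved sequence.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonError(f"invalid codon {codon!r}: expected 3 bases from ACGT")
    return GENETIC_CODE[codon]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence (length divisible by 3) codon by codon."""
    if len(cds) % 3 != 0:
        raise CodonError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def _hamming(c1: str, c2: str) -> int:
    return sum(a != b for a, b in zip(c1, c2))


@lru_cache(maxsize=1)
def cost_matrix() -> np.ndarray:
    """21x21 integer matrix of minimal substitution costs over SYMBOLS order.

    Entry [i, j] is the minimum Hamming distance between any codon of
    SYMBOLS[i] and any codon of SYMBOLS[j]; symmetric with zero diagonal.
    """
    n = len(SYMBOLS)
    mat = np.full((n, n), 3, dtype=int)
    for i, a in enumerate(SYMBOLS):
        for j, b in enumerate(SYMBOLS):
            mat[i, j] = min(
                _hamming(c1, c2) for c1 in CODONS_OF[a] for c2 in CODONS_OF[b]
            )
    return mat


def substitution_cost(aa1: str, aa2: str) -> int:
    """Minimal number of DNA substitutions converting aa1 into aa2 (0-3)."""
    try:
        i, j = SYMBOLS.index(aa1.upper()), SYMBOLS.index(aa2.upper())
    except ValueError as exc:
        raise CodonError(f"invalid residue symbol in ({aa1!r}, {aa2!r})") from exc
    return int(cost_matrix()[i, j])


def codon_change_effect(ref_codon: str, alt_codon: str) -> str:
    """Classify a codon change.

    Returns one of 'synonymous', 'nonsynonymous', 'stop_gained', 'stop_lost'.
    Identical translations (including stop -> stop) are synonymous.
    """
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "nonsynonymous"


def cost_matrix_frame():
    """Cost matrix as a labelled pandas DataFrame (for the CLI dump)."""
    import pandas as pd

    labels = list(SYMBOLS)
    return pd.DataFrame(cost_matrix(), index=labels, columns=labels)
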