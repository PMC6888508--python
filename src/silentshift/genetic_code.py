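"""Standard genetic code lookups shared across the package.

Derived once from Biopython's standard (NCBI id 1) codon table. Stop codons
form their own three-member "family" labelled ``*`` so that CoCoPUTs-style
tables, which count stops, can be represented uniformly.
"""

from itertools import product

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"

#: all 64 codons in lexicographic order
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

#: all 4096 ordered codon pairs, as (first, second) tuples
CODON_PAIRS: tuple[tuple[str, str], ...] = tuple(product(CODONS, repeat=2))

STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: codon -> one-letter amino acid, with '*' for stops
CODON_TO_AA: dict[str, str] = {
    c: ("*" if c in STOP_CODONS else _STANDARD.forward_table[c]) for c in CODONS
}

#: amino acid (incl. '*') -> tuple of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: amino acid -> family size n_i (number of synonymous codons)
FAMILY_SIZES: dict[str, int] = {aa: len(cs) for aa, cs in SYNONYMOUS_FAMILIES.items()}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for ``codon`` ('*' for a stop)."""
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not a valid DNA codon: {codon!r}") from None
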