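"""Codon and codon-pair usage tables: counting, RSCU, frequencies, percentiles.

Relative synonymous codon usage (RSCU, Sharp & Li) for codon *j* of the
amino-acid family *i* with counts :math:`X_{ij}`, family total
:math:`T_i = \\sum_j X_{ij}` and family size :math:`n_i` is

.. math:: \\mathrm{RSCU}_{ij} = \\frac{X_{ij}}{T_i / n_i},

so 1 means no bias and values range over :math:`[0, n_i]`. Codon pairs are
ordered adjacent in-frame codons; their usage is summarized as frequency per
million pairs and a strict-less percent rank over all 4096 ordered pairs.

Counts are real-valued so that expression weighting (one weight per CDS,
e.g. a transcript's TPM) runs through the same code path as raw counting —
this is how tissue-weighted usage tables are built from a genome CDS set
plus a tissue expression table.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    CODON_PAIRS,
    CODONS,
    FAMILY_SIZES,
    SYNONYMOUS_FAMILIES,
    translate_codon,
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame protein-coding nucleotide sequence.

    ``seq`` must be non-empty, a multiple of 3 long, and contain only
    A/C/G/T (ambiguity codes are rejected at construction).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq or len(self.seq) % 3 != 0:
            raise ValueError(
                f"CDS {self.id!r}: length {len(self.seq)} is not a positive multiple of 3"
            )
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"CDS {self.id!r}: invalid characters {sorted(bad)} (only A/C/G/T allowed)"
            )

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        """In-frame codons, 5'→3', including the terminal stop if present."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def codon(self, codon_index: int) -> str:
        """Codon by 1-based index."""
        if not 1 <= codon_index <= self.n_codons:
            raise IndexError(f"codon index {codon_index} outside 1..{self.n_codons}")
        return self.seq[3 * (codon_index - 1) : 3 * codon_index]


@dataclass
class ExpressionTable:
    """Per-transcript expression levels (TPM), all non-negative."""

    tpm: dict[str, float]

    def __post_init__(self) -> None:
        for tid, v in self.tpm.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"TPM for {tid!r} must be finite and >= 0, got {v}")

    def __getitem__(self, tid: str) -> float:
        return self.tpm[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.tpm

    def ids(self) -> list[str]:
        return list(self.tpm)


@dataclass
class CodonUsageTable:
    """Real-valued counts over the 64 codons, with RSCU filled on demand.

    ``rscu`` maps codon -> RSCU; codons of families with zero total count
    are absent from the mapping (undefined, not zero).
    """

    scope: str
    counts: dict[str, float]
    rscu: dict[str, float] = field(default_factory=dict)

    family_sizes: Mapping[str, int] = field(default_factory=lambda: dict(FAMILY_SIZES))

    def __post_init__(self) -> None:
        full = {c: 0.0 for c in CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"unknown codon {codon!r} in table {self.scope!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon!r} in table {self.scope!r}")
            full[codon] = float(n)
        self.counts = full

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> float:
        return sum(self.counts[c] for c in SYNONYMOUS_FAMILIES[aa])


@dataclass
class CodonPairTable:
    """Real-valued counts over the 4096 ordered codon pairs.

    ``freq_per_million`` and ``percentile`` are filled by
    :func:`pair_frequencies`; percentiles use a strict-less percent rank
    over all 4096 pairs (×100/4095), so the unique maximum scores 100 and
    any pair tied with the minimum scores 0.
    """

    scope: str
    counts: dict[tuple[str, str], float]
    freq_per_million: dict[tuple[str, str], float] = field(default_factory=dict)
    percentile: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {p: 0.0 for p in CODON_PAIRS}
        for pair, n in self.counts.items():
            if pair not in full:
                raise ValueError(f"unknown codon pair {pair!r} in table {self.scope!r}")
            if n < 0:
                raise ValueError(f"negative count for pair {pair!r} in table {self.scope!r}")
            full[pair] = float(n)
        self.counts = full

    @property
    def total(self) -> float:
        return sum(self.counts.values())


def _weights_for(
    cds_set: list[CodingSequence], weights: ExpressionTable | None
) -> list[float]:
    if not cds_set:
        raise ValueError("empty CDS set")
    if weights is None:
        return [1.0] * len(cds_set)
    out = []
    for cds in cds_set:
        if cds.id not in weights:
            raise KeyError(f"CDS id {cds.id!r} absent from the expression table")
        out.append(weights[cds.id])
    return out


def count_codons(
    cds_set: Iterable[CodingSequence],
    weights: ExpressionTable | None = None,
    scope: str = "cds_set",
) -> CodonUsageTable:
    """Count in-frame codons over a CDS set, optionally TPM-weighted.

    Each sequence contributes its weight (TPM if ``weights`` is given,
    else 1) per codon occurrence, terminal stop included. A CDS id missing
    from ``weights`` raises ``KeyError`` naming the id.
    """
    cds_list = list(cds_set)
    ws = _weights_for(cds_list, weights)
    counts: dict[str, float] = {c: 0.0 for c in CODONS}
    for cds, w in zip(cds_list, ws):
        if w == 0.0:
            continue
        for codon in cds.codons():
            counts[codon] += w
    return CodonUsageTable(scope=scope, counts=counts)


def compute_rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill ``table.rscu`` in place (and return it) per Sharp & Li.

    Families with zero total count have their codons left out of the
    mapping entirely: their RSCU is undefined, not zero.
    """
    rscu: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        t_i = sum(table.counts[c] for c in codons)
        if t_i <= 0:
            continue
        expected = t_i / len(codons)
        for c in codons:
            rscu[c] = table.counts[c] / expected
    table.rscu = rscu
    return table


def count_codon_pairs(
    cds_set: Iterable[CodingSequence],
    weights: ExpressionTable | None = None,
    scope: str = "cds_set",
) -> CodonPairTable:
    """Count ordered adjacent in-frame codon pairs, optionally TPM-weighted.

    A CDS of L codons contributes L−1 overlapping pairs; single-codon
    sequences contribute nothing.
    """
    cds_list = list(cds_set)
    ws = _weights_for(cds_list, weights)
    counts: dict[tuple[str, str], float] = {}
    for cds, w in zip(cds_list, ws):
        if w == 0.0:
            continue
        codons = cds.codons()
        for a, b in zip(codons, codons[1:]):
            key = (a, b)
            counts[key] = counts.get(key, 0.0) + w
    return CodonPairTable(scope=scope, counts=counts)


def pair_frequencies(table: CodonPairTable) -> CodonPairTable:
    """Fill frequency-per-million and percentile ranks in place.

    ``freq_per_million[p] = 1e6 * count[p] / total``; the percentile of a
    pair is the percentage of the other 4095 ordered pairs with strictly
    lower frequency. Raises on an all-zero table.
    """
    total = table.total
    if total <= 0:
        raise ValueError(f"pair table {table.scope!r} has zero total count")
    freqs = np.array([table.counts[p] for p in CODON_PAIRS]) * (1e6 / total)
    order = np.sort(freqs)
    n_below = np.searchsorted(order, freqs, side="left")
    pct = 100.0 * n_below / (len(CODON_PAIRS) - 1)
    table.freq_per_million = dict(zip(CODON_PAIRS, freqs.tolist()))
    table.percentile = dict(zip(CODON_PAIRS, pct.tolist()))
    return table


def translate_cds(cds: CodingSequence) -> str:
    """Amino-acid sequence of the CDS ('*' for stops), via the standard code."""
    return "".join(translate_codon(c) for c in cds.codons())
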