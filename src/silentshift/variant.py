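"""Coding-coordinate variant parsing and codon-context impact reports.

A substitution in HGVS-style coding notation (``c.354G>A``; c.1 is the A of
the start codon) is mapped to its codon, classified as synonymous or not
via the standard genetic code, and — for synonymous changes — scored
against one or more background usage tables: RSCU of the wild-type and
variant codons, and frequency/percentile of the two ordered codon pairs the
focal codon forms with its preceding and following neighbours. Codons are
always derived from the nucleotide sequence, never from row labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .codon_usage import (
    CodingSequence,
    CodonPairTable,
    CodonUsageTable,
    compute_rscu,
    pair_frequencies,
)
from .genetic_code import SYNONYMOUS_FAMILIES, translate_codon

_VARIANT_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class CdsVariant:
    """A single-nucleotide substitution in CDS (c.) coordinates, 1-based."""

    raw: str
    position: int
    ref_base: str
    alt_base: str

    @property
    def codon_index(self) -> int:
        """1-based index of the codon containing the variant position."""
        return (self.position - 1) // 3 + 1

    @property
    def codon_offset(self) -> int:
        """Position of the variant within its codon, in {1, 2, 3}."""
        return (self.position - 1) % 3 + 1

    def __str__(self) -> str:
        return f"c.{self.position}{self.ref_base}>{self.alt_base}"


def parse_variant(raw: str) -> CdsVariant:
    """Parse ``c.<pos><ref>><alt>`` notation into a :class:`CdsVariant`.

    Raises ``ValueError`` naming the offending token for malformed input,
    identical ref/alt bases, or position < 1.
    """
    m = _VARIANT_RE.match(raw.strip())
    if not m:
        raise ValueError(
            f"cannot parse variant {raw!r}: expected c.<position><ref>><alt>, e.g. c.354G>A"
        )
    position = int(m.group(1))
    ref, alt = m.group(2), m.group(3)
    if position < 1:
        raise ValueError(f"variant {raw!r}: position must be >= 1 (c.1 is the first CDS base)")
    if ref == alt:
        raise ValueError(f"variant {raw!r}: reference and alternate base are identical")
    return CdsVariant(raw=raw.strip(), position=position, ref_base=ref, alt_base=alt)


@dataclass(frozen=True)
class CodonContext:
    """The focal codon before/after substitution and its flanking codons.

    ``preceding``/``following`` are ``None`` at CDS boundaries.
    """

    preceding: str | None
    focal_wt: str
    focal_alt: str
    following: str | None
    amino_acid: str
    codon_index: int


def locate_context(cds: CodingSequence, v: CdsVariant) -> CodonContext:
    """Slice the codon context of a variant out of its CDS.

    Verifies that the base at ``v.position`` matches ``v.ref_base``; a
    mismatch raises with expected vs. found, which guards against off-by-one
    coordinate conventions.
    """
    if v.position > len(cds.seq):
        raise ValueError(
            f"variant position {v.position} beyond CDS {cds.id!r} of length {len(cds.seq)}"
        )
    found = cds.seq[v.position - 1]
    if found != v.ref_base:
        raise ValueError(
            f"reference base mismatch at c.{v.position} of {cds.id!r}: "
            f"variant says {v.ref_base}, CDS has {found}"
        )
    idx = v.codon_index
    wt = cds.codon(idx)
    off = v.codon_offset - 1
    alt = wt[:off] + v.alt_base + wt[off + 1 :]
    preceding = cds.codon(idx - 1) if idx > 1 else None
    following = cds.codon(idx + 1) if idx < cds.n_codons else None
    return CodonContext(
        preceding=preceding,
        focal_wt=wt,
        focal_alt=alt,
        following=following,
        amino_acid=translate_codon(wt),
        codon_index=idx,
    )


def classify(context: CodonContext) -> tuple[bool, str]:
    """Synonymy flag and protein notation (``p.P118P`` style) for a context.

    Stop codons on either side are out of scope (nonsense/readthrough) and
    raise ``ValueError``.
    """
    aa_wt = translate_codon(context.focal_wt)
    aa_alt = translate_codon(context.focal_alt)
    if aa_wt == "*" or aa_alt == "*":
        raise ValueError(
            f"stop codon in context ({context.focal_wt}->{context.focal_alt}): "
            "nonsense and readthrough variants are out of scope"
        )
    return aa_wt == aa_alt, f"p.{aa_wt}{context.codon_index}{aa_alt}"


@dataclass(frozen=True)
class CodonImpactRow:
    """Usage figures for one candidate codon at the focal position."""

    codon: str
    role: str  # "wt", "alt" or "syn" (other synonymous codon)
    rscu: float | None
    preceding_freq: float | None
    preceding_percentile: float | None
    following_freq: float | None
    following_percentile: float | None


@dataclass(frozen=True)
class BackgroundImpact:
    scope: str
    rows: tuple[CodonImpactRow, ...]


@dataclass
class VariantImpactReport:
    """Per-background usage consequences of a coding substitution.

    For a non-synonymous variant the usage fields are absent and
    ``warning`` explains why; backgrounds appear in input order.
    """

    variant: CdsVariant
    context: CodonContext
    synonymous: bool
    protein_notation: str
    backgrounds: list[BackgroundImpact] = field(default_factory=list)
    warning: str | None = None

    def rscu_frame(self) -> pd.DataFrame:
        """Tidy RSCU table: one row per (background, codon)."""
        recs = [
            {"background": bg.scope, "codon": r.codon, "role": r.role, "rscu": r.rscu}
            for bg in self.backgrounds
            for r in bg.rows
        ]
        return pd.DataFrame(recs)

    def pairs_frame(self) -> pd.DataFrame:
        """Tidy codon-pair table: one row per (background, codon)."""
        recs = []
        for bg in self.backgrounds:
            for r in bg.rows:
                recs.append(
                    {
                        "background": bg.scope,
                        "codon": r.codon,
                        "role": r.role,
                        "preceding_pair": (
                            f"{self.context.preceding}-{r.codon}" if self.context.preceding else None
                        ),
                        "preceding_freq_per_million": r.preceding_freq,
                        "preceding_percentile": r.preceding_percentile,
                        "following_pair": (
                            f"{r.codon}-{self.context.following}" if self.context.following else None
                        ),
                        "following_freq_per_million": r.following_freq,
                        "following_percentile": r.following_percentile,
                    }
                )
        return pd.DataFrame(recs)


def _impact_row(
    codon: str,
    role: str,
    context: CodonContext,
    usage: CodonUsageTable,
    pairs: CodonPairTable,
) -> CodonImpactRow:
    rscu = usage.rscu.get(codon)
    pre_f = pre_p = fol_f = fol_p = None
    if context.preceding is not None:
        key = (context.preceding, codon)
        pre_f = pairs.freq_per_million[key]
        pre_p = pairs.percentile[key]
    if context.following is not None:
        key = (codon, context.following)
        fol_f = pairs.freq_per_million[key]
        fol_p = pairs.percentile[key]
    return CodonImpactRow(codon, role, rscu, pre_f, pre_p, fol_f, fol_p)


def build_report(
    cds: CodingSequence,
    v: CdsVariant,
    backgrounds: list[tuple[CodonUsageTable, CodonPairTable]],
    include_all_synonyms: bool = False,
) -> VariantImpactReport:
    """Assemble the full impact report for one variant.

    For each background (a codon table and a pair table, derived or RSCU/
    frequency columns filled here if missing) the report carries RSCU of
    the wild-type and variant codons plus frequency-per-million and
    percentile of the (preceding, focal) and (focal, following) pairs;
    with ``include_all_synonyms`` every other codon of the amino-acid
    family gets a row too. Non-synonymous variants yield a report with the
    usage fields absent and a warning, not an error.
    """
    context = locate_context(cds, v)
    synonymous, notation = classify(context)
    report = VariantImpactReport(
        variant=v, context=context, synonymous=synonymous, protein_notation=notation
    )
    if not synonymous:
        report.warning = (
            f"{v} is non-synonymous ({notation}); codon-usage shift analysis "
            "applies to synonymous substitutions only"
        )
        return report

    family = SYNONYMOUS_FAMILIES[context.amino_acid]
    for usage, pairs in backgrounds:
        if not usage.rscu:
            compute_rscu(usage)
        if not pairs.freq_per_million:
            pair_frequencies(pairs)
        if all(c not in usage.rscu for c in family):
            raise ValueError(
                f"background {usage.scope!r} has zero counts for the entire "
                f"{context.amino_acid} family; cannot score {v}"
            )
        rows = [
            _impact_row(context.focal_wt, "wt", context, usage, pairs),
            _impact_row(context.focal_alt, "alt", context, usage, pairs),
        ]
        if include_all_synonyms:
            for codon in family:
                if codon not in (context.focal_wt, context.focal_alt):
                    rows.append(_impact_row(codon, "syn", context, usage, pairs))
        report.backgrounds.append(BackgroundImpact(scope=usage.scope, rows=tuple(rows)))
    return report
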