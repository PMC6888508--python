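"""Readers and writers for the package's plain-text interchange formats.

Formats:

* CDS sets — multi-record FASTA (wrapped lines fine), read with Biopython.
* Background usage tables — CoCoPUTs-style TSV with header ``codon\\tcount``
  or ``codon_pair\\tcount`` (pair written ``AAA-AAC``); writers add the
  derived columns (``rscu`` / ``freq_per_million`` + ``percentile``).
* Expression — TSV ``id\\ttpm`` with header.
* Read alignments — TSV ``transcript_id\\tfive_prime\\tlength`` with header,
  ``five_prime`` 0-based on the transcript.
* Transcript models — TSV ``id\\tlength\\tcds_start\\tcds_end`` with header,
  0-based half-open CDS interval.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .codon_usage import (
    CodingSequence,
    CodonPairTable,
    CodonUsageTable,
    ExpressionTable,
)
from .genetic_code import CODON_PAIRS, CODONS
from .ribo import FootprintAlignment, TranscriptModel


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Load a CDS set from FASTA; every record is validated on construction."""
    records = [
        CodingSequence(id=rec.id, seq=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_cds_fasta(cds_set: list[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cds in cds_set:
            header = f">{cds.id}" + (f" {cds.description}" if cds.description else "")
            fh.write(header + "\n")
            for i in range(0, len(cds.seq), 60):
                fh.write(cds.seq[i : i + 60] + "\n")


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["id", "tpm"], path)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate transcript id {dup!r} in {path}")
    return ExpressionTable(tpm=dict(zip(df["id"].astype(str), df["tpm"].astype(float))))


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    pd.DataFrame({"id": table.ids(), "tpm": [table[t] for t in table.ids()]}).to_csv(
        path, sep="\t", index=False
    )


def read_codon_table_tsv(path: str | Path, scope: str | None = None) -> CodonUsageTable:
    """Load a CoCoPUTs-style ``codon\\tcount`` TSV as a codon usage table."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["codon", "count"], path)
    counts = dict(zip(df["codon"].str.upper(), df["count"].astype(float)))
    return CodonUsageTable(scope=scope or str(path), counts=counts)


def read_pair_table_tsv(path: str | Path, scope: str | None = None) -> CodonPairTable:
    """Load a ``codon_pair\\tcount`` TSV; pairs are written ``AAA-AAC``."""
    df = pd.read_csv(path, sep="\t")
    _require(df, ["codon_pair", "count"], path)
    counts = {}
    for raw, n in zip(df["codon_pair"].str.upper(), df["count"].astype(float)):
        first, _, second = raw.partition("-")
        if not second:
            raise ValueError(f"malformed codon pair {raw!r} in {path} (expected AAA-AAC)")
        counts[(first, second)] = n
    return CodonPairTable(scope=scope or str(path), counts=counts)


def write_codon_table_tsv(table: CodonUsageTable, path: str | Path) -> None:
    rows = {
        "codon": list(CODONS),
        "count": [table.counts[c] for c in CODONS],
    }
    if table.rscu:
        rows["rscu"] = [table.rscu.get(c, float("nan")) for c in CODONS]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_pair_table_tsv(table: CodonPairTable, path: str | Path) -> None:
    rows = {
        "codon_pair": [f"{a}-{b}" for a, b in CODON_PAIRS],
        "count": [table.counts[p] for p in CODON_PAIRS],
    }
    if table.freq_per_million:
        rows["freq_per_million"] = [table.freq_per_million[p] for p in CODON_PAIRS]
        rows["percentile"] = [table.percentile[p] for p in CODON_PAIRS]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_alignments_tsv(path: str | Path) -> list[FootprintAlignment]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["transcript_id", "five_prime", "length"], path)
    return [
        FootprintAlignment(str(t), int(f), int(n))
        for t, f, n in zip(df["transcript_id"], df["five_prime"], df["length"])
    ]


def write_alignments_tsv(reads: list[FootprintAlignment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in reads],
            "five_prime": [r.five_prime for r in reads],
            "length": [r.length for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def read_models_tsv(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["id", "length", "cds_start", "cds_end"], path)
    return [
        TranscriptModel(str(i), int(n), int(s), int(e))
        for i, n, s, e in zip(df["id"], df["length"], df["cds_start"], df["cds_end"])
    ]


def write_models_tsv(models: list[TranscriptModel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [m.id for m in models],
            "length": [m.length for m in models],
            "cds_start": [m.cds_start for m in models],
            "cds_end": [m.cds_end for m in models],
        }
    ).to_csv(path, sep="\t", index=False)


def _require(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header required")
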