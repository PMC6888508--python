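"""Generative models for every input the pipeline consumes.

The simulator emulates, with known ground truth, the statistical structure
the analysis stages assume:

* **CDS sets** — amino-acid backbones drawn uniformly over the 20 residues
  (start ATG, one terminal stop, no internal stops), with each codon drawn
  within its synonymous family proportionally to a target RSCU, so the
  usage-table stage can be checked for parameter recovery.
* **Expression** — log-normal TPM, the canonical shape of bulk expression.
* **Ribo-seq libraries** — transcripts get fixed-length UTRs around each
  CDS; mRNA fragments fall uniformly over transcripts chosen proportional
  to TPM × length; footprint (RPF) abundance per transcript is proportional
  to its realized mRNA CDS density times an intended translation-efficiency
  multiplier, with each footprint's P-site codon drawn proportional to a
  per-codon dwell weight and its 5' end placed ``true_offset`` nt upstream
  of the P-site. Per-transcript read totals are multinomial given the
  library depth, so totals are exact and every draw is reproducible
  byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_usage import CodingSequence, ExpressionTable
from .genetic_code import SYNONYMOUS_FAMILIES, translate_codon
from .ribo import FootprintAlignment, TranscriptModel

_SENSE_AAS = tuple(sorted(aa for aa in SYNONYMOUS_FAMILIES if aa != "*"))


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of the generative model.

    Defaults describe a small but realistic study: 50 transcripts of 300
    codons, log-normal TPM (log-mean 2, log-sd 1, i.e. median ~7 TPM),
    uniform codon usage and dwell times unless overridden, the canonical
    12-nt P-site offset, footprint lengths concentrated at 28–30 nt with a
    minor 20–22 nt class, 50-nt UTRs (so any offset ≤ 18 nt is
    representable) and 10^5 reads per library.
    """

    seed: int = 0
    n_sequences: int = 50
    codons_per_seq: int = 300
    target_rscu: dict[str, float] = field(default_factory=dict)
    tpm_logmean: float = 2.0
    tpm_logsd: float = 1.0
    dwell_weights: dict[str, float] = field(default_factory=dict)
    true_offset: int = 12
    rpf_length_dist: dict[int, float] = field(
        default_factory=lambda: {20: 0.03, 21: 0.04, 22: 0.03, 28: 0.35, 29: 0.35, 30: 0.20}
    )
    depth: int = 100_000
    mrna_min_length: int = 25
    mrna_max_length: int = 35
    utr5: int = 50
    utr3: int = 50
    te_multipliers: dict[str, float] = field(default_factory=dict)
    #: occupancy multiplier at the start codon (the initiation peak seen in
    #: real footprint data); this is what makes the 5'→P-site offset
    #: identifiable from the start-codon metagene. Set to 1 for flat profiles.
    init_boost: float = 4.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _family_probs(config: GeneratorConfig) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-family codon sampling probabilities from the target RSCU."""
    out = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        w = np.array([config.target_rscu.get(c, 1.0) for c in codons], dtype=float)
        if (w < 0).any():
            raise ValueError(f"negative target RSCU in family {aa!r}")
        if w.sum() == 0:
            raise ValueError(f"target RSCU is zero for the entire {aa!r} family")
        out[aa] = (codons, w / w.sum())
    return out


def gen_cds(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[CodingSequence]:
    """Draw a codon-biased CDS set with known target RSCU.

    Every sequence starts with ATG, ends with one stop codon and contains
    no internal stop; interior codons are drawn within the family of a
    uniformly chosen amino acid, proportional to ``target_rscu``.
    """
    rng = config.rng() if rng is None else rng
    fams = _family_probs(config)
    stop_codons, stop_p = fams["*"]
    n_interior = max(config.codons_per_seq - 2, 0)
    total = config.n_sequences * n_interior
    aa_idx = rng.choice(len(_SENSE_AAS), size=total)
    interior = np.empty(total, dtype="<U3")
    for k, aa in enumerate(_SENSE_AAS):
        mask = aa_idx == k
        m = int(mask.sum())
        if m:
            codon_set, p = fams[aa]
            interior[mask] = np.array(codon_set)[rng.choice(len(codon_set), size=m, p=p)]
    stops = np.array(stop_codons)[rng.choice(len(stop_codons), size=config.n_sequences, p=stop_p)]
    seqs = []
    for i in range(config.n_sequences):
        body = interior[i * n_interior : (i + 1) * n_interior]
        seqs.append(
            CodingSequence(
                id=f"synth{i:04d}",
                seq="ATG" + "".join(body) + str(stops[i]),
                description="synthetic CDS",
            )
        )
    return seqs


def gen_expression(
    config: GeneratorConfig, ids: list[str], rng: np.random.Generator | None = None
) -> ExpressionTable:
    """Log-normal TPM table over ``ids`` (natural-log parameters)."""
    if not ids:
        raise ValueError("no transcript ids given")
    rng = config.rng() if rng is None else rng
    tpm = np.exp(rng.normal(config.tpm_logmean, config.tpm_logsd, size=len(ids)))
    return ExpressionTable(tpm=dict(zip(ids, tpm.tolist())))


def gen_ribo_libraries(
    config: GeneratorConfig,
    cds_set: list[CodingSequence],
    expression: ExpressionTable,
    rng: np.random.Generator | None = None,
) -> tuple[list[FootprintAlignment], list[FootprintAlignment], list[TranscriptModel]]:
    """Draw matched RPF and mRNA libraries from the dwell-weight model.

    Returns ``(rpf_reads, mrna_reads, models)``. mRNA fragments are uniform
    over transcripts (chosen ∝ TPM × length); footprints per transcript are
    multinomial with weights ∝ realized mRNA CDS count × TE multiplier, and
    within a transcript each footprint's P-site codon is drawn ∝ the dwell
    weight of the codon's nucleotide triplet.
    """
    rng = config.rng() if rng is None else rng
    if config.true_offset > config.utr5:
        raise ValueError(
            f"true_offset {config.true_offset} exceeds the 5' UTR ({config.utr5} nt): "
            "footprints would start before the transcript"
        )
    max_rpf_len = max(config.rpf_length_dist)
    if config.utr3 < max_rpf_len:
        raise ValueError(
            f"3' UTR ({config.utr3} nt) shorter than the longest footprint "
            f"({max_rpf_len} nt); terminal footprints would overrun the transcript"
        )
    models = [
        TranscriptModel(
            id=cds.id,
            length=config.utr5 + len(cds.seq) + config.utr3,
            cds_start=config.utr5,
            cds_end=config.utr5 + len(cds.seq),
        )
        for cds in cds_set
    ]
    if config.depth == 0:
        return [], [], models

    # --- mRNA library: transcript ∝ TPM × length, 5' uniform, length uniform
    lengths = np.array([m.length for m in models])
    tpm = np.array([expression[m.id] for m in models])
    w = tpm * lengths
    if w.sum() == 0:
        raise ValueError("all transcripts have zero TPM·length; nothing to sequence")
    n_per_transcript = rng.multinomial(config.depth, w / w.sum())
    mrna_reads: list[FootprintAlignment] = []
    frag_lengths = np.arange(config.mrna_min_length, config.mrna_max_length + 1)
    for model, n in zip(models, n_per_transcript):
        if n == 0:
            continue
        ls = frag_lengths[rng.integers(0, len(frag_lengths), size=n)]
        starts = rng.integers(0, model.length - ls + 1)
        mrna_reads.extend(
            FootprintAlignment(model.id, int(s), int(l)) for s, l in zip(starts, ls)
        )

    # --- RPF library: transcript ∝ mRNA CDS count × TE multiplier
    mrna_cds = np.zeros(len(models))
    index = {m.id: i for i, m in enumerate(models)}
    for read in mrna_reads:
        m = models[index[read.transcript_id]]
        if m.cds_start <= read.five_prime < m.cds_end:
            mrna_cds[index[read.transcript_id]] += 1
    mult = np.array([config.te_multipliers.get(m.id, 1.0) for m in models])
    w_rpf = mrna_cds * mult
    if w_rpf.sum() == 0:
        raise ValueError("no mRNA coverage in any CDS; cannot place footprints")
    n_rpf = rng.multinomial(config.depth, w_rpf / w_rpf.sum())

    rpf_lengths = np.array(sorted(config.rpf_length_dist))
    rpf_p = np.array([config.rpf_length_dist[l] for l in rpf_lengths], dtype=float)
    rpf_p = rpf_p / rpf_p.sum()
    cds_by_id = {c.id: c for c in cds_set}
    rpf_reads: list[FootprintAlignment] = []
    for model, n in zip(models, n_rpf):
        if n == 0:
            continue
        codons = [
            cds_by_id[model.id].seq[i : i + 3]
            for i in range(0, model.cds_end - model.cds_start, 3)
        ]
        dwell = np.array([config.dwell_weights.get(c, 1.0) for c in codons], dtype=float)
        dwell[0] *= config.init_boost
        if dwell.sum() == 0:
            raise ValueError(f"all dwell weights zero on transcript {model.id!r}")
        codon_counts = rng.multinomial(n, dwell / dwell.sum())
        ls = rpf_lengths[rng.choice(len(rpf_lengths), size=n, p=rpf_p)]
        pos = 0
        for c_idx, k in enumerate(codon_counts):
            psite = model.cds_start + 3 * c_idx
            for _ in range(k):
                rpf_reads.append(
                    FootprintAlignment(model.id, psite - config.true_offset, int(ls[pos]))
                )
                pos += 1
    return rpf_reads, mrna_reads, models


def synthetic_p118_cds(
    config: GeneratorConfig | None = None, n_codons: int = 150
) -> CodingSequence:
    """Synthetic CDS embedding the GAC·CCG·TCC context at codons 117–119.

    A stand-in, generated from the simulator's codon model, for a real
    protease transcript in which the proline at residue 118 is encoded by
    CCG flanked by GAC (Asp) and TCC (Ser); only those three codons are
    fixed — everything else is random. Intended for variant-context tests
    where c.354G>A must map onto codon 118.
    """
    if n_codons < 120:
        raise ValueError("need at least 120 codons to place the context at 117-119")
    config = config or GeneratorConfig(seed=118, codons_per_seq=n_codons, n_sequences=1)
    cds = gen_cds(config)[0]
    codons = [cds.seq[i : i + 3] for i in range(0, len(cds.seq), 3)]
    codons[116:119] = ["GAC", "CCG", "TCC"]
    seq = "".join(codons)
    out = CodingSequence(
        id="synthetic_P118",
        seq=seq,
        description="synthetic CDS with GAC-CCG-TCC at codons 117-119",
    )
    assert translate_codon(out.codon(118)) == "P"
    return out
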