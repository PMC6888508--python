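# Methods

`silentshift` quantifies how a synonymous coding substitution changes its
local codon-usage context, and provides the downstream quantitation of a
ribosome-profiling experiment that asks whether such a change is visible in
translation. This note records the models, the defaults and why, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## Codon usage and codon pairs

**RSCU.** For codon *j* of amino-acid family *i* with counts X_ij, family
total T_i and family size n_i (Sharp & Li):

    RSCU_ij = X_ij / (T_i / n_i)

RSCU is 1 under uniform synonymous usage and ranges over [0, n_i]. Families
with T_i = 0 have *undefined* RSCU and are reported as missing, never as 0
— a zero would wrongly claim the codon is avoided when it is simply
unobserved. Counts are real-valued so that expression weighting (below)
shares the raw-counting code path exactly.

**Codon pairs.** All 4096 ordered pairs of adjacent in-frame codons are
indexed; a CDS of L codons contributes L−1 overlapping pairs. Usage is
summarized as frequency per million pairs, and as a percentile rank:

    percentile(p) = 100 × #{q : freq(q) < freq(p)} / 4095

i.e. a strict-less percent rank over all 4096 ordered pairs. This is the
simplest rank statistic that yields 0 for any pair tied with the minimum
and 100 for a unique maximum; a midpoint (average-tie) rank was the main
alternative and differs only in how ties are split. Percentile is weakly
monotone in frequency by construction.

**Stop codons** are counted in both codon and pair tables (public
codon-usage compendia include them); the stop "family" gets RSCU like any
other but is excluded from variant reports, since stop-gain/readthrough is
out of scope.

**Tissue weighting.** A tissue-specific table is the genome CDS table with
each sequence's contribution multiplied by its expression (TPM) in that
tissue. Weighting is per sequence record; aggregating transcript-level to
gene-level TPM is the caller's responsibility. RSCU and percentiles are
invariant to rescaling all TPMs by a constant (only ratios matter), which
the tests assert.

## Variant mapping and the impact report

Coordinates follow the HGVS coding convention: c.1 is the first base of
the CDS (the A of ATG), so position p lies in codon ⌈p/3⌉ at offset
((p−1) mod 3)+1. The reference base stated in the descriptor is checked
against the sequence and a mismatch is a hard error — this is the guard
that catches off-by-one coordinate mistakes. Synonymy is decided by
translating the wild-type and substituted codons under the standard
genetic code; variant and focal codons are always derived from the
nucleotides, never from a row label (printed tables elsewhere have been
known to swap third-base G>C / G>T labels between CCC and CCT; deriving
from chemistry makes such swaps impossible here).

The report carries, per background table and in input order: RSCU of the
wild-type and variant codons, and frequency-per-million plus percentile of
the two ordered context pairs (preceding, focal) and (focal, following) —
optionally for every synonymous codon of the family. At CDS boundaries the
missing flank's cells are absent, not zero. Non-synonymous input degrades
to a report with a warning rather than an error, so the tool stays usable
in screens; synonymy gates only the usage-shift fields.

## Ribosome-profiling quantitation

Input is transcript-coordinate alignments (5′ position, fragment length)
plus CDS intervals; alignment itself, rRNA cleanup and multi-mapping
resolution are upstream of this package.

**Length filtering** keeps ribosome-protected fragments of 20–22 and
28–30 nt (the two footprint classes of mammalian ribo-seq; defaults) and
mRNA fragments ≥ 25 nt.

**P-site offset.** Each footprint is assigned to the codon located a fixed
offset downstream of its 5′ end. The offset is calibrated from the
start-codon metagene: over reads with cds_start − five_prime = d ∈ [0, 18],
the calibrated offset is the modal d. Ties break toward the canonical
mammalian 12 nt, then toward the smaller value. Calibration is pooled over
fragment lengths by default (a single global offset, matching common
mammalian practice); `by_length=True` calibrates each length separately.
The modal-d estimator is identifiable because initiation enriches
footprints whose P-site is the start codon itself; on data without a start
peak the metagene is flat and the estimate is meaningless — hence the
generator models the peak (below).

**Occupancy.** With N_c reads P-site-assigned to codon c, N_CDS their
total and L_CDS the CDS length in codons,

    normalized_c = N_c / (N_CDS / L_CDS)

so mean(normalized) = 1 and Σ normalized = L_CDS for every non-empty
profile. Reads whose P-site falls in a UTR are excluded from N_CDS. A
transcript with no CDS-assigned reads yields an all-zero profile flagged
`empty` (not NaN), keeping cumulative sums well defined. Cumulative
profiles sum `normalized` along the CDS, optionally after log1p — log1p
rather than log because zero-occupancy codons are common at realistic
depth.

**RPKM and TE.** RPKM = 10⁹ × reads / (CDS length in nt × library size);
TE = RPF RPKM / mRNA RPKM per transcript, absent (with a warning) when the
mRNA density is zero. Library sizes in `summarize_te` are the totals of
*CDS-assigned* reads in each library, so both densities are normalized
over the same coding territory: the library-wide mean TE is then ~1 and
feeding one library as both inputs returns TE exactly 1. RPF counts use
the P-site convention; mRNA counts use the 5′-end-in-CDS convention (no
ribosome geometry applies to RNA fragments).

## The synthetic-data generator

The generator is the package's ground-truth instrument: every pipeline
stage is validated by recovering a parameter the generator set.

* **CDS sets** — amino-acid backbones uniform over the 20 residues; within
  each family, codons drawn with probabilities proportional to a target
  RSCU; ATG start, one terminal stop, no internal stops by construction.
  Defaults: 50 sequences × 300 codons, a typical small transcriptome slice.
* **Expression** — log-normal TPM (log-mean 2.0, log-sd 1.0: median ≈ 7
  TPM with a realistic right tail).
* **Libraries** — transcripts get 50-nt UTRs (any offset ≤ 18 nt is
  representable); mRNA fragments fall on transcripts chosen ∝ TPM × length,
  with uniform 5′ ends and lengths uniform on 25–35 nt. Footprint counts
  per transcript are multinomial (library totals exact) with weights
  ∝ realized mRNA CDS count × TE multiplier — footprint density
  proportional to mRNA density times TE is the definition of TE, so the
  multiplier is the recoverable ground truth. Within a transcript each
  footprint's P-site codon is drawn ∝ a per-codon dwell weight, the 5′ end
  is placed `true_offset` (default 12) nt upstream, and the length comes
  from a distribution concentrated at 28–30 nt with a minor 20–22 nt
  class. The start codon's dwell is multiplied by `init_boost` (default
  4), modelling the initiation peak of real footprint data; without it the
  start-codon metagene is flat and *no* estimator of the modal-d form can
  identify the offset. Tests of occupancy flatness set `init_boost=1`
  explicitly.

Fixed seed ⇒ byte-identical FASTA/TSV outputs (asserted). Not emulated:
sequencing error, rRNA/tRNA contamination, alignment ambiguity, nucleotide
composition of UTRs (reads are coordinates, not sequences), codon
autocorrelation along real genes, and biological replicate structure.
Passing recovery tests therefore shows the estimators are correct under
the stated generative model, not that they are robust to artifacts real
libraries contain.

A small fixture, `synthetic_p118_cds`, embeds the GAC·CCG·TCC context at
codons 117–119 of an otherwise random 150-codon CDS so that c.354G>A maps
to a proline codon 118 with defined flanks; it is synthetic and shares
nothing else with any real transcript.

## Problem sizes and statistical tolerances

Recovery checks run at desk scale: offset recovery at depth 5,000 (exact
for any true offset in [0, 18]); TE recovery at depth 10⁵ over 50
transcripts (the 1.3× multiplier is recovered within 5%, the sampling sd
being ≈ 3.5% at that depth); dwell-weight and flat-occupancy convergence
at depth 10⁵ with a 3-SE band per codon (3.5 SE when ~200 codons are
tested simultaneously, the family-wise equivalent). Generator RSCU
fidelity uses a 0.05 absolute band at 10⁶ codons: at that size the
binomial sd of RSCU is ≤ 0.01 for every family, making 0.05 a ≥ 5σ bound;
at much smaller sizes the same band is a ~1.6σ event per codon for
six-codon families and would fail for any correct sampler. Background
tables for codon-pair percentile analyses use ≥ 3×10⁵ codons — with only
tens of thousands of codons most of the 4096 pairs have near-zero counts
and percentile shifts degenerate to ties.

## Known limitations

* Percentile convention: public codon-pair compendia do not state their
  rank convention; a midpoint-rank variant would shift mid-scale values by
  up to half the tie mass. Comparisons against externally published
  percentiles should use the same snapshot and convention.
* The reference-transcript RSCU check requires the real RefSeq CDS
  (NM_139025.4); it is not redistributed here and must be supplied at
  `data/external/NM_139025.4_cds.fasta` by the user.
* TE is a per-transcript ratio; no statistical comparison machinery
  (replicates, tests) is included.
* `calibrate_offset` assumes uniquely resolved alignments; multi-mapped
  reads must be resolved upstream.
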