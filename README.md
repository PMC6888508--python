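# silentshift

Synonymous ("silent") coding variants change no amino acid, yet some change
how well a protein is made. One mechanism is local codon usage: replacing a
rare codon with a common synonym, or a rare codon *pair* with a common one,
can alter translation. `silentshift` is a small pipeline for analysing
exactly that, built around the case of a CCG→CCA proline substitution
(c.354G>A, p.P118P) in a plasma-protease transcript:

* **Codon-usage tables** — count codons and ordered adjacent codon pairs
  over any CDS set (optionally weighting each transcript by its TPM to get
  tissue-specific usage), compute relative synonymous codon usage
  (RSCU = X_ij / (T_i/n_i); 1 = no bias), frequency per million codon
  pairs, and percentile ranks over all 4096 ordered pairs.
* **Variant impact reports** — parse a substitution in HGVS-style coding
  notation (c.1 = A of ATG), map it to its codon and flanking codon pairs,
  classify synonymy under the standard genetic code, and tabulate the
  usage shift (wild-type vs. variant RSCU, context-pair frequencies and
  percentiles) against any number of background tables.
* **Ribosome-profiling quantitation** — filter footprints to the 20–22 /
  28–30 nt classes, calibrate the 5′→P-site offset from the start-codon
  metagene, build per-codon normalized occupancy
  `N_c / (N_CDS / L_CDS)` (mean 1 per CDS), cumulative occupancy
  profiles, and per-transcript translation efficiency
  TE = RPF RPKM / mRNA RPKM.
* **A generative simulator** — codon-biased CDS sets with controllable
  RSCU, log-normal TPM, and matched RPF/mRNA libraries from a per-codon
  dwell-weight model with a configurable P-site offset, so every stage can
  be validated by parameter recovery without any external data.

It is aimed at people analysing candidate synonymous variants who want the
codon/codon-pair arithmetic and the downstream ribo-seq quantitation in
one tested, scriptable place.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py --seed 1   # CDS set, TPM, RPF+mRNA reads
python analysis/02_usage_tables.py               # background usage tables
python analysis/03_variant_impact.py             # c.354G>A impact report
python analysis/04_ribo_profiling.py             # occupancy, TE, figure
```

Output of the run above:

```
unweighted proline RSCU: CCG 0.38, CCA 1.23, CCC 1.19, CCT 1.20
tissue-weighted proline RSCU: CCG 0.30, CCA 1.45, CCC 1.14, CCT 1.11

c.354G>A -> p.P118P (synonymous)
[background.codons] RSCU CCG 0.38 -> CCA 1.23; GAC-pair percentile 0.0 -> 83.7; TCC-pair percentile 48.5 -> 61.8
[background_tissue.codons] RSCU CCG 0.30 -> CCA 1.45; GAC-pair percentile 0.0 -> 87.5; TCC-pair percentile 43.6 -> 91.8

P-site offset used: 12 nt (mode: auto)
TE of synth0010 (simulated 1.3x): 1.284
TE of the other 49 transcripts: median 0.992 (IQR 0.972-1.015)
Mean normalized occupancy over non-empty profiles: 0.999998..1.000001 (conservation requires 1)
```

Reading this: the simulated background depletes CCG within the proline
family (RSCU 0.38 ≪ 1), so the synonymous change to CCA lands on a much
commoner codon (1.23) and both codon pairs it forms with its GAC/TCC
neighbours jump up the percentile scale — the usage-shift signature of an
expression-enhancing silent variant. Downstream, the metagene calibration
recovers the 12-nt offset the reads were generated with, occupancy
normalization conserves a mean of exactly 1 per transcript, and the
transcript simulated with a 1.3× translation-efficiency multiplier is
quantified at TE 1.28 against a background of TE ≈ 1.

The same stages are available as a CLI (`silentshift simulate | tables |
impact | riboprof`) and as plain library calls; see `docs/methods.md` for
the models, conventions and limitations.

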