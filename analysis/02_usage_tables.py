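"""Build background codon / codon-pair usage tables from the simulated CDS set.

Produces two backgrounds: the raw (unweighted) usage of the CDS set and a
tissue-style table in which every sequence is weighted by its TPM — the
same construction that turns a genome-wide CDS table plus tissue expression
into tissue-specific usage. Writes TSVs under results/tables/ and prints
the proline RSCU column of each so the codon-bias structure is visible.

Run after 01_simulate_inputs.py: python analysis/02_usage_tables.py
"""

import argparse
from pathlib import Path

from silentshift import io
from silentshift.workflows import run_tables_workflow


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", default="results/simulated")
    ap.add_argument("--outdir", default="results/tables")
    args = ap.parse_args()
    indir, outdir = Path(args.indir), Path(args.outdir)

    plain = run_tables_workflow(indir / "cds.fasta", outdir / "background", scope="cds-set")
    weighted = run_tables_workflow(
        indir / "cds.fasta",
        outdir / "background_tissue",
        tpm_tsv=indir / "expression.tsv",
        scope="tissue-weighted",
    )
    for label, paths in (("unweighted", plain), ("tissue-weighted", weighted)):
        table = io.read_codon_table_tsv(paths["codon_table"])
        from silentshift import compute_rscu

        compute_rscu(table)
        rscu = {c: table.rscu[c] for c in ("CCG", "CCA", "CCC", "CCT")}
        print(f"{label} proline RSCU: " + ", ".join(f"{c} {v:.2f}" for c, v in rscu.items()))
    print(f"Tables written under {outdir}/")


if __name__ == "__main__":
    main()
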