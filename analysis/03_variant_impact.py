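"""Score the synonymous substitution c.354G>A against the usage backgrounds.

The query is a synthetic CDS carrying the GAC·CCG·TCC context at codons
117-119, so c.354G>A maps to the third base of the proline codon 118
(p.P118P, CCG->CCA). The report gives, per background: RSCU of the
wild-type and variant codons (plus the other two proline codons) and the
frequency-per-million and percentile of the GAC·CCx and CCx·TCC codon
pairs. Against a CCG-depleted background the variant must move both
context pairs up the percentile scale.

Run after 02_usage_tables.py: python analysis/03_variant_impact.py
"""

import argparse
from pathlib import Path

from silentshift import io
from silentshift.simulate import synthetic_p118_cds
from silentshift.workflows import run_impact_workflow


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tables", default="results/tables")
    ap.add_argument("--outdir", default="results/impact")
    args = ap.parse_args()
    tables, outdir = Path(args.tables), Path(args.outdir)

    query = outdir / "query_cds.fasta"
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_cds_fasta([synthetic_p118_cds()], query)

    backgrounds = [
        (tables / "background.codons.tsv", tables / "background.pairs.tsv"),
        (tables / "background_tissue.codons.tsv", tables / "background_tissue.pairs.tsv"),
    ]
    report = run_impact_workflow(
        query, "c.354G>A", backgrounds, outdir, include_self_background=False
    )
    print(f"{report.variant} -> {report.protein_notation} "
          f"({'synonymous' if report.synonymous else 'non-synonymous'})")
    for bg in report.backgrounds:
        wt, alt = bg.rows[0], bg.rows[1]
        print(
            f"[{bg.scope}] RSCU {wt.codon} {wt.rscu:.2f} -> {alt.codon} {alt.rscu:.2f}; "
            f"GAC-pair percentile {wt.preceding_percentile:.1f} -> {alt.preceding_percentile:.1f}; "
            f"TCC-pair percentile {wt.following_percentile:.1f} -> {alt.following_percentile:.1f}"
        )
    print(f"Full report: {outdir}/impact_report.md")


if __name__ == "__main__":
    main()
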