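"""End-to-end workflows tying the analysis stages together.

Each workflow is a pure function of its inputs and parameters: given the
same files, flags and seed it writes byte-identical outputs, plus a
machine-readable provenance YAML recording inputs, parameters and package
version. The CLI in :mod:`silentshift.cli` and the numbered scripts under
``analysis/`` are thin wrappers over these functions.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .codon_usage import (
    CodingSequence,
    compute_rscu,
    count_codon_pairs,
    count_codons,
    pair_frequencies,
)
from .ribo import (
    DEFAULT_MRNA_MIN_LENGTH,
    DEFAULT_RPF_RANGES,
    calibrate_offset,
    codon_occupancy,
    cumulative_profile,
    filter_lengths,
    summarize_te,
)
from .simulate import GeneratorConfig, gen_cds, gen_expression, gen_ribo_libraries
from .variant import VariantImpactReport, build_report, parse_variant


def _write_provenance(outdir: Path, stage: str, record: dict) -> None:
    record = {"stage": stage, "silentshift_version": __version__, **record}
    with open(outdir / f"provenance_{stage}.yaml", "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)


def run_simulate_workflow(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic input set (FASTA, TSVs) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    cds_set = gen_cds(config, rng)
    expression = gen_expression(config, [c.id for c in cds_set], rng)
    rpf, mrna, models = gen_ribo_libraries(config, cds_set, expression, rng)
    paths = {
        "cds": outdir / "cds.fasta",
        "expression": outdir / "expression.tsv",
        "rpf": outdir / "rpf_alignments.tsv",
        "mrna": outdir / "mrna_alignments.tsv",
        "models": outdir / "transcript_models.tsv",
    }
    io.write_cds_fasta(cds_set, paths["cds"])
    io.write_expression_tsv(expression, paths["expression"])
    io.write_alignments_tsv(rpf, paths["rpf"])
    io.write_alignments_tsv(mrna, paths["mrna"])
    io.write_models_tsv(models, paths["models"])
    _write_provenance(
        outdir,
        "simulate",
        {
            "config": dataclasses.asdict(config),
            "outputs": {k: str(v) for k, v in paths.items()},
        },
    )
    return paths


def run_tables_workflow(
    cds_fasta: str | Path,
    out_prefix: str | Path,
    tpm_tsv: str | Path | None = None,
    scope: str | None = None,
) -> dict[str, Path]:
    """Build codon and codon-pair usage tables from a CDS FASTA.

    With ``tpm_tsv`` the counts are expression-weighted (each CDS
    contributes its TPM per occurrence), which is how a tissue-specific
    table is derived from a genome-wide CDS set plus tissue expression.
    """
    cds_set = io.read_cds_fasta(cds_fasta)
    weights = io.read_expression_tsv(tpm_tsv) if tpm_tsv else None
    scope = scope or ("tissue-weighted" if weights else Path(cds_fasta).stem)
    usage = compute_rscu(count_codons(cds_set, weights, scope=scope))
    pairs = pair_frequencies(count_codon_pairs(cds_set, weights, scope=scope))
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "codon_table": Path(f"{out_prefix}.codons.tsv"),
        "pair_table": Path(f"{out_prefix}.pairs.tsv"),
    }
    io.write_codon_table_tsv(usage, paths["codon_table"])
    io.write_pair_table_tsv(pairs, paths["pair_table"])
    _write_provenance(
        out_prefix.parent,
        "tables",
        {
            "inputs": {"cds_fasta": str(cds_fasta), "tpm_tsv": str(tpm_tsv) if tpm_tsv else None},
            "scope": scope,
            "outputs": {k: str(v) for k, v in paths.items()},
        },
    )
    return paths


def _variant_label(row_codon: str, wt_codon: str, codon_index: int) -> str:
    """c.-notation label for a focal-codon replacement, derived from bases."""
    diffs = [i for i in range(3) if row_codon[i] != wt_codon[i]]
    if not diffs:
        return "WT"
    if len(diffs) > 1:
        return f"({wt_codon}>{row_codon})"
    off = diffs[0]
    pos = 3 * (codon_index - 1) + off + 1
    return f"c.{pos}{wt_codon[off]}>{row_codon[off]}"


def write_impact_markdown(report: VariantImpactReport, path: str | Path) -> None:
    """Render the impact report as two markdown tables (RSCU and pairs)."""
    ctx = report.context
    lines = [
        f"# Codon-usage impact of {report.variant} ({report.protein_notation})",
        "",
    ]
    if not report.synonymous:
        lines += [report.warning or "non-synonymous variant", ""]
        Path(path).write_text("\n".join(lines))
        return
    scopes = [bg.scope for bg in report.backgrounds]
    lines += [
        f"Focal codon {ctx.codon_index} ({ctx.amino_acid}): {ctx.focal_wt} -> "
        f"{ctx.focal_alt}; preceding {ctx.preceding or '-'}, following {ctx.following or '-'}",
        "",
        "## Relative synonymous codon usage",
        "",
        "| Variant | Codon | " + " | ".join(f"RSCU ({s})" for s in scopes) + " |",
        "|" + "---|" * (2 + len(scopes)),
    ]
    codons = [r.codon for r in report.backgrounds[0].rows]
    by_scope = {bg.scope: {r.codon: r for r in bg.rows} for bg in report.backgrounds}
    for codon in codons:
        label = _variant_label(codon, ctx.focal_wt, ctx.codon_index)
        cells = [
            "" if by_scope[s][codon].rscu is None else f"{by_scope[s][codon].rscu:.2f}"
            for s in scopes
        ]
        lines.append(f"| {label} | {codon} | " + " | ".join(cells) + " |")
    lines += [
        "",
        "## Codon-pair usage (frequency per million / percentile)",
        "",
        "| Variant | Pair | "
        + " | ".join(f"{s} freq | {s} pct" for s in scopes)
        + " |",
        "|" + "---|" * (2 + 2 * len(scopes)),
    ]
    for codon in codons:
        label = _variant_label(codon, ctx.focal_wt, ctx.codon_index)
        for side in ("preceding", "following"):
            flank = getattr(ctx, side)
            if flank is None:
                continue
            pair = f"{flank} {codon}" if side == "preceding" else f"{codon} {flank}"
            cells = []
            for s in scopes:
                r = by_scope[s][codon]
                f = getattr(r, f"{side}_freq")
                p = getattr(r, f"{side}_percentile")
                cells += [f"{f:.3f}", f"{p:.3f}"]
            lines.append(f"| {label} | {pair} | " + " | ".join(cells) + " |")
    lines.append("")
    Path(path).write_text("\n".join(lines))


def run_impact_workflow(
    cds_fasta: str | Path,
    variant: str,
    backgrounds: list[tuple[str | Path, str | Path]],
    outdir: str | Path,
    cds_id: str | None = None,
    include_all_synonyms: bool = True,
    include_self_background: bool = True,
    tpm_tsv: str | Path | None = None,
) -> VariantImpactReport:
    """Score a coding variant against background usage tables.

    ``backgrounds`` is an ordered list of (codon-table TSV, pair-table TSV)
    pairs; with ``include_self_background`` the query CDS set itself is
    prepended as a background (the gene-level column of a usage report),
    TPM-weighted if ``tpm_tsv`` is given. Writes tidy TSVs, a markdown
    report mirroring the two-table layout, and provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cds_set = io.read_cds_fasta(cds_fasta)
    if cds_id is None:
        cds = cds_set[0]
    else:
        matches = [c for c in cds_set if c.id == cds_id]
        if not matches:
            raise ValueError(f"CDS id {cds_id!r} not found in {cds_fasta}")
        cds = matches[0]
    v = parse_variant(variant)
    bg_tables = []
    if include_self_background:
        weights = io.read_expression_tsv(tpm_tsv) if tpm_tsv else None
        scope = "query-cdna" if weights is None else "query-cdna-tissue-weighted"
        bg_tables.append(
            (
                compute_rscu(count_codons(cds_set, weights, scope=scope)),
                pair_frequencies(count_codon_pairs(cds_set, weights, scope=scope)),
            )
        )
    for codon_tsv, pair_tsv in backgrounds:
        bg_tables.append(
            (
                compute_rscu(io.read_codon_table_tsv(codon_tsv, scope=Path(codon_tsv).stem)),
                pair_frequencies(io.read_pair_table_tsv(pair_tsv, scope=Path(pair_tsv).stem)),
            )
        )
    report = build_report(cds, v, bg_tables, include_all_synonyms=include_all_synonyms)
    report.rscu_frame().to_csv(outdir / "impact_rscu.tsv", sep="\t", index=False)
    report.pairs_frame().to_csv(outdir / "impact_pairs.tsv", sep="\t", index=False)
    write_impact_markdown(report, outdir / "impact_report.md")
    _write_provenance(
        outdir,
        "impact",
        {
            "inputs": {
                "cds_fasta": str(cds_fasta),
                "cds_id": cds.id,
                "variant": variant,
                "backgrounds": [[str(a), str(b)] for a, b in backgrounds],
                "tpm_tsv": str(tpm_tsv) if tpm_tsv else None,
            },
            "parameters": {
                "include_all_synonyms": include_all_synonyms,
                "include_self_background": include_self_background,
            },
            "synonymous": report.synonymous,
            "protein_notation": report.protein_notation,
        },
    )
    return report


def run_riboprof_workflow(
    rpf_tsv: str | Path,
    mrna_tsv: str | Path,
    models_tsv: str | Path,
    outdir: str | Path,
    offset: int | str = "auto",
    rpf_ranges: tuple[tuple[int, int], ...] = DEFAULT_RPF_RANGES,
    mrna_min_length: int = DEFAULT_MRNA_MIN_LENGTH,
) -> pd.DataFrame:
    """Quantify occupancy, cumulative profiles and TE from read tables.

    ``offset='auto'`` calibrates a pooled P-site offset from the
    start-codon metagene; an integer bypasses calibration. Empty read
    files produce empty outputs and a warning, not an error. Returns the
    TE table as a DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = io.read_models_tsv(models_tsv)
    rpf = filter_lengths(io.read_alignments_tsv(rpf_tsv), rpf_ranges)
    mrna = [
        r for r in io.read_alignments_tsv(mrna_tsv) if r.length >= mrna_min_length
    ]
    if not rpf or not mrna:
        warnings.warn("empty RPF or mRNA library after filtering; writing empty outputs")
        empty_occ = pd.DataFrame(
            columns=["transcript_id", "codon", "raw", "normalized", "cumulative", "cumulative_log"]
        )
        te_df = pd.DataFrame(columns=["transcript_id", "rpf_rpkm", "mrna_rpkm", "te"])
        empty_occ.to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
        te_df.to_csv(outdir / "te.tsv", sep="\t", index=False)
        _write_provenance(outdir, "riboprof", {"warning": "empty library", "offset": None})
        return te_df

    if offset == "auto":
        used_offset = calibrate_offset(rpf, models)[None]
    else:
        used_offset = int(offset)

    rpf_by_tid: dict[str, list] = {}
    for r in rpf:
        rpf_by_tid.setdefault(r.transcript_id, []).append(r)
    occ_rows = []
    for model in models:
        profile = codon_occupancy(rpf_by_tid.get(model.id, []), model, used_offset)
        cum = cumulative_profile(profile)
        cum_log = cumulative_profile(profile, log_transform=True)
        for c in range(profile.n_codons):
            occ_rows.append(
                {
                    "transcript_id": model.id,
                    "codon": c,
                    "raw": profile.raw[c],
                    "normalized": profile.normalized[c],
                    "cumulative": cum[c],
                    "cumulative_log": cum_log[c],
                }
            )
    pd.DataFrame(occ_rows).to_csv(
        outdir / "occupancy.tsv", sep="\t", index=False, float_format="%.6g"
    )

    te = summarize_te(rpf, mrna, models, used_offset)
    te_df = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in te],
            "rpf_rpkm": [t.rpf_rpkm for t in te],
            "mrna_rpkm": [t.mrna_rpkm for t in te],
            "te": [t.te for t in te],
        }
    )
    te_df.to_csv(outdir / "te.tsv", sep="\t", index=False, float_format="%.6g")
    _write_provenance(
        outdir,
        "riboprof",
        {
            "inputs": {"rpf": str(rpf_tsv), "mrna": str(mrna_tsv), "models": str(models_tsv)},
            "parameters": {
                "offset_mode": offset,
                "offset_used": used_offset,
                "rpf_ranges": [list(r) for r in rpf_ranges],
                "mrna_min_length": mrna_min_length,
            },
            "n_rpf": len(rpf),
            "n_mrna": len(mrna),
        },
    )
    return te_df
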