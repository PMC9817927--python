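"""End-to-end helpers gluing the analysis stages together.

These are the functions behind the CLI subcommands: given annotated
mitogenome records they produce the per-gene codon-usage profiles, the
bias analyses and the summary tables that the study workflow emits as TSV.
"""

from __future__ import annotations

import pandas as pd

from . import bias_analysis, codon_usage, composition, genome_io
from .genetic_code import GeneticCode, VERTEBRATE_MITO

SIGNIFICANT_CUB_ENC = 35.0


def profiles_for_record(record, code: GeneticCode = VERTEBRATE_MITO):
    """Codon-usage profiles of the 13 protein-coding genes of one genome."""
    strands = genome_io.assign_strands(record)
    genes = genome_io.extract_pcgs(record, strands)
    out = []
    for g in genes:
        counts = codon_usage.extract_codons(g.cds, gene=g.gene, taxon=g.taxon,
                                            code=code)
        out.append(codon_usage.profile(counts, strand_label=g.strand_label))
    return out


def profiles_for_cohort(records, code: GeneticCode = VERTEBRATE_MITO):
    profiles = []
    for rec in records:
        profiles.extend(profiles_for_record(rec, code))
    return profiles


def profile_frame(profiles) -> pd.DataFrame:
    """Per-(taxon, gene) index table: ENC, GC contents, codon count, strand."""
    return pd.DataFrame([
        {"taxon": p.taxon, "gene": p.gene, "strand": p.strand_label,
         "n_codons": p.n_codons, "enc": p.enc, "gc1": p.gc1, "gc2": p.gc2,
         "gc12": p.gc12, "gc3": p.gc3, "gc3s": p.gc3s}
        for p in profiles
    ])


def rscu_matrix(profiles) -> pd.DataFrame:
    """Rows (taxon, gene), one column per sense codon."""
    rows = []
    for p in profiles:
        row = {"taxon": p.taxon, "gene": p.gene}
        row.update(p.rscu)
        rows.append(row)
    return pd.DataFrame(rows)


def significant_cub_tally(profiles, threshold: float = SIGNIFICANT_CUB_ENC):
    """Count of gene/taxon profiles with ENC at or below the bias threshold."""
    n_total = len(profiles)
    n_sig = sum(1 for p in profiles if p.enc == p.enc and p.enc <= threshold)
    return {"n_profiles": n_total, "n_significant": n_sig,
            "pct_significant": 100.0 * n_sig / n_total if n_total else float("nan")}


def summarize_genomes(records):
    """Per-genome length/gene-content rows plus the cohort strand block."""
    rows = []
    for rec in records:
        order, mismatch = genome_io.classify_gene_order(rec)
        genes = genome_io.extract_pcgs(rec)
        survey = genome_io.survey_start_stop(genes)
        rows.append({
            "taxon": rec.taxon or rec.accession,
            "accession": rec.accession,
            "length_bp": rec.length,
            "n_pcg": len(rec.pcg_features()),
            "n_features": len(rec.features),
            "gene_order": order,
            "order_mismatch": mismatch or "",
            "non_atg_starts": ";".join(
                f"{r['gene']}:{r['start_codon']}" for r in survey
                if r["non_atg_start"]),
        })
    cohort = composition.cohort_strand_summary(records) if records else {}
    return pd.DataFrame(rows), cohort


def bias_report(profiles):
    """PR2-style summaries are per codon-count; here: ENC-curve table and
    neutrality fits per gene, contribution-sorted."""
    points, curve_summary = bias_analysis.enc_gc3s_table(profiles)
    fits = bias_analysis.neutrality_fits_by_gene(profiles)
    fit_frame = pd.DataFrame([
        {"gene": f.gene, "n": f.n, "slope": f.slope, "intercept": f.intercept,
         "r2": f.r2, "mutation_contribution_pct": f.mutation_contribution_pct,
         "selection_dominated": f.selection_dominated}
        for f in fits
    ])
    curve_frame = pd.DataFrame([
        {"gene": pt.gene, "taxon": pt.taxon, "gc3s": pt.gc3s,
         "enc_observed": pt.enc_observed, "enc_expected": pt.enc_expected,
         "deficit": pt.deficit}
        for pt in points
    ])
    return curve_frame, curve_summary, fit_frame
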