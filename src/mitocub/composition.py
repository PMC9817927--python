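"""Nucleotide composition and strand-asymmetry summaries.

Mitochondrial replication is asymmetric: the strand left single-stranded
longest accumulates deamination-driven mutations, so the heavy strand ends
up G+T rich and the light strand A+C rich.  These helpers quantify that
strand-biased compositional asymmetry for single sequences and cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import MitogenomeRecord, assign_strands


@dataclass
class CompositionSummary:
    counts: dict          # base -> integer count (N excluded)
    fractions: dict       # base -> proportion of non-N length
    gt: float             # G+T fraction
    ac: float             # A+C fraction


def base_composition(seq: str) -> CompositionSummary:
    """Exact base counts and fractions; N bases excluded from numerator
    and denominator."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence empty or all-N")
    fractions = {b: c / total for b, c in counts.items()}
    gt = fractions["G"] + fractions["T"]
    return CompositionSummary(counts=counts, fractions=fractions, gt=gt, ac=1.0 - gt)


def cohort_strand_summary(records: list):
    """Mean and sample SD of per-strand G+T content across a cohort.

    For each record the submitted strand and its complement are labelled
    H/L by composition; the summary reports, in percent, the mean and
    (n-1)-denominator SD of the L- and H-strand G+T fractions.  With fewer
    than two records the SDs are NaN.
    """
    gt_l, gt_h = [], []
    for rec in records:
        sa = assign_strands(rec)
        if sa.label_submitted == "L":
            gt_l.append(sa.gt_submitted)
            gt_h.append(sa.gt_complement)
        else:
            gt_l.append(sa.gt_complement)
            gt_h.append(sa.gt_submitted)
    gl, gh = np.asarray(gt_l), np.asarray(gt_h)
    sd = lambda x: float(np.std(x, ddof=1)) * 100 if len(x) > 1 else float("nan")
    return {
        "mean_gt_L": float(gl.mean()) * 100,
        "sd_gt_L": sd(gl),
        "mean_gt_H": float(gh.mean()) * 100,
        "sd_gt_H": sd(gh),
        "n": len(records),
    }


def composition_table(records: list):
    """Per-taxon A/C/G/T and G+T fractions for both strands, as rows of dicts."""
    rows = []
    for rec in records:
        sa = assign_strands(rec)
        sub = base_composition(rec.sequence)
        for label, comp in (
            (sa.label_submitted, sub),
            (sa.label_complement, _complement_summary(sub)),
        ):
            row = {"taxon": rec.taxon or rec.accession, "strand": label}
            row.update({b: comp.fractions[b] for b in "ACGT"})
            row["GT"] = comp.gt
            rows.append(row)
    return rows


def _complement_summary(comp: CompositionSummary) -> CompositionSummary:
    # The complement strand's composition follows from A<->T, C<->G exchange.
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    counts = {b: comp.counts[pair[b]] for b in "ACGT"}
    fractions = {b: comp.fractions[pair[b]] for b in "ACGT"}
    gt = fractions["G"] + fractions["T"]
    return CompositionSummary(counts=counts, fractions=fractions, gt=gt, ac=1.0 - gt)
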