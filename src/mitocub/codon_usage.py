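"""Codon counting and per-gene codon-usage indices.

Implements the classic codon-usage toolkit for mitochondrial genes under
the vertebrate mitochondrial code: relative synonymous codon usage (RSCU),
Wright's effective number of codons (ENC, following the CodonW conventions
for family averaging and missing degeneracy classes), and G+C content at
the three codon positions (GC1, GC2, GC12, GC3) plus its synonymous-site
variant GC3s.

RSCU for codon c in synonymous family F is

    RSCU(c) = n_c * |F| / sum_{c' in F} n_{c'}

so uniform synonymous usage gives 1 for every codon.  ENC summarises how
far usage departs from uniformity on a 20-60 scale (20 = one codon per
amino acid, 60 = uniform under table 2, which has 60 sense codons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import GeneticCode, VERTEBRATE_MITO

log = logging.getLogger(__name__)


@dataclass
class CodonCounts:
    """Counts of the sense codons of one gene, stops excluded."""

    gene: str = ""
    taxon: str = ""
    counts: dict = field(default_factory=dict)
    code: GeneticCode = VERTEBRATE_MITO

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def third_position_totals(self) -> dict:
        """Counts of A/C/G/T at third positions of the counted sense codons."""
        totals = {b: 0 for b in "ACGT"}
        for codon, n in self.counts.items():
            totals[codon[2]] += n
        return totals


@dataclass
class CodonUsageProfile:
    gene: str
    taxon: str
    rscu: dict
    enc: float
    gc1: float
    gc2: float
    gc12: float
    gc3: float
    gc3s: float
    n_codons: int
    strand_label: str = ""


def extract_codons(cds: str, gene: str = "", taxon: str = "",
                   code: GeneticCode = VERTEBRATE_MITO) -> CodonCounts:
    """Count sense codons of a coding sequence.

    Reads successive triplets from the first base.  A trailing complete stop
    codon and any trailing incomplete codon (the ``T--``/``TA-`` remnant of a
    polyadenylation-completed stop) are dropped; in-frame internal stop
    triplets are dropped with a warning; codons containing N are ignored.
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError("coding sequence shorter than 2 codons")
    usable = len(cds) - (len(cds) % 3)
    codons = [cds[i:i + 3] for i in range(0, usable, 3)]
    if codons and codons[-1] in code.stop_codons:
        codons.pop()
    counts: dict = {}
    for i, codon in enumerate(codons):
        if "N" in codon:
            continue
        if codon in code.stop_codons:
            log.warning("%s/%s: internal stop codon %s at codon %d dropped",
                        taxon, gene, codon, i + 1)
            continue
        counts[codon] = counts.get(codon, 0) + 1
    if sum(counts.values()) < 2:
        raise ValueError("fewer than 2 codons after trimming")
    return CodonCounts(gene=gene, taxon=taxon, counts=counts, code=code)


def rscu(counts: CodonCounts) -> dict:
    """RSCU per sense codon; families never observed map to NaN."""
    out = {}
    for fam in counts.code.families:
        total = sum(counts.counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = (counts.counts.get(c, 0) * len(fam) / total
                      if total > 0 else float("nan"))
    return out


def codon_homozygosity(n: int, counts: list) -> float:
    """Wright's F-hat for one synonymous family: (n*sum p_i^2 - 1)/(n - 1)."""
    p = np.asarray(counts, dtype=float) / n
    return (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)


def enc(counts: CodonCounts) -> float:
    """Effective number of codons (Wright), CodonW conventions.

    Per synonymous family with at least 2 counted codons, the codon
    homozygosity F-hat is estimated; families with F-hat <= 0 are skipped.
    ENC sums N_k / mean(F-hat) over the degeneracy classes k of the active
    code (for table 2: 12 two-fold, 6 four-fold, 2 six-fold families).  A
    class with no qualifying family borrows the unweighted mean F-hat of
    the classes that have data.  The result is capped at the number of
    sense codons.  NaN when no family has data.
    """
    code = counts.code
    fhat_by_class: dict = {}
    for fam in code.families:
        fam_counts = [counts.counts.get(c, 0) for c in fam]
        n = sum(fam_counts)
        if n < 2:
            continue
        f = codon_homozygosity(n, fam_counts)
        if f <= 0:
            continue
        fhat_by_class.setdefault(len(fam), []).append(f)
    if not fhat_by_class:
        return float("nan")
    class_sizes = code.family_size_counts()
    mean_fhat = {k: float(np.mean(v)) for k, v in fhat_by_class.items()}
    fallback = float(np.mean(list(mean_fhat.values())))
    total = 0.0
    for k, n_families in class_sizes.items():
        total += n_families / mean_fhat.get(k, fallback)
    return min(total, float(len(code.sense_codons)))


def gc_site_contents(counts: CodonCounts):
    """GC fraction at each codon position over the counted codons.

    Returns ``(gc1, gc2, gc3, gc12)`` with ``gc12 = (gc1 + gc2) / 2``.
    """
    n = counts.n_codons
    if n == 0:
        raise ValueError("no codons")
    gc = [0, 0, 0]
    for codon, m in counts.counts.items():
        for k in range(3):
            if codon[k] in "GC":
                gc[k] += m
    gc1, gc2, gc3 = (g / n for g in gc)
    return gc1, gc2, gc3, (gc1 + gc2) / 2


def gc3s(counts: CodonCounts) -> float:
    """GC fraction at third positions of codons from families with >= 2
    synonyms.  Under table 2 every sense codon qualifies, so GC3s equals
    GC3 computed over sense codons."""
    num = den = 0
    for codon, m in counts.counts.items():
        if counts.code.degeneracy(codon) >= 2:
            den += m
            if codon[2] in "GC":
                num += m
    if den == 0:
        return float("nan")
    return num / den


def profile(counts: CodonCounts, strand_label: str = "") -> CodonUsageProfile:
    """Assemble the full per-gene codon-usage profile."""
    gc1, gc2, gc3, gc12 = gc_site_contents(counts)
    return CodonUsageProfile(
        gene=counts.gene, taxon=counts.taxon, rscu=rscu(counts), enc=enc(counts),
        gc1=gc1, gc2=gc2, gc12=gc12, gc3=gc3, gc3s=gc3s(counts),
        n_codons=counts.n_codons, strand_label=strand_label,
    )


OVER_REPRESENTED_THRESHOLD = 1.6
PREFERRED_THRESHOLD = 1.0


def mean_rscu_and_classify(profiles: list,
                           thresholds=(OVER_REPRESENTED_THRESHOLD, PREFERRED_THRESHOLD)):
    """Average RSCU per codon across taxa and classify codon preference.

    A codon is *over-represented* when its cross-taxon mean RSCU exceeds the
    upper threshold (default 1.6) and *preferred* when the mean lies in
    (1.0, 1.6]; everything else is *under_or_normal*.  Codons that are NaN in
    every profile are excluded.  Also tallies, per strand label, how many
    over-represented/preferred codons end in each base — the signature of
    strand-asymmetric mutation pressure (light-strand genes favour A/C
    endings, the heavy-strand gene G/T).

    Returns ``(classification, mean_rscu, ending_tallies)``.
    """
    hi, lo = thresholds
    by_codon: dict = {}
    for p in profiles:
        for codon, val in p.rscu.items():
            if not np.isnan(val):
                by_codon.setdefault(codon, []).append(val)
    mean_rscu = {c: float(np.mean(v)) for c, v in by_codon.items()}
    classification = {}
    for codon, m in mean_rscu.items():
        if m > hi:
            classification[codon] = "over_represented"
        elif m > lo:
            classification[codon] = "preferred"
        else:
            classification[codon] = "under_or_normal"

    tallies: dict = {}
    strands = {p.strand_label for p in profiles if p.strand_label}
    for strand in strands:
        strand_profiles = [p for p in profiles if p.strand_label == strand]
        by_c: dict = {}
        for p in strand_profiles:
            for codon, val in p.rscu.items():
                if not np.isnan(val):
                    by_c.setdefault(codon, []).append(val)
        tally = {b: 0 for b in "ACGT"}
        for codon, vals in by_c.items():
            if float(np.mean(vals)) > lo:  # over-represented or preferred
                tally[codon[2]] += 1
        tallies[strand] = tally
    return classification, mean_rscu, tallies
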