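"""Synthetic mitogenomes, codon counts and codon alignments with planted truth.

Every generator is a pure function of its configuration and seed, and every
planted parameter is recoverable by the corresponding analysis stage: the
genome generator lays out 13 protein-coding genes in the ancestral avian
gene order (MT-ND6 on the opposite strand), plants a controllable heavy/
light-strand G+T asymmetry and an A/C-ending codon bias on light-strand
genes; the codon-count generator plants per-family synonymous probabilities
whose RSCU the estimator must return; the neutrality generator plants a
GC12-on-GC3 slope; and the M0 simulator is the generative twin of the GY94
likelihood, evolving codons along a tree by exact transition matrices.

Default gene lengths and compositional targets mirror typical passerine
mitogenomes (total ~16.7 kb, heavy-strand G+T about 62%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_usage import CodonCounts
from .divergence.alignment import CodonAlignment
from .divergence.m0 import CodonModel
from .genetic_code import GeneticCode, VERTEBRATE_MITO
from .genome_io import (ANCESTRAL_AVIAN_ORDER, GeneFeature, MitogenomeRecord,
                        PCG_SYMBOLS, revcomp)

#: Typical per-gene coding lengths (bp, including start and stop codons).
DEFAULT_GENE_LENGTHS = {
    "MT-ND1": 975, "MT-ND2": 1038, "MT-CO1": 1548, "MT-CO2": 681,
    "MT-ATP8": 165, "MT-ATP6": 681, "MT-CO3": 783, "MT-ND3": 348,
    "MT-ND4L": 294, "MT-ND4": 1377, "MT-ND5": 1815, "MT-CYB": 1140,
    "MT-ND6": 516,
}

TRNA_LENGTH = 70
RRNA_LENGTHS = {"MT-RNR1": 975, "MT-RNR2": 1590}
CR_LENGTH = 1250

#: GenBank-style aliases used when writing records, exercising the synonym
#: mapping on the way back in.
_GENBANK_ALIASES = {
    "MT-ND1": "ND1", "MT-ND2": "ND2", "MT-ND3": "ND3", "MT-ND4": "ND4",
    "MT-ND4L": "ND4L", "MT-ND5": "ND5", "MT-ND6": "ND6",
    "MT-CO1": "COX1", "MT-CO2": "COX2", "MT-CO3": "COX3",
    "MT-ATP6": "ATP6", "MT-ATP8": "ATP8", "MT-CYB": "CYTB",
    "MT-RNR1": "12S ribosomal RNA", "MT-RNR2": "16S ribosomal RNA",
    "CR": "D-loop",
    "MT-TF": "tRNA-Phe", "MT-TV": "tRNA-Val", "MT-TL1": "tRNA-Leu(UUR)",
    "MT-TI": "tRNA-Ile", "MT-TQ": "tRNA-Gln", "MT-TM": "tRNA-Met",
    "MT-TW": "tRNA-Trp", "MT-TA": "tRNA-Ala", "MT-TN": "tRNA-Asn",
    "MT-TC": "tRNA-Cys", "MT-TY": "tRNA-Tyr", "MT-TS1": "tRNA-Ser(UCN)",
    "MT-TD": "tRNA-Asp", "MT-TK": "tRNA-Lys", "MT-TG": "tRNA-Gly",
    "MT-TR": "tRNA-Arg", "MT-TH": "tRNA-His", "MT-TS2": "tRNA-Ser(AGY)",
    "MT-TL2": "tRNA-Leu(CUN)", "MT-TT": "tRNA-Thr", "MT-TP": "tRNA-Pro",
    "MT-TE": "tRNA-Glu",
}


@dataclass
class GeneratorConfig:
    """Knobs of the mitogenome generator.

    ``strand_gt_asymmetry`` is the target G+T fraction of the heavy strand
    (the submitted light strand gets the complement); ``ac_tilt``
    multiplies the sampling weight of A/C-ending codons in light-strand
    genes (heavy-strand genes get the mirrored G/T tilt); ``concentration``
    controls how far per-taxon synonymous preferences may wander from that
    tilted base distribution (infinite = none).
    """

    seed: int = 0
    n_taxa: int = 22
    gene_lengths: dict = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    strand_gt_asymmetry: float = 0.617
    ac_tilt: float = 2.0
    concentration: float = float("inf")
    gc3_range: tuple = (0.35, 0.60)
    code: GeneticCode = VERTEBRATE_MITO


#: Light-strand base frequencies typical of passerine mitogenomes, used as
#: the shape of the compositional model; rescaled to hit the configured
#: asymmetry target.
_L_STRAND_SHAPE = {"A": 0.302, "C": 0.315, "G": 0.145, "T": 0.238}


def _base_freqs_for_gt(gt_target: float) -> dict:
    """Rescale the light-strand shape so G+T equals ``gt_target``."""
    shape_gt = _L_STRAND_SHAPE["G"] + _L_STRAND_SHAPE["T"]
    out = {}
    for b in "GT":
        out[b] = _L_STRAND_SHAPE[b] * gt_target / shape_gt
    for b in "AC":
        out[b] = _L_STRAND_SHAPE[b] * (1.0 - gt_target) / (1.0 - shape_gt)
    return out


def _codon_distribution(base_freqs: dict, tilt_bases: str, tilt: float,
                        code: GeneticCode) -> np.ndarray:
    """Sense-codon sampling distribution: product of positional base
    frequencies with a multiplicative third-position ending tilt."""
    probs = np.array([
        base_freqs[c[0]] * base_freqs[c[1]] * base_freqs[c[2]]
        * (tilt if c[2] in tilt_bases else 1.0)
        for c in code.sense_codons
    ])
    return probs / probs.sum()


def _expected_gt_per_base(probs: np.ndarray, code: GeneticCode) -> float:
    weights = np.array([sum(b in "GT" for b in c) / 3.0 for c in code.sense_codons])
    return float(np.dot(probs, weights))


def _draw_cds(rng: np.random.Generator, length: int, probs: np.ndarray,
              code: GeneticCode) -> str:
    """Start codon + body codons drawn iid from ``probs`` + TAA stop."""
    n_body = length // 3 - 2
    idx = rng.choice(len(probs), size=n_body, p=probs)
    body = "".join(code.sense_codons[i] for i in idx)
    return "ATG" + body + "TAA"


def generate_mitogenome(config: GeneratorConfig, taxon: str = "synthetic_taxon",
                        accession: str = "SYN000001",
                        rng: np.random.Generator | None = None):
    """One annotated synthetic mitogenome plus its planted truth bundle.

    Returns ``(record, truth)`` where ``truth`` holds the coding-sense cds
    per gene, strand labels, and the codon sampling distributions.  The
    non-coding compartments (tRNAs, rRNAs, control region) are drawn from a
    base distribution solved so the whole submitted strand hits the
    complement of the heavy-strand G+T target in expectation.
    """
    if config.strand_gt_asymmetry > 0.9:
        raise ValueError("infeasible asymmetry target (> 0.9)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    code = config.code
    gt_l = 1.0 - config.strand_gt_asymmetry
    f_l = _base_freqs_for_gt(gt_l)
    f_h = {b: f_l[{"A": "T", "T": "A", "C": "G", "G": "C"}[b]] for b in "ACGT"}

    probs_l = _codon_distribution(f_l, "AC", config.ac_tilt, code)
    probs_h = _codon_distribution(f_h, "GT", config.ac_tilt, code)

    # expected G+T on the *submitted* strand contributed by the coding parts
    lengths = config.gene_lengths
    exp_gt = 0.0
    coding_len = 0
    for sym in PCG_SYMBOLS:
        L = lengths[sym]
        coding_len += L
        body = L - 6
        if sym == "MT-ND6":
            # drawn on the heavy strand then reverse-complemented in
            e = body * _expected_gt_per_base(probs_h, code) + 3.0  # ATG + TAA
            exp_gt += L - e
        else:
            exp_gt += body * _expected_gt_per_base(probs_l, code) + 3.0

    noncoding_len = 22 * TRNA_LENGTH + sum(RRNA_LENGTHS.values()) + CR_LENGTH
    total_len = coding_len + noncoding_len
    gt_nc = (total_len * gt_l - exp_gt) / noncoding_len
    if not 0.02 < gt_nc < 0.98:
        raise ValueError("infeasible asymmetry target for this gene layout")
    f_nc = _base_freqs_for_gt(gt_nc)
    nc_p = np.array([f_nc[b] for b in "ACGT"])

    def draw_noncoding(n):
        return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=nc_p)])

    segments, features = [], []
    truth_cds, truth_labels = {}, {}
    pos = 0
    for sym, orientation in ANCESTRAL_AVIAN_ORDER:
        if sym in PCG_SYMBOLS:
            probs = probs_h if sym == "MT-ND6" else probs_l
            cds = _draw_cds(rng, lengths[sym], probs, code)
            seg = revcomp(cds) if orientation == "opposite" else cds
            kind = "PCG"
            truth_cds[sym] = cds
            truth_labels[sym] = "H" if sym == "MT-ND6" else "L"
        else:
            if sym == "CR":
                n, kind = CR_LENGTH, "control_region"
            elif sym in RRNA_LENGTHS:
                n, kind = RRNA_LENGTHS[sym], "rRNA"
            else:
                n, kind = TRNA_LENGTH, "tRNA"
            seg = draw_noncoding(n)
        segments.append(seg)
        features.append(GeneFeature(name=sym, kind=kind, start=pos + 1,
                                    end=pos + len(seg), orientation=orientation))
        pos += len(seg)

    record = MitogenomeRecord(accession=accession, sequence="".join(segments),
                              features=features, taxon=taxon)
    truth = {
        "cds": truth_cds,
        "strand_labels": truth_labels,
        "codon_probs_L": probs_l,
        "codon_probs_H": probs_h,
        "gt_L_target": gt_l,
    }
    return record, truth


def generate_cohort(config: GeneratorConfig):
    """``n_taxa`` independent genomes from seed-derived substreams."""
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_taxa)
    records, truths = [], []
    for i, ss in enumerate(seqs):
        taxon = f"taxon_{i + 1:02d}"
        rec, truth = generate_mitogenome(
            config, taxon=taxon, accession=f"SYN{i + 1:06d}",
            rng=np.random.default_rng(ss))
        records.append(rec)
        truths.append(truth)
    return records, truths


def write_genbank(record: MitogenomeRecord, path) -> None:
    """Serialise a record as a GenBank flat file with common gene aliases."""
    from Bio import SeqIO
    seqrec = SeqRecord(Seq(record.sequence), id=record.accession,
                       name=record.accession.replace(".", "_")[:16],
                       description=f"{record.taxon} mitochondrion, complete genome")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular"
    seqrec.annotations["organism"] = record.taxon
    for feat in record.features:
        strand = -1 if feat.orientation == "opposite" else 1
        loc = FeatureLocation(feat.start - 1, feat.end, strand=strand)
        alias = _GENBANK_ALIASES.get(feat.name, feat.name)
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "control_region": "D-loop"}.get(feat.kind, "misc_feature")
        quals = {"gene": [alias]} if feat.kind == "PCG" else {"product": [alias]}
        if ftype == "D-loop":
            quals = {"note": [alias]}
        seqrec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def generate_codon_counts(n_codons: int, seed: int,
                          concentration: float = float("inf"),
                          ac_tilt: float = 1.0,
                          family_probs: dict | None = None,
                          code: GeneticCode = VERTEBRATE_MITO):
    """Multinomial codon counts with planted synonymous probabilities.

    Codons are allocated to synonymous families in proportion to family
    size; within each family the synonymous probabilities are either given
    explicitly (``family_probs``, keyed by any member codon), or drawn from
    a Dirichlet whose mean is the A/C-tilted uniform distribution
    (``concentration = inf`` uses the mean itself).  Returns
    ``(CodonCounts, truth_rscu)`` with truth RSCU = probability x family
    size.
    """
    rng = np.random.default_rng(seed)
    counts: dict = {}
    truth_rscu: dict = {}
    total_sense = len(code.sense_codons)
    for fam in code.families:
        k = len(fam)
        n_fam = int(round(n_codons * k / total_sense))
        if family_probs is not None and any(c in family_probs for c in fam):
            p = np.array([family_probs.get(c, np.nan) for c in fam])
            if np.isnan(p).any():
                raise ValueError(f"family_probs must cover all of {fam}")
        else:
            base = np.array([ac_tilt if c[2] in "AC" else 1.0 for c in fam])
            base = base / base.sum()
            if np.isinf(concentration):
                p = base
            else:
                p = rng.dirichlet(concentration * k * base)
        p = p / p.sum()
        draw = rng.multinomial(n_fam, p)
        for c, n, pc in zip(fam, draw, p):
            if n:
                counts[c] = int(n)
            truth_rscu[c] = float(pc * k)
    return CodonCounts(gene="synthetic", taxon="synthetic", counts=counts,
                       code=code), truth_rscu


def generate_neutrality_points(slope: float, intercept: float, noise_sd: float,
                               n: int, seed: int, gc3_range=(0.35, 0.60)):
    """(GC3, GC12) pairs with a planted linear relation.

    GC3 is uniform on ``gc3_range``; GC12 = intercept + slope*GC3 + Gaussian
    noise, clipped to [0, 1].  Returns ``(gc3, gc12, n_clipped)``.
    """
    rng = np.random.default_rng(seed)
    gc3 = rng.uniform(gc3_range[0], gc3_range[1], size=n)
    gc12 = intercept + slope * gc3 + rng.normal(0.0, noise_sd, size=n)
    clipped = int(np.sum((gc12 < 0) | (gc12 > 1)))
    return gc3, np.clip(gc12, 0.0, 1.0), clipped


def simulate_m0(tree, kappa: float, omega: float, freqs, n_codons: int,
                seed: int, code: GeneticCode = VERTEBRATE_MITO,
                gene: str = "simulated") -> CodonAlignment:
    """Evolve a codon alignment under GY94/M0 along a tree.

    Root codons are drawn from the stationary frequencies; each branch
    applies the exact transition matrix exp(Qt).  Stop codons cannot arise
    because the state space holds sense codons only.
    """
    model = CodonModel(freqs, kappa, omega, code)
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(
        data=str(tree), schema="newick", preserve_underscores=True)
    rng = np.random.default_rng(seed)
    n_states = len(code.sense_codons)

    states = {}  # node -> codon index array
    leaves = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            states[node] = rng.choice(n_states, size=n_codons, p=model.pi)
        else:
            bl = node.edge.length or 0.0
            parent = states[node.parent_node]
            child = np.empty(n_codons, dtype=int)
            if bl == 0.0:
                child[:] = parent
            else:
                P = model.transition_matrix(bl)
                P = P / P.sum(axis=1, keepdims=True)
                for s in np.unique(parent):
                    idx = np.where(parent == s)[0]
                    child[idx] = rng.choice(n_states, size=len(idx), p=P[s])
            states[node] = child
        if node.is_leaf():
            leaves[node.taxon.label] = states[node]

    taxa = sorted(leaves)
    rows = ["".join(code.sense_codons[i] for i in leaves[tx]) for tx in taxa]
    return CodonAlignment(gene=gene, taxa=taxa, rows=rows)


def caterpillar_tree_newick(n_taxa: int = 6, branch_length: float = 0.1) -> str:
    """A deterministic ladder tree for simulations, taxa t1..tn."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    b = format(branch_length, "g")
    tree = f"(t1:{b},t2:{b})"
    for i in range(3, n_taxa + 1):
        tree = f"({tree}:{b},t{i}:{b})"
    return tree + ";"
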