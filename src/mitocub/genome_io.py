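"""Reading annotated mitogenomes and extracting oriented protein-coding genes.

Vertebrate mitochondrial records are submitted as a single linear string of
the circular molecule; most genes sit on the submitted strand, a minority
(notably MT-ND6 and a handful of tRNAs) on its complement.  This module maps
the free-text gene names found in GenBank files onto a closed HGNC-style
symbol set, labels the two strands H (heavy, higher G+T) and L (light, lower
G+T) from their composition, pulls out the 13 protein-coding genes in coding
orientation, classifies the gene order against the ancestral avian
arrangement first described in chicken, and surveys start/stop codons.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

PCG_SYMBOLS = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6",
    "MT-CO3", "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-CYB", "MT-ND6",
)

#: Circular gene order of the ancestral avian mitogenome (chicken-type),
#: one (symbol, orientation) pair per feature, starting at tRNA-Phe.
#: Orientation is relative to the majority (submitted) strand.
ANCESTRAL_AVIAN_ORDER = (
    ("MT-TF", "same"), ("MT-RNR1", "same"), ("MT-TV", "same"),
    ("MT-RNR2", "same"), ("MT-TL1", "same"), ("MT-ND1", "same"),
    ("MT-TI", "same"), ("MT-TQ", "opposite"), ("MT-TM", "same"),
    ("MT-ND2", "same"), ("MT-TW", "same"), ("MT-TA", "opposite"),
    ("MT-TN", "opposite"), ("MT-TC", "opposite"), ("MT-TY", "opposite"),
    ("MT-CO1", "same"), ("MT-TS1", "opposite"), ("MT-TD", "same"),
    ("MT-CO2", "same"), ("MT-TK", "same"), ("MT-ATP8", "same"),
    ("MT-ATP6", "same"), ("MT-CO3", "same"), ("MT-TG", "same"),
    ("MT-ND3", "same"), ("MT-TR", "same"), ("MT-ND4L", "same"),
    ("MT-ND4", "same"), ("MT-TH", "same"), ("MT-TS2", "same"),
    ("MT-TL2", "same"), ("MT-ND5", "same"), ("MT-CYB", "same"),
    ("MT-TT", "same"), ("MT-TP", "opposite"), ("MT-ND6", "opposite"),
    ("MT-TE", "opposite"), ("CR", "same"),
)

STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene on a mitogenome.

    Coordinates are 1-based inclusive on the submitted strand (the GenBank
    convention); ``orientation`` says whether the gene is read off the
    submitted strand (``same``) or its reverse complement (``opposite``).
    """

    name: str
    kind: str  # PCG | tRNA | rRNA | control_region | other
    start: int
    end: int
    orientation: str = "same"


@dataclass
class MitogenomeRecord:
    accession: str
    sequence: str
    features: list = field(default_factory=list)
    taxon: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def pcg_features(self) -> list:
        return [f for f in self.features if f.kind == "PCG"]


@dataclass
class GeneSequence:
    """A protein-coding gene read 5'->3' in coding orientation."""

    gene: str
    taxon: str
    cds: str
    strand_label: str  # H | L


@dataclass
class StrandAssignment:
    gt_submitted: float
    gt_complement: float
    label_submitted: str  # H | L

    @property
    def label_complement(self) -> str:
        return "L" if self.label_submitted == "H" else "H"


def _normalize_alias(name: str) -> str:
    return re.sub(r"[\s\-_]+", " ", name.strip().upper())


def _load_synonyms() -> dict:
    table = {}
    text = (resources.files("mitocub") / "data" / "gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        alias, symbol = line.split("\t")
        table[_normalize_alias(alias)] = symbol
    return table


_SYNONYMS = _load_synonyms()


def map_gene_name(name: str):
    """Map a GenBank gene/product name to the closed symbol set, or None."""
    return _SYNONYMS.get(_normalize_alias(name))


def _kind_for(symbol: str, ftype: str) -> str:
    if symbol in PCG_SYMBOLS:
        return "PCG"
    if symbol == "CR":
        return "control_region"
    if symbol and symbol.startswith("MT-RNR"):
        return "rRNA"
    if symbol and symbol.startswith("MT-T"):
        return "tRNA"
    return {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(ftype, "other")


def read_genbank(path) -> MitogenomeRecord:
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    Feature names are mapped onto the closed symbol set through the shipped
    synonym table; features whose names cannot be mapped are retained with a
    kind inferred from the feature type and a warning logged.

    Raises
    ------
    ValueError
        If the record has no sequence or no CDS features.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: record has no sequence")

    features = []
    n_cds = 0
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        if feat.type == "D-loop" and not raw:
            raw = "D-loop"
        symbol = map_gene_name(raw)
        if symbol is None:
            if feat.type == "misc_feature":
                continue
            log.warning("%s: unmapped feature name %r (type %s)", rec.id, raw, feat.type)
            symbol = raw or feat.type
        kind = _kind_for(symbol if symbol in _SYNONYMS.values() else "", feat.type)
        if feat.type == "CDS":
            n_cds += 1
            kind = "PCG" if symbol in PCG_SYMBOLS else kind
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        orientation = "opposite" if feat.location.strand == -1 else "same"
        features.append(GeneFeature(symbol, kind, start, end, orientation))

    if n_cds == 0:
        raise ValueError(f"{path}: no PCGs (zero CDS features)")
    taxon = rec.annotations.get("organism", "") or rec.description
    return MitogenomeRecord(accession=rec.id, sequence=seq, features=features, taxon=taxon)


def gt_fraction(seq: str) -> float:
    """G+T fraction of a sequence; N excluded from both counts and length."""
    n_valid = sum(seq.count(b) for b in "ACGT")
    if n_valid == 0:
        raise ValueError("sequence is empty or all-N")
    return (seq.count("G") + seq.count("T")) / n_valid


def assign_strands(record: MitogenomeRecord) -> StrandAssignment:
    """Label the submitted strand H or L from its G+T content.

    The heavy (H) strand is the one with the higher G+T fraction; by base
    complementarity the two strands' G+T fractions sum to exactly 1, so a
    single composition scan decides both labels.  An exact tie is labelled
    L with a warning.
    """
    gt = gt_fraction(record.sequence.upper())
    label = "H" if gt > 0.5 else "L"
    if gt == 0.5:
        log.warning("%s: strands have equal G+T; submitted strand labelled L", record.accession)
    return StrandAssignment(gt_submitted=gt, gt_complement=1.0 - gt, label_submitted=label)


def extract_pcgs(record: MitogenomeRecord, strands: StrandAssignment | None = None) -> list:
    """Extract the 13 protein-coding genes in coding orientation.

    Opposite-orientation features are reverse-complemented so every returned
    ``cds`` reads 5'->3' in coding sense.  ``strand_label`` is the H/L label
    of the strand the gene is encoded on.  Genes are returned in ancestral
    avian order.
    """
    if strands is None:
        strands = assign_strands(record)
    order = {g: i for i, g in enumerate(PCG_SYMBOLS)}
    out = []
    for feat in record.pcg_features():
        if feat.start < 1 or feat.end > record.length:
            raise ValueError(f"{feat.name}: coordinates beyond sequence bounds")
        if feat.end - feat.start + 1 < 3:
            raise ValueError(f"{feat.name}: PCG shorter than 3 nt")
        cds = record.sequence[feat.start - 1 : feat.end]
        if feat.orientation == "opposite":
            cds = revcomp(cds)
            label = strands.label_complement
        else:
            label = strands.label_submitted
        out.append(GeneSequence(gene=feat.name, taxon=record.taxon or record.accession,
                                cds=cds, strand_label=label))
    out.sort(key=lambda g: order.get(g.gene, 99))
    return out


def classify_gene_order(record: MitogenomeRecord):
    """Compare the circular gene arrangement with the ancestral avian order.

    Returns ``("ancestral_avian", None)`` on an exact rotation-invariant,
    orientation-aware match, else ``("other", reason)`` where ``reason``
    names the first mismatch under the best rotation.  Duplicated symbols
    classify as ``other`` rather than raising.
    """
    feats = sorted(
        (f for f in record.features if f.name in {s for s, _ in ANCESTRAL_AVIAN_ORDER}),
        key=lambda f: f.start,
    )
    observed = [(f.name, f.orientation) for f in feats]
    ref = list(ANCESTRAL_AVIAN_ORDER)
    names = [n for n, _ in observed]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        return "other", f"duplicated symbols: {', '.join(dupes)}"
    if len(observed) != len(ref):
        missing = sorted({s for s, _ in ref} - set(names))
        return "other", f"feature count {len(observed)} != {len(ref)}; missing: {', '.join(missing)}"

    best_reason = None
    for shift in range(len(observed)):
        rotated = observed[shift:] + observed[:shift]
        for i, (obs, exp) in enumerate(zip(rotated, ref)):
            if obs != exp:
                if shift == 0 or best_reason is None:
                    best_reason = (f"position {i}: found {obs[0]}({obs[1]}), "
                                   f"expected {exp[0]}({exp[1]})")
                break
        else:
            return "ancestral_avian", None
    return "other", best_reason


def survey_start_stop(genes: list):
    """Tabulate start and stop codons of coding sequences.

    A complete in-frame terminal {TAA, TAG, AGA, AGG} is reported as the
    stop; a frame remainder of 1 or 2 nt signals a stop completed by
    post-transcriptional polyadenylation and is reported as ``T--`` or
    ``TA-``.  Non-ATG starts (e.g. the GTG initiation seen in some nuthatch
    MT-CO1 genes) are flagged.
    """
    rows = []
    for g in genes:
        cds = g.cds.upper()
        start = cds[:3]
        rem = len(cds) % 3
        if rem == 1:
            stop = cds[-1] + "--"
        elif rem == 2:
            stop = cds[-2:] + "-"
        else:
            last = cds[-3:]
            stop = last if last in STOP_CODONS else last
        rows.append({
            "gene": g.gene,
            "taxon": g.taxon,
            "start_codon": start,
            "stop_codon": stop,
            "non_atg_start": start != "ATG",
        })
    return rows


def write_gene_fastas(genes: list, path) -> None:
    """Write coding sequences as multi-FASTA with ``taxon|gene|strand`` headers."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.taxon}|{g.gene}|{g.strand_label}\n{g.cds}\n")
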