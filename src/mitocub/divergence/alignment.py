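"""Codon alignments and site-level variability statistics.

Gap policy throughout is *complete deletion*: any alignment column holding
a gap or N in any sequence is excluded from both the numerator and the
denominator, for the percentage of variable sites (PV) and the average
pairwise nucleotide diversity (pi) alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import SeqIO


@dataclass
class CodonAlignment:
    """Equal-length aligned coding sequences for one gene."""

    gene: str
    taxa: list
    rows: list  # DNA strings over {A,C,G,T,N,-}

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """Character matrix (n_taxa x length) of single-byte codes."""
        return np.array([list(r.upper()) for r in self.rows], dtype="U1")


def read_codon_fasta(path, gene: str = "") -> CodonAlignment:
    """Load a FASTA codon alignment; the record id is the taxon."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return CodonAlignment(gene=gene or "", taxa=taxa, rows=rows)


def _included_columns(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of columns free of gaps and Ns in every row."""
    return ~np.any((mat == "-") | (mat == "N"), axis=0)


def pv(alignment: CodonAlignment) -> float:
    """Percentage of variable sites under complete deletion."""
    if alignment.n_taxa < 2:
        raise ValueError("PV needs at least 2 sequences")
    mat = alignment.matrix()
    keep = _included_columns(mat)
    if not keep.any():
        raise ValueError("no sites left after complete deletion")
    sub = mat[:, keep]
    variable = np.any(sub != sub[0], axis=0).sum()
    return 100.0 * float(variable) / int(keep.sum())


def pi(alignment: CodonAlignment) -> float:
    """Average pairwise nucleotide diversity per site, complete deletion."""
    if alignment.n_taxa < 2:
        raise ValueError("pi needs at least 2 sequences")
    mat = alignment.matrix()
    keep = _included_columns(mat)
    if not keep.any():
        raise ValueError("no sites left after complete deletion")
    sub = mat[:, keep]
    n_sites = int(keep.sum())
    diffs = [
        float((sub[i] != sub[j]).sum()) / n_sites
        for i, j in combinations(range(alignment.n_taxa), 2)
    ]
    return float(np.mean(diffs))
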