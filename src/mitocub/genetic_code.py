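"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The whole package is built around table 2: four termination codons
(TAA, TAG, AGA, AGG), 60 sense codons, and a synonymous-family structure
of 12 two-fold, 6 four-fold and 2 six-fold families.  The maximum
effective number of codons under this code is therefore 60, not the 61
familiar from the standard code.

The table itself comes from Biopython; this module adds the family
partition, codon indexing and single-step substitution classification
that the codon-usage and codon-model layers need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (a in PURINES) == (b in PURINES) and a != b


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with its synonymous-family partition of sense codons.

    Attributes
    ----------
    table_id : NCBI translation table number.
    codon_to_aa : map from each sense codon to its one-letter amino acid.
    stop_codons : frozenset of termination codons.
    families : tuple of tuples; each inner tuple lists the codons of one
        synonymous family, sorted alphabetically.
    """

    table_id: int
    codon_to_aa: dict = field(hash=False)
    stop_codons: frozenset
    families: tuple

    @property
    def sense_codons(self) -> tuple:
        """All sense codons in alphabetical order."""
        return tuple(sorted(self.codon_to_aa))

    def family_of(self, codon: str) -> tuple:
        return self._family_index()[codon]

    def _family_index(self):
        if not hasattr(self, "_fam_idx"):
            idx = {}
            for fam in self.families:
                for c in fam:
                    idx[c] = fam
            object.__setattr__(self, "_fam_idx", idx)
        return self._fam_idx

    def degeneracy(self, codon: str) -> int:
        return len(self.family_of(codon))

    def is_synonymous(self, c1: str, c2: str) -> bool:
        return self.codon_to_aa[c1] == self.codon_to_aa[c2]

    def family_size_counts(self) -> dict:
        """Map degeneracy class k -> number of k-fold families."""
        out: dict = {}
        for fam in self.families:
            out[len(fam)] = out.get(len(fam), 0) + 1
        return out


@lru_cache(maxsize=None)
def get_code(table_id: int = 2) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table.

    Defaults to table 2, the vertebrate mitochondrial code.
    """
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(tab.forward_table)
    by_aa: dict = {}
    for codon, aa in codon_to_aa.items():
        by_aa.setdefault(aa, []).append(codon)
    families = tuple(tuple(sorted(v)) for _, v in sorted(by_aa.items()))
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(tab.stop_codons),
        families=families,
    )


# The default code used everywhere unless a caller overrides it.
VERTEBRATE_MITO = get_code(2)


def single_step_class(c1: str, c2: str, code: GeneticCode):
    """Classify a pair of sense codons differing at exactly one position.

    Returns ``(transition, synonymous)`` booleans, or ``None`` when the
    codons differ at zero or more than one position.  Used to build GY94
    rate matrices, where multi-step changes have instantaneous rate zero.
    """
    diffs = [(a, b) for a, b in zip(c1, c2) if a != b]
    if len(diffs) != 1:
        return None
    a, b = diffs[0]
    return is_transition(a, b), code.is_synonymous(c1, c2)
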