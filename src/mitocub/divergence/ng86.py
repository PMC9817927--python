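"""Nei-Gojobori (1986) counting estimator of dN and dS.

Synonymous and nonsynonymous *sites* are counted per codon from the
fraction of the three possible single-base changes at each position that
preserve the amino acid; a change creating a stop codon counts as
nonsynonymous, so sites sum to exactly 3 per codon.  *Differences* between
codon pairs are averaged over all minimal mutational pathways, excluding
pathways that pass through a stop codon.  Proportions are corrected for
multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, permutations
from math import log

from ..genetic_code import BASES, GeneticCode, VERTEBRATE_MITO


@lru_cache(maxsize=None)
def syn_sites(codon: str, table_id: int = 2) -> float:
    """Synonymous site count of one sense codon (0..3)."""
    code = VERTEBRATE_MITO if table_id == 2 else None
    if code is None:
        from ..genetic_code import get_code
        code = get_code(table_id)
    aa = code.codon_to_aa[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant not in code.stop_codons and code.codon_to_aa[mutant] == aa:
                s += 1.0
    return s / 3.0


def _pathway_counts(c1: str, c2: str, code: GeneticCode):
    """Average synonymous/nonsynonymous difference counts between two
    codons over minimal mutational pathways (stop-passing paths excluded)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in code.stop_codons:
                blocked = True
                break
            if code.codon_to_aa[current] == code.codon_to_aa[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every route passes a stop; fall back to ignoring the block
        for order in permutations(diff_pos):
            current, sd, nd = c1, 0, 0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1:]
                if nxt in code.stop_codons or \
                        code.codon_to_aa.get(current, "*") != code.codon_to_aa.get(nxt, "*"):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float):
    """JC69 distance; None when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - (4.0 / 3.0) * p) + 0.0  # +0.0 normalises -0.0


def ng86(seq1: str, seq2: str, code: GeneticCode = VERTEBRATE_MITO):
    """NG86 dN, dS and omega for one gap-free codon sequence pair.

    Returns a dict with site counts (S, N), raw proportions (pS, pN),
    corrected distances (dS, dN) and ``omega = dN/dS`` (None when dS is 0
    or the JC correction is undefined).
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequence length mismatch")
    if len(seq1) % 3:
        raise ValueError("length not divisible by 3")
    n_codons = len(seq1) // 3
    S = sd = nd = 0.0
    for k in range(n_codons):
        c1, c2 = seq1[3 * k: 3 * k + 3], seq2[3 * k: 3 * k + 3]
        if c1 in code.stop_codons or c2 in code.stop_codons:
            raise ValueError(f"stop codon in frame at codon {k + 1}")
        S += (syn_sites(c1, code.table_id) + syn_sites(c2, code.table_id)) / 2.0
        d_s, d_n = _pathway_counts(c1, c2, code)
        sd += d_s
        nd += d_n
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return {"S": S, "N": N, "pS": pS, "pN": pN, "sd": sd, "nd": nd,
            "dS": dS, "dN": dN, "omega": omega}


def ng86_mean_pairwise(alignment, code: GeneticCode = VERTEBRATE_MITO):
    """Mean pairwise NG86 dN, dS and their ratio over all sequence pairs.

    Pairs with undefined JC correction are skipped; the count of skipped
    pairs is reported.  Gap-containing codon columns are removed pairwise.
    """
    dns, dss, skipped = [], [], 0
    for i, j in combinations(range(alignment.n_taxa), 2):
        s1, s2 = _strip_gapped_codons(alignment.rows[i], alignment.rows[j], code)
        if not s1:
            skipped += 1
            continue
        res = ng86(s1, s2, code)
        if res["dN"] is None or res["dS"] is None:
            skipped += 1
            continue
        dns.append(res["dN"])
        dss.append(res["dS"])
    if not dns:
        return {"dN": None, "dS": None, "omega": None, "n_pairs": 0,
                "n_skipped": skipped}
    dn = sum(dns) / len(dns)
    ds = sum(dss) / len(dss)
    return {"dN": dn, "dS": ds, "omega": dn / ds if ds > 0 else None,
            "n_pairs": len(dns), "n_skipped": skipped}


def _strip_gapped_codons(r1: str, r2: str, code: GeneticCode):
    """Drop codon columns with a gap, N or stop codon in either row."""
    keep1, keep2 = [], []
    for k in range(0, len(r1) - len(r1) % 3, 3):
        c1, c2 = r1[k:k + 3].upper(), r2[k:k + 3].upper()
        if (set(c1) <= set(BASES) and set(c2) <= set(BASES)
                and c1 not in code.stop_codons and c2 not in code.stop_codons):
            keep1.append(c1)
            keep2.append(c2)
    return "".join(keep1), "".join(keep2)
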