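"""Per-gene evolutionary-rate tables.

Combines alignment variability (PV, pi), counting-based NG86 dN/dS and the
M0 maximum-likelihood omega into one row per gene, with a selection-regime
call: omega < 1 purifying, = 1 neutral, > 1 positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ..genetic_code import GeneticCode, VERTEBRATE_MITO
from .alignment import CodonAlignment, pv, pi
from .m0 import ConvergenceError, m0_fit
from .ng86 import ng86_mean_pairwise

log = logging.getLogger(__name__)

NEUTRAL_BAND = 1e-9  # omega is continuous; exact equality with 1 is nominal


@dataclass
class DivergenceStats:
    gene: str
    length: int
    pv: float
    pi: float
    dn: float
    ds: float
    omega: float          # M0 maximum-likelihood dN/dS
    regime: str
    ng86_dn: float = None
    ng86_ds: float = None
    ng86_omega: float = None
    error: str = ""


def selection_regime(omega) -> str:
    if omega is None:
        return "undefined"
    if abs(omega - 1.0) <= NEUTRAL_BAND:
        return "neutral"
    return "purifying" if omega < 1.0 else "positive"


def gene_table(alignments: list, tree, code: GeneticCode = VERTEBRATE_MITO,
               fit_m0: bool = True) -> list:
    """One :class:`DivergenceStats` row per gene alignment.

    Errors in a single gene are captured in that row's ``error`` field so
    the rest of the table is still produced.  ``fit_m0=False`` skips the
    likelihood fit and reports NG86 values in the dn/ds/omega columns.
    """
    rows = []
    for aln in alignments:
        try:
            row = _one_gene(aln, tree, code, fit_m0)
        except Exception as exc:  # propagate per gene, keep the table
            log.warning("%s: %s", aln.gene, exc)
            row = DivergenceStats(gene=aln.gene, length=aln.length,
                                  pv=float("nan"), pi=float("nan"),
                                  dn=float("nan"), ds=float("nan"),
                                  omega=float("nan"), regime="undefined",
                                  error=str(exc))
        rows.append(row)
    return rows


def _one_gene(aln: CodonAlignment, tree, code, fit_m0: bool) -> DivergenceStats:
    pv_val = pv(aln)
    pi_val = pi(aln)
    ng = ng86_mean_pairwise(aln, code)
    if fit_m0:
        try:
            fit = m0_fit(aln, tree, code=code)
        except ConvergenceError as exc:
            fit = exc.fit
        dn, ds, omega = fit.dn, fit.ds, fit.omega
    else:
        dn, ds, omega = ng["dN"], ng["dS"], ng["omega"]
    return DivergenceStats(
        gene=aln.gene, length=aln.length, pv=pv_val, pi=pi_val,
        dn=dn, ds=ds, omega=omega, regime=selection_regime(omega),
        ng86_dn=ng["dN"], ng86_ds=ng["dS"], ng86_omega=ng["omega"],
    )
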