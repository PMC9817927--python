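"""Mutation-pressure vs selection analyses of codon usage bias.

Three complementary views, each per gene across taxa:

* **PR2 plot** — parity rule 2 predicts that without strand-specific
  mutation or selection pressure, G = C and A = T at third codon positions.
  Each gene/taxon pair contributes a point (G3/(G3+C3), A3/(A3+T3));
  distance from (0.5, 0.5) measures the violation.
* **ENC-GC3s plot** — Wright's expected curve gives the ENC a gene would
  have if GC3s alone (i.e. mutation pressure) drove codon choice:
  ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2).  Points below the curve mean
  additional (selective) bias.
* **Neutrality plot** — OLS regression of GC12 on GC3 across taxa.  A slope
  of 1 means third-position composition drags positions 1+2 along
  (pure mutation pressure); 0 means positions 1+2 are decoupled (pure
  selective constraint).  |slope|*100 is reported as the percent
  contribution of mutation pressure; |slope| < 0.5 flags a
  selection-dominated gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

from .codon_usage import CodonCounts, CodonUsageProfile

SELECTION_DOMINATED_SLOPE = 0.5


@dataclass
class PR2Point:
    gene: str
    taxon: str
    gc_bias: float  # G3 / (G3 + C3)
    at_bias: float  # A3 / (A3 + T3)

    @property
    def quadrant(self) -> str:
        if np.isnan(self.gc_bias) or np.isnan(self.at_bias):
            return "undefined"
        gc = "G" if self.gc_bias > 0.5 else "C"
        at = "A" if self.at_bias > 0.5 else "T"
        return gc + at


@dataclass
class NeutralityFit:
    gene: str
    n: int
    slope: float
    intercept: float
    r2: float

    @property
    def mutation_contribution_pct(self) -> float:
        return abs(self.slope) * 100.0

    @property
    def selection_dominated(self) -> bool:
        return abs(self.slope) < SELECTION_DOMINATED_SLOPE


@dataclass
class EncCurvePoint:
    gene: str
    taxon: str
    gc3s: float
    enc_observed: float
    enc_expected: float

    @property
    def deficit(self) -> float:
        return self.enc_expected - self.enc_observed


def pr2_point(counts: CodonCounts) -> PR2Point:
    """PR2 bias coordinates from third-position base totals of sense codons.

    A coordinate whose denominator is zero is NaN rather than an error.
    """
    t3 = counts.third_position_totals()
    gc_den = t3["G"] + t3["C"]
    at_den = t3["A"] + t3["T"]
    gc_bias = t3["G"] / gc_den if gc_den else float("nan")
    at_bias = t3["A"] / at_den if at_den else float("nan")
    return PR2Point(gene=counts.gene, taxon=counts.taxon,
                    gc_bias=gc_bias, at_bias=at_bias)


def enc_expected(gc3s):
    """Wright's expected ENC as a function of GC3s.

    ENC_exp(s) = 2 + s + 29 / (s^2 + (1-s)^2).  Vectorised; the endpoint
    values follow from the same expression (s=0 gives 31, s=1 gives 32).
    """
    s = np.asarray(gc3s, dtype=float)
    val = 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)
    return float(val) if val.ndim == 0 else val


def enc_gc3s_table(profiles: list):
    """Join observed ENC and GC3s per gene/taxon against the expected curve.

    Rows with NaN ENC are dropped (their count is reported).  Returns
    ``(points, summary)`` where summary gives the fraction of points lying
    below the curve (positive deficit).
    """
    points, dropped = [], 0
    for p in profiles:
        if np.isnan(p.enc) or np.isnan(p.gc3s):
            dropped += 1
            continue
        points.append(EncCurvePoint(
            gene=p.gene, taxon=p.taxon, gc3s=p.gc3s,
            enc_observed=p.enc, enc_expected=enc_expected(p.gc3s),
        ))
    below = sum(1 for pt in points if pt.deficit > 0)
    summary = {
        "n_points": len(points),
        "n_dropped": dropped,
        "fraction_below_curve": below / len(points) if points else float("nan"),
    }
    return points, summary


def neutrality_fit(gc3, gc12, gene: str = "") -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3 across taxa for one gene.

    Requires at least 3 points and non-degenerate GC3.  The slope equals
    cov(gc3, gc12)/var(gc3); r2 is the squared Pearson correlation (0 when
    GC12 is constant).
    """
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if len(x) < 3:
        raise ValueError("neutrality fit needs at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("degenerate regressor: GC3 has zero variance")
    if np.all(y == y[0]):
        # linregress returns nan r for a constant response; slope is exactly 0
        return NeutralityFit(gene=gene, n=len(x), slope=0.0,
                             intercept=float(y[0]), r2=0.0)
    res = stats.linregress(x, y)
    return NeutralityFit(gene=gene, n=len(x), slope=float(res.slope),
                         intercept=float(res.intercept), r2=float(res.rvalue) ** 2)


def neutrality_fits_by_gene(profiles: list):
    """One neutrality regression per gene across taxa, sorted by ascending
    mutation-pressure contribution."""
    by_gene: dict = {}
    for p in profiles:
        by_gene.setdefault(p.gene, []).append(p)
    fits = []
    for gene, plist in by_gene.items():
        gc3 = [p.gc3 for p in plist]
        gc12 = [p.gc12 for p in plist]
        try:
            fits.append(neutrality_fit(gc3, gc12, gene=gene))
        except ValueError as exc:
            log.warning("%s: %s (skipped)", gene, exc)
    fits.sort(key=lambda f: f.mutation_contribution_pct)
    return fits
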