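# Methods

This note records the models, conventions and numerical choices behind
`mitocub`, in the order the pipeline applies them.

## Genetic code

Everything runs under the vertebrate mitochondrial code (NCBI translation
table 2, via Biopython): four termination codons (TAA, TAG, AGA, AGG) and
60 sense codons partitioned into 12 two-fold, 6 four-fold and 2 six-fold
synonymous families. Two consequences are worth keeping in mind: the
maximum effective number of codons is 60 (not the standard code's 61), and
every sense codon belongs to a family with at least two synonyms, so GC3s
computed over sense codons coincides with GC3. The code table is a
parameter of every public function for users who need a different
organellar code.

## Genome model and strand labelling

A mitogenome record is the submitted strand of the circular molecule plus
typed gene features with 1-based inclusive coordinates (the GenBank
convention; conversion happens only at I/O boundaries). Free-text gene
names are mapped onto the closed HGNC-style symbol set through a shipped
synonym table; unmapped names are retained with a logged warning rather
than failing the parse.

Strand labels follow composition: the heavy (H) strand is the one with the
higher G+T fraction, its complement is light (L). Because complementarity
makes the two fractions sum to exactly 1, one scan decides both labels; an
exact tie is labelled L with a warning. N bases are excluded from both the
numerator and denominator of every compositional fraction.

Gene order is classified against the ancestral avian arrangement (the
chicken-type order) by rotation-invariant, orientation-aware comparison of
the circular symbol sequence. The published rearrangement taxonomy for
birds distinguishes several derived types, but they lack machine-checkable
signatures, so the classifier returns a binary ancestral/other call plus
the first mismatching position for manual diagnosis. Duplicated symbols
classify as `other` rather than raising.

Incomplete stop codons (`T--`, `TA-`), completed by polyadenylation in
vivo, are detected from the frame remainder of the annotated CDS, not from
annotation notes.

## Codon-usage indices

Codon counting reads successive triplets, drops one trailing complete stop
codon and any trailing incomplete codon, drops in-frame internal stops
with a warning, and ignores codons containing N.

**RSCU** for codon *c* in family *F* is `n_c |F| / Σ_{c'∈F} n_{c'}`;
families with zero observations are NA. Codon-preference classes across
taxa use the unweighted per-codon mean of the non-NA RSCU values:
over-represented above 1.6, preferred in (1.0, 1.6] — the boundary value
1.6 is preferred, matching the strict inequality on the upper class.

**ENC** follows Wright's estimator with the CodonW conventions. Per family
with n ≥ 2 counted codons, the codon homozygosity is
`F̂ = (n Σp_i² − 1)/(n − 1)`; families with F̂ ≤ 0 or n < 2 are skipped.
ENC sums `N_k / mean(F̂)` over degeneracy classes (12/F̄₂ + 6/F̄₄ + 2/F̄₆
under table 2). A class with no qualifying family borrows the unweighted
mean F̂ of the classes that have data — the generalisation of Wright's
`F₃ = (F₂+F₄)/2` rule for the standard code's missing class. The result is
capped at 60. Genes where no family qualifies return NA and are dropped
from curve tables with a reported count.

**GC sites**: GC1/GC2/GC3 are G|C fractions at each codon position over
the counted codons, GC12 their mean. GC3s restricts the third-position
count to codons from families with ≥ 2 synonyms, which under table 2 is
all of them.

## Mutation pressure vs selection

**PR2** uses all sense codons' third positions per gene and taxon:
x = G3/(G3+C3), y = A3/(A3+T3), with an NA coordinate when a denominator
is zero. No restriction to four-fold families is applied, since the axis
definition uses raw third-position counts; both conventions are easy to
obtain from `CodonCounts` if needed.

**ENC–GC3s** compares observed ENC to Wright's expected curve
`ENC_exp(s) = 2 + s + 29/(s² + (1−s)²)`; the endpoints follow from the
same expression (31 at s = 0). "Below the curve" is judged by the sign of
the deficit with no tolerance band, and the summary reports the fraction
below.

**Neutrality plot**: ordinary least squares of GC12 on GC3 across taxa,
per gene (one regression per gene, one point per species). OLS rather than
reduced major axis is used because the analysis interprets a single
regression coefficient of GC12 *on* GC3 as the mutation–selection
equilibrium frequency; |slope|·100 is reported as the percent contribution
of mutation pressure, and |slope| < 0.5 flags a selection-dominated gene.
The fit requires ≥ 3 points and a non-constant regressor; a constant
response returns slope 0 exactly.

## Divergence statistics

**PV** and **π** use complete deletion: any column with a gap or N in any
row is removed from numerator and denominator alike (the default of the
standard polymorphism software this mirrors). PV is the percentage of
remaining columns that vary; π is the mean over unordered pairs of
(differences / retained sites), so π ≤ PV/100 holds row-wise.

**NG86** counts synonymous sites per codon as the fraction of the three
single-base changes at each position that preserve the amino acid; a
change creating a stop counts as nonsynonymous, so S + N = 3 per codon
exactly. Differences between codons are averaged over minimal mutational
pathways, excluding pathways through stop codons (with a fallback to
counting blocked steps as nonsynonymous in the degenerate case where every
pathway is blocked). Proportions are Jukes–Cantor corrected,
`d = −(3/4)ln(1 − 4p/3)`, undefined (NA) at p ≥ 3/4. Note that very short
fragments can saturate: a single synonymous difference in one codon gives
pS = 3 and hence NA — a property of the estimator, not an error.

**M0 (GY94)**: instantaneous rates between sense codons differing at one
position are `π_j · κ^[transition] · ω^[nonsynonymous]`, zero otherwise,
scaled so branch lengths are expected substitutions per codon. F3X4
frequencies come from the alignment's position-specific base composition,
floored at 1e-8 and renormalised. The chain is reversible, so transition
matrices use an eigendecomposition of the π-symmetrised generator, and the
likelihood (Felsenstein pruning over compressed site patterns, per-node
scaling) is invariant to the root.

The fit maximises over κ, ω and all branch lengths — every branch, as
codeml does, not a single scale factor — by deterministic coordinate
sweeps: branches in post-order (reusing the cached eigendecomposition),
then κ ∈ [0.01, 100], then ω ∈ [1e-5, 20], each by bounded Brent search;
initial values κ = 2, ω = 0.2, branches 0.1 where the tree gives none;
convergence when a full sweep improves lnL by < 1e-6. Non-convergence
raises an error carrying the best fit so far. Alignments with no variable
pattern are flagged unidentifiable (branch lengths fall to the lower
bound).

Tree-level dN and dS are decomposed codeml-style: substitution fractions
from the fitted-ω flow, site fractions from the ω = 1 flow of the same κ
and frequencies, `dS = t·ρ_S/(3ρ_S*)` and `dN = t·ρ_N/(3ρ_N*)` with t the
tree length. ω itself is the primary selection quantity; the per-gene
table also carries NG86 mean-pairwise values as a counting-based
companion.

## Synthetic data

The generators exist so every stage can be tested against planted truth,
offline and deterministically (every generator is a pure function of its
seed; cohorts use spawned seed sequences per taxon).

The genome generator lays out 13 protein-coding genes with typical
passerine lengths (MT-ATP8 165 bp … MT-ND5 1815 bp, total genome
16,716 bp), 22 tRNA and 2 rRNA placeholders and one control region in the
ancestral avian order, with MT-ND6 on the opposite strand. Coding bodies
are drawn codon-wise from a product-of-positions distribution built on a
passerine-like light-strand base composition, with a multiplicative
A/C-ending tilt (default 2.0) on light-strand genes and the mirrored G/T
tilt on MT-ND6. The non-coding compartments are drawn from a base
distribution solved so that the whole submitted strand hits the complement
of the heavy-strand G+T target (default 0.617) in expectation; at 16.7 kb
the binomial error is ~0.4%, so the realised asymmetry is reproducible to
well within a percentage point. Targets above 0.9 are rejected as
infeasible. Placeholder RNAs carry only the planted composition — no
secondary structure, no realistic control-region repeats — and the
generator produces no indels, overlapping genes or frameshifts, so passing
tests validate the statistics, not annotation robustness on messy real
records.

The codon-count generator allocates codons to families in proportion to
family size and draws multinomially from planted synonymous probabilities
(explicit, or Dirichlet around the tilted uniform); truth RSCU is
probability × family size. The neutrality generator draws GC3 uniformly on
a configurable range (default 0.35–0.60, matching the spread such genes
show) and adds Gaussian noise to the planted line, clipping to [0, 1] and
reporting clip counts. The M0 simulator draws root codons from the
stationary distribution and evolves them by exact exp(Qt) transition
matrices — the generative twin of the likelihood, so simulation–recovery
tests are internally consistent; frequency vectors used in recovery tests
have exact F3X4 product structure to keep the fitted frequency model
well-specified.

## Problem sizes and tolerances in the test suite

Exact identities (RSCU sums, ENC bounds, curve values, collinear OLS,
complete-deletion fixtures, zero-branch likelihoods) are asserted to
floating-point precision. Stochastic recoveries use tolerances derived
from the estimator's sampling error: the planted neutrality slope 0.1364
with noise SD 0.005 at n = 22 has an OLS standard error of ≈ 0.015, so
recovery is checked as mean-within-±0.03 and ≥ 90% of 200 replicates
within ±0.03 (a 2σ band); ω = 0.1 recovery on a 6-taxon, 800-codon
simulation is checked at ±20% relative, about twice the Monte-Carlo spread
observed across seeds. The likelihood oracle uses a 3-taxon, 2-codon case
small enough for exhaustive 60² internal-state enumeration with dense
matrix exponentials. Cohort-level integration runs 22 taxa, the size at
which the per-strand PR2 quadrant separation is essentially deterministic.

## Known limitations

* Gene extraction trusts the input annotation; boundary post-editing,
  joins across the origin for protein-coding genes, and frameshift repair
  are out of scope.
* The M0 optimiser is a coordinate-sweep method chosen for determinism;
  on ridge-shaped likelihoods (e.g. near-zero variation) it converges to
  the boundary rather than reporting a curvature-based CI. No standard
  errors are computed.
* NG86 pathway handling excludes stop-passing routes (the MEGA
  convention); implementations that include them will differ slightly on
  multi-step codon pairs.
* dN/dS site/substitution decomposition follows the flow-based codeml
  scaling; other definitions of "sites" give different dN and dS but the
  same ω.
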