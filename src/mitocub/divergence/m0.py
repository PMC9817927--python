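"""One-ratio GY94 codon substitution model (M0) with F3X4 frequencies.

The instantaneous rate from sense codon i to j is zero unless they differ
at exactly one position, and otherwise

    q_ij = pi_j            synonymous transversion
         = pi_j * kappa    synonymous transition
         = pi_j * omega    nonsynonymous transversion
         = pi_j * kappa * omega   nonsynonymous transition

with the diagonal set so rows sum to zero and the whole matrix scaled so
branch lengths are expected substitutions per codon.  The chain is
reversible with stationary distribution pi, so transition matrices come
from an eigendecomposition of the pi-symmetrised generator, and the
likelihood is invariant to the root position.  Likelihoods are computed by
Felsenstein pruning over compressed codon site patterns with per-node
scaling; the fit maximises the likelihood over kappa, omega and all branch
lengths by deterministic coordinate sweeps (branches in post-order, then
kappa, then omega) using bounded Brent searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ..genetic_code import GeneticCode, VERTEBRATE_MITO, single_step_class
from .alignment import CodonAlignment

log = logging.getLogger(__name__)

FREQ_FLOOR = 1e-8


@lru_cache(maxsize=None)
def _pair_classification(table_id: int):
    """Indices and (transition, synonymous) flags of all single-step sense
    codon pairs for one code table."""
    from ..genetic_code import get_code
    code = get_code(table_id)
    codons = code.sense_codons
    ii, jj, ts, syn = [], [], [], []
    for a, c1 in enumerate(codons):
        for b, c2 in enumerate(codons):
            if a == b:
                continue
            cls = single_step_class(c1, c2, code)
            if cls is None:
                continue
            ii.append(a)
            jj.append(b)
            ts.append(cls[0])
            syn.append(cls[1])
    return (np.array(ii), np.array(jj),
            np.array(ts, dtype=bool), np.array(syn, dtype=bool))


class CodonModel:
    """A parameterised GY94/M0 rate matrix with cached eigendecomposition."""

    def __init__(self, freqs, kappa: float, omega: float,
                 code: GeneticCode = VERTEBRATE_MITO):
        self.code = code
        self.codons = code.sense_codons
        self.kappa = float(kappa)
        self.omega = float(omega)
        pi = np.asarray(freqs, dtype=float)
        if pi.shape != (len(self.codons),):
            raise ValueError(f"freqs must have length {len(self.codons)}")
        pi = np.maximum(pi, FREQ_FLOOR)
        self.pi = pi / pi.sum()
        self.Q = self._build_q()
        self._decompose()

    def _build_q(self) -> np.ndarray:
        n = len(self.codons)
        ii, jj, ts, syn = _pair_classification(self.code.table_id)
        rate = self.pi[jj].copy()
        rate[ts] *= self.kappa
        rate[~syn] *= self.omega
        Q = np.zeros((n, n))
        Q[ii, jj] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.pi, np.diag(Q)))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        Q /= mu
        # bookkeeping for the dN/dS decomposition
        flow = self.pi[ii] * Q[ii, jj]
        self.syn_flow_fraction = float(flow[syn].sum() / flow.sum())
        return Q

    def _decompose(self) -> None:
        d = np.sqrt(self.pi)
        B = (self.Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0  # enforce exact symmetry
        lam, U = np.linalg.eigh(B)
        self._lam = lam
        self._A = U / d[:, None]        # diag(1/sqrt(pi)) @ U
        self._Binv = (U * d[:, None]).T  # U.T @ diag(sqrt(pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to [0, 1] against round-off."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._A * np.exp(self._lam * t)) @ self._Binv
        return np.clip(P, 0.0, 1.0)


def f3x4_frequencies(alignment: CodonAlignment,
                     code: GeneticCode = VERTEBRATE_MITO) -> np.ndarray:
    """F3X4 codon frequencies from position-specific base composition.

    Base frequencies are tallied separately at the three codon positions
    over all fully resolved codons in the alignment; each sense codon's
    frequency is the product of its three positional base frequencies,
    floored at 1e-8 and renormalised over sense codons.
    """
    pos_counts = np.zeros((3, 4))
    base_index = {b: k for k, b in enumerate("ACGT")}
    for row in alignment.rows:
        row = row.upper()
        for k in range(0, len(row) - len(row) % 3, 3):
            codon = row[k:k + 3]
            if any(b not in base_index for b in codon):
                continue
            for p in range(3):
                pos_counts[p, base_index[codon[p]]] += 1
    if pos_counts.sum() == 0:
        raise ValueError("no resolved codons in alignment")
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    freqs = np.array([
        pos_freqs[0, base_index[c[0]]]
        * pos_freqs[1, base_index[c[1]]]
        * pos_freqs[2, base_index[c[2]]]
        for c in code.sense_codons
    ])
    freqs = np.maximum(freqs, FREQ_FLOOR)
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# pruning machinery

class _PrunedTree:
    """Post-order node list and compressed site patterns for fast pruning."""

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree,
                 code: GeneticCode):
        self.code = code
        codon_index = {c: k for k, c in enumerate(code.sense_codons)}
        n_states = len(code.sense_codons)

        taxon_rows = {}
        for taxon, row in zip(alignment.taxa, alignment.rows):
            taxon_rows[taxon] = row.upper()

        nodes = list(tree.postorder_node_iter())
        self.node_children: list = []
        self.node_edge: list = []
        self.leaf_taxon: list = []
        index_of = {}
        for i, nd in enumerate(nodes):
            index_of[nd] = i
            self.node_children.append([index_of[ch] for ch in nd.child_nodes()])
            self.node_edge.append(nd.edge.length if nd.edge.length is not None else 0.0)
            self.leaf_taxon.append(nd.taxon.label if nd.is_leaf() else None)
        self.root_index = len(nodes) - 1

        leaf_labels = [lbl for lbl in self.leaf_taxon if lbl is not None]
        missing = set(alignment.taxa) - set(leaf_labels)
        extra = set(leaf_labels) - set(alignment.taxa)
        if missing or extra:
            raise ValueError(
                f"tree/alignment taxon mismatch (missing from tree: {sorted(missing)}, "
                f"not in alignment: {sorted(extra)})")

        # column codon states per taxon; -1 = missing (gap or ambiguity)
        n_codon_cols = alignment.length // 3
        states = {}
        for taxon, row in taxon_rows.items():
            arr = np.full(n_codon_cols, -1, dtype=int)
            for k in range(n_codon_cols):
                arr[k] = codon_index.get(row[3 * k: 3 * k + 3], -1)
            states[taxon] = arr

        cols = np.stack([states[lbl] for lbl in leaf_labels], axis=0)  # leaves x sites
        patterns, self.weights = np.unique(cols, axis=1, return_counts=True)
        self.n_patterns = patterns.shape[1]

        # per-leaf tip partials as index arrays; build dense partials lazily
        self.tip_states = {}
        for r, lbl in enumerate(leaf_labels):
            self.tip_states[lbl] = patterns[r]
        self.n_states = n_states

    def loglik(self, model: CodonModel, edge_lengths=None) -> float:
        """Scaled pruning log-likelihood over compressed patterns."""
        if edge_lengths is None:
            edge_lengths = self.node_edge
        npat, nst = self.n_patterns, self.n_states
        partial = {}
        scale = np.zeros(npat)
        for i, children in enumerate(self.node_children):
            if not children:  # leaf
                L = np.zeros((npat, nst))
                st = self.tip_states[self.leaf_taxon[i]]
                obs = st >= 0
                L[np.where(obs)[0], st[obs]] = 1.0
                L[~obs, :] = 1.0
                partial[i] = L
            else:
                L = np.ones((npat, nst))
                for ch in children:
                    P = model.transition_matrix(edge_lengths[ch])
                    L *= partial.pop(ch) @ P.T
                if i != self.root_index:
                    mx = L.max(axis=1)
                    mx[mx == 0] = 1.0
                    L /= mx[:, None]
                    scale += np.log(mx)
                partial[i] = L
        root_L = partial[self.root_index] @ model.pi
        if np.any(root_L <= 0):
            raise ValueError("non-finite likelihood (zero site likelihood)")
        lnl = float(np.dot(self.weights, np.log(root_L) + scale))
        if not np.isfinite(lnl):
            raise ValueError("non-finite likelihood")
        return lnl


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    return dendropy.Tree.get(data=str(tree), schema="newick",
                             preserve_underscores=True)


def m0_loglik(alignment: CodonAlignment, tree, kappa: float, omega: float,
              freqs, code: GeneticCode = VERTEBRATE_MITO) -> float:
    """Log-likelihood of a codon alignment under M0 at fixed parameters.

    ``tree`` may be a newick string or a dendropy Tree whose edge lengths
    are the branch lengths to use.
    """
    t = _load_tree(tree)
    pruned = _PrunedTree(alignment, t, code)
    model = CodonModel(freqs, kappa, omega, code)
    return pruned.loglik(model)


@dataclass
class M0Fit:
    kappa: float
    omega: float
    lnl: float
    branch_lengths: list
    tree_length: float
    freqs: np.ndarray = field(repr=False)
    dn: float = float("nan")
    ds: float = float("nan")
    converged: bool = True
    identifiable: bool = True
    n_sweeps: int = 0


class ConvergenceError(RuntimeError):
    """Raised when coordinate sweeps exhaust the budget; carries the
    best fit so far in ``.fit``."""

    def __init__(self, message, fit):
        super().__init__(message)
        self.fit = fit


def _dn_ds_decomposition(fit_model: CodonModel, tree_length: float,
                         code: GeneticCode):
    """codeml-style dN/dS scaling.

    Site fractions come from the neutral (omega=1) flow of the same kappa
    and frequencies; substitution fractions from the fitted flow; branch
    lengths are expected substitutions per codon, and sites per codon are
    3 * fraction.
    """
    neutral = CodonModel(fit_model.pi, fit_model.kappa, 1.0, code)
    rho_s1 = neutral.syn_flow_fraction
    rho_s = fit_model.syn_flow_fraction
    ds = tree_length * rho_s / (3.0 * rho_s1)
    dn = tree_length * (1.0 - rho_s) / (3.0 * (1.0 - rho_s1))
    return dn, ds


def m0_fit(alignment: CodonAlignment, tree,
           code: GeneticCode = VERTEBRATE_MITO,
           kappa_init: float = 2.0, omega_init: float = 0.2,
           branch_init: float = 0.1, max_sweeps: int = 60,
           tol: float = 1e-6) -> M0Fit:
    """Maximum-likelihood M0 fit on a fixed topology.

    F3X4 frequencies are taken from the alignment.  Branch lengths are
    initialised at ``branch_init`` where the input tree does not provide
    them.  Optimisation is by deterministic coordinate sweeps — every
    branch in post-order, then kappa, then omega, each by bounded Brent —
    until the log-likelihood improves by less than ``tol`` over a full
    sweep.  Genes shorter than 50 codons trigger a warning; an alignment
    with no variable patterns is flagged unidentifiable.
    """
    if alignment.n_taxa < 3:
        raise ValueError("M0 fit needs at least 3 sequences")
    if alignment.length // 3 < 50:
        log.warning("%s: fewer than 50 codons; M0 estimates will be noisy",
                    alignment.gene or "alignment")

    t = _load_tree(tree)
    pruned = _PrunedTree(alignment, t, code)
    freqs = f3x4_frequencies(alignment, code)

    edges = list(pruned.node_edge)
    for i in range(len(edges)):
        if not edges[i] or edges[i] <= 0:
            edges[i] = branch_init if i != pruned.root_index else 0.0
    edges[pruned.root_index] = 0.0
    # optimisable edges: every non-root node's subtending branch
    opt_edges = [i for i in range(len(edges)) if i != pruned.root_index]

    identifiable = len(set(alignment.rows)) > 1
    kappa, omega = float(kappa_init), float(omega_init)

    B_LO, B_HI = 1e-8, 50.0
    K_LO, K_HI = 1e-2, 100.0
    W_LO, W_HI = 1e-5, 20.0

    model = CodonModel(freqs, kappa, omega, code)
    lnl = pruned.loglik(model, edges)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        prev = lnl
        # branches (rate matrix fixed: reuse the eigendecomposition)
        for ei in opt_edges:
            def nll_branch(x, _ei=ei):
                trial = edges.copy()
                trial[_ei] = x
                return -pruned.loglik(model, trial)
            res = minimize_scalar(nll_branch, bounds=(B_LO, B_HI),
                                  method="bounded",
                                  options={"xatol": 1e-9})
            edges[ei] = float(res.x)
        # kappa
        def nll_kappa(x):
            return -pruned.loglik(CodonModel(freqs, x, omega, code), edges)
        res = minimize_scalar(nll_kappa, bounds=(K_LO, K_HI), method="bounded",
                              options={"xatol": 1e-6})
        kappa = float(res.x)
        # omega
        def nll_omega(x):
            return -pruned.loglik(CodonModel(freqs, kappa, x, code), edges)
        res = minimize_scalar(nll_omega, bounds=(W_LO, W_HI), method="bounded",
                              options={"xatol": 1e-7})
        omega = float(res.x)
        model = CodonModel(freqs, kappa, omega, code)
        lnl = pruned.loglik(model, edges)
        if abs(lnl - prev) < tol:
            converged = True
            break

    tree_length = float(sum(edges[i] for i in opt_edges))
    if not identifiable:
        log.warning("alignment has no variation; omega is unidentifiable")
    dn, ds = _dn_ds_decomposition(model, tree_length, code)
    fit = M0Fit(kappa=kappa, omega=omega, lnl=lnl,
                branch_lengths=[edges[i] for i in opt_edges],
                tree_length=tree_length, freqs=freqs, dn=dn, ds=ds,
                converged=converged, identifiable=identifiable,
                n_sweeps=sweeps)
    if not converged:
        raise ConvergenceError(
            f"M0 fit did not converge in {max_sweeps} sweeps", fit)
    return fit
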