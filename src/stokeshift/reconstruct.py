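"""Marginal empirical-Bayes ancestral reconstruction.

Computes, for every inner node and alignment site, the posterior distribution
over the 20 amino acids under a reversible replacement matrix with
discrete-gamma rate heterogeneity.  The inside (Felsenstein pruning) pass
propagates partial likelihoods from the leaves to the root; the outside pass
propagates the complementary likelihood of everything outside each node's
subtree; their product, weighted over rate categories and renormalized, is
the marginal posterior.  Per-node, per-site scaling keeps the recursion in
range for alignments of at least ten thousand sites.

Gap and ``X`` leaf states are missing data (all-ones partial likelihoods),
so an all-gap column's posterior falls back to the model's equilibrium
frequencies.  Rate categories are integrated out, not assigned per site.
"""

from __future__ import annotations

import numpy as np

from .io import (
    AMINO_ACIDS,
    AncestralLibrary,
    AncestralProfile,
    GammaRates,
    MISSING_CODE,
    MultipleAlignment,
    N_STATES,
    PhyloTree,
    ReversibleRateMatrix,
)


class ReconstructionError(RuntimeError):
    pass


class TransitionCalculator:
    """Transition probabilities P(t) = exp(Qt) via the symmetric
    eigendecomposition available for reversible generators."""

    def __init__(self, matrix: ReversibleRateMatrix):
        pi = matrix.frequencies
        self._sq = np.sqrt(pi)
        sym = self._sq[:, None] * matrix.q / self._sq[None, :]
        self._eigval, self._eigvec = np.linalg.eigh((sym + sym.T) / 2.0)

    def probabilities(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        w = self._eigvec * np.exp(self._eigval * t)[None, :]
        p = (w @ self._eigvec.T) / self._sq[:, None] * self._sq[None, :]
        np.clip(p, 0.0, None, out=p)
        return p


def _leaf_partials(aln: MultipleAlignment, tree: PhyloTree) -> dict[int, np.ndarray]:
    codes = aln.encode()
    row_of = {sid: k for k, sid in enumerate(aln.ids)}
    partials: dict[int, np.ndarray] = {}
    for i in range(tree.n_nodes):
        if not tree.is_leaf[i]:
            continue
        name = tree.names[i]
        if name not in row_of:
            raise ReconstructionError(f"leaf '{name}' missing from alignment")
        c = codes[row_of[name]]
        arr = np.zeros((aln.length, N_STATES))
        obs = c < MISSING_CODE
        arr[np.nonzero(obs)[0], c[obs]] = 1.0
        arr[~obs] = 1.0
        partials[i] = arr
    return partials


def _category_pass(
    tree: PhyloTree,
    leaf_partials: dict[int, np.ndarray],
    calc: TransitionCalculator,
    rate: float,
    length: int,
):
    """Inside and outside arrays (with per-site log scalings) for one rate
    category.  Returns (inside, log_in, outside, log_out, site_loglik)."""
    pmats = [calc.probabilities(tree.branch_lengths[i] * rate) for i in range(tree.n_nodes)]
    inside: list[np.ndarray | None] = [None] * tree.n_nodes
    log_in = np.zeros((tree.n_nodes, length))
    message: list[np.ndarray | None] = [None] * tree.n_nodes

    for i in tree.postorder():
        if tree.is_leaf[i]:
            inside[i] = leaf_partials[i]
        else:
            acc = np.ones((length, N_STATES))
            for c in tree.children[i]:
                acc *= message[c]
                log_in[i] += log_in[c]
            scale = acc.max(axis=1)
            if np.any(scale <= 0.0):
                raise ReconstructionError(
                    "zero partial likelihood (numerical underflow) at node "
                    f"'{tree.names[i]}'"
                )
            acc /= scale[:, None]
            log_in[i] += np.log(scale)
            inside[i] = acc
        if i != tree.root:
            message[i] = inside[i] @ pmats[i].T

    pi = calc._sq**2
    root_site = inside[tree.root] @ pi
    site_loglik = np.log(root_site) + log_in[tree.root]

    outside: list[np.ndarray | None] = [None] * tree.n_nodes
    log_out = np.zeros((tree.n_nodes, length))
    outside[tree.root] = np.tile(pi, (length, 1))
    for i in tree.preorder():
        if tree.is_leaf[i]:
            continue
        kids = tree.children[i]
        for c in kids:
            acc = outside[i].copy()
            lg = log_out[i].copy()
            for sib in kids:
                if sib == c:
                    continue
                acc *= message[sib]
                lg += log_in[sib]
            out = acc @ pmats[c]
            scale = out.max(axis=1)
            dead = scale <= 0.0  # possible only with reducible generators
            scale[dead] = 1.0
            out /= scale[:, None]
            with np.errstate(divide="ignore"):
                lg += np.log(scale)
            lg[dead] = -np.inf
            outside[c] = out
            log_out[c] = lg
    return inside, log_in, outside, log_out, site_loglik


def log_likelihood(
    aln: MultipleAlignment,
    tree: PhyloTree,
    matrix: ReversibleRateMatrix,
    rates: GammaRates,
) -> float:
    """Total log-likelihood of the alignment on the tree."""
    calc = TransitionCalculator(matrix)
    leaves = _leaf_partials(aln, tree)
    per_cat = np.empty((rates.ncat, aln.length))
    for c in range(rates.ncat):
        *_, site_ll = _category_pass(tree, leaves, calc, float(rates.rates[c]), aln.length)
        per_cat[c] = site_ll + np.log(rates.weights[c])
    m = per_cat.max(axis=0)
    return float(np.sum(m + np.log(np.exp(per_cat - m).sum(axis=0))))


def marginal_posteriors(
    aln: MultipleAlignment,
    tree: PhyloTree,
    matrix: ReversibleRateMatrix,
    rates: GammaRates,
) -> AncestralProfile:
    """Posterior amino-acid distributions at every inner node and site."""
    calc = TransitionCalculator(matrix)
    leaves = _leaf_partials(aln, tree)
    length = aln.length
    inner = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]

    accum = {i: np.zeros((length, N_STATES)) for i in inner}
    accum_log = {i: np.full(length, -np.inf) for i in inner}
    for c in range(rates.ncat):
        inside, log_in, outside, log_out, _ = _category_pass(
            tree, leaves, calc, float(rates.rates[c]), length
        )
        logw = np.log(rates.weights[c])
        for i in inner:
            joint = inside[i] * outside[i]
            lg = log_in[i] + log_out[i] + logw
            m = np.maximum(accum_log[i], lg)
            finite = np.isfinite(m)
            w_old = np.zeros(length)
            w_new = np.zeros(length)
            w_old[finite] = np.exp(accum_log[i][finite] - m[finite])
            w_new[finite] = np.exp(lg[finite] - m[finite])
            accum[i] = accum[i] * w_old[:, None] + joint * w_new[:, None]
            accum_log[i] = m

    profiles = {}
    for i in inner:
        total = accum[i].sum(axis=1)
        if np.any(total <= 0):
            raise ReconstructionError(
                f"zero posterior mass at node '{tree.names[i]}'"
            )
        profiles[tree.names[i]] = accum[i] / total[:, None]
    return AncestralProfile(profiles)


def sample_library(
    profile: AncestralProfile, node: str, n_samples: int, seed: int
) -> AncestralLibrary:
    """Draw ``n_samples`` ancestral sequences site-independently from the
    node's marginal posteriors (the "full" ancestral library)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if node not in profile:
        raise KeyError(f"node '{node}' not in profile")
    pp = profile[node]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(pp, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n_samples, pp.shape[0]))
    idx = np.empty_like(u, dtype=int)
    for s in range(pp.shape[0]):
        idx[:, s] = np.searchsorted(cum[s], u[:, s], side="right")
    seqs = ["".join(AMINO_ACIDS[a] for a in row) for row in idx]
    return AncestralLibrary(node=node, sequences=seqs, provenance="sampled")
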