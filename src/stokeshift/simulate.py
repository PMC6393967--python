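"""Synthetic data: Yule trees, sequence evolution with branch shifts, gaps.

The simulator is the pipeline's positive and negative control.  Sequences
evolve site-independently on a rooted tree under a reversible replacement
matrix with a discrete-gamma category fixed per site across the whole tree.
Designated *shift* branches substitute a different generator — by default
the same matrix with its exchangeabilities permuted by a fixed derangement
and rescaled to unit rate, so substitutions that are globally rare become
locally common while the expected number of substitutions is unchanged.
That is exactly the deviation the rare-substitution d-measure is built to
detect, whereas a rate scaling would not be.  All ancestral sequences are
recorded so reconstruction and branch scores can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    AMINO_ACIDS,
    GammaRates,
    MultipleAlignment,
    N_STATES,
    PhyloTree,
    ReversibleRateMatrix,
)
from .reconstruct import TransitionCalculator


@dataclass
class SimulationTruth:
    """Everything the simulator knows that an analysis would have to infer."""

    tree: PhyloTree
    true_ancestors: dict[str, str]
    shift_branches: frozenset[str]  # identified by child-node name
    shift_matrix: ReversibleRateMatrix | None
    seed: int


def simulate_yule_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    height: float = 1.0,
) -> PhyloTree:
    """A rooted bifurcating pure-birth tree, rescaled to the target height.

    Waiting times between splits are Exp(k·birth_rate) with k the current
    lineage count; after the last split every open lineage is extended by a
    final Exp(n·birth_rate) draw, then all node depths are rescaled so the
    leaves sit at ``height`` substitutions/site from the root.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    # root is the first divergence, at time 0; each node records its birth
    # time and, once it splits, its split time and children
    birth = [0.0, 0.0, 0.0]
    split: list[float | None] = [0.0, None, None]
    children: list[tuple[int, int] | None] = [(1, 2), None, None]
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        pick = active[rng.integers(len(active))]
        kids = (len(birth), len(birth) + 1)
        for _ in range(2):
            birth.append(t)
            split.append(None)
            children.append(None)
        split[pick] = t
        children[pick] = kids
        active.remove(pick)
        active.extend(kids)
    total = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    scale = height / total
    leaf_counter = iter(range(1, n_taxa + 1))

    def newick(i: int) -> str:
        end = total if children[i] is None else split[i]
        blen = (end - birth[i]) * scale
        if children[i] is None:
            return f"T{next(leaf_counter)}:{blen!r}"
        l, r = children[i]
        inner = f"({newick(l)},{newick(r)})"
        return inner if i == 0 else f"{inner}:{blen!r}"

    return PhyloTree.from_newick(newick(0) + ";")


def derange_exchangeabilities(matrix: ReversibleRateMatrix) -> ReversibleRateMatrix:
    """The default shift process: exchangeabilities rank-reversed.

    The 190 exchangeabilities are permuted by the fixed derangement that
    sends the k-th largest value to the position of the k-th smallest, over
    unchanged frequencies, rescaled to unit expected rate.  Replacements the
    original matrix considers rarest thereby become the most frequent, while
    the expected number of substitutions per unit branch length is the same
    — the deviation is in *which* substitutions occur, not how many.
    """
    tri = matrix.lower_triangle()
    order = np.argsort(tri, kind="stable")
    out = np.empty_like(tri)
    out[order] = tri[order[::-1]]
    return ReversibleRateMatrix.from_lower_triangle(out, matrix.frequencies)


def choose_shift_branch(
    tree: PhyloTree, seed: int | None = None, min_length_fraction: float = 0.3
) -> str:
    """Designate (seeded) the branch carrying the synthetic conversion event.

    The event must be expressed through substitutions to exist at all, so
    the branch is drawn uniformly among internal branches (child a non-root
    inner node) spanning at least ``min_length_fraction`` of the tree height
    — a major evolutionary episode, roughly that fraction of a substitution
    per site.  If no internal branch is that long, the longest one is used.
    """
    candidates = sorted(child for _, child in tree.inner_branches())
    if not candidates:
        raise ValueError("tree has no internal branches")
    floor = min_length_fraction * tree.height()
    long_enough = [c for c in candidates if tree.branch_lengths[tree.index[c]] >= floor]
    if not long_enough:
        return max(candidates, key=lambda c: tree.branch_lengths[tree.index[c]])
    rng = np.random.default_rng(seed)
    return long_enough[rng.integers(len(long_enough))]


def _sample_children(
    parent_states: np.ndarray, pmat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(pmat, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.size)
    rows = cum[parent_states]
    return (u[:, None] > rows).sum(axis=1)


def simulate_evolution(
    tree: PhyloTree,
    matrix: ReversibleRateMatrix,
    rates: GammaRates,
    length: int,
    seed: int | None = None,
    shift_branches: frozenset[str] | set[str] = frozenset(),
    shift_matrix: ReversibleRateMatrix | None = None,
) -> tuple[MultipleAlignment, SimulationTruth]:
    """Evolve a root sequence drawn from equilibrium down the tree.

    ``shift_branches`` names child nodes whose parent branch evolves under
    ``shift_matrix`` (default: the deranged-exchangeability variant of
    ``matrix``).  Returns the gap-free leaf alignment and the full truth
    record.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    shift_branches = frozenset(shift_branches)
    unknown = shift_branches - set(tree.names)
    if unknown:
        raise ValueError(f"shift branches not in tree: {sorted(unknown)}")
    if shift_branches and shift_matrix is None:
        shift_matrix = derange_exchangeabilities(matrix)
    rng = np.random.default_rng(seed)
    cats = rng.integers(rates.ncat, size=length)
    root_states = rng.choice(N_STATES, size=length, p=matrix.frequencies)

    calc = TransitionCalculator(matrix)
    shift_calc = TransitionCalculator(shift_matrix) if shift_matrix is not None else None
    states: dict[int, np.ndarray] = {tree.root: root_states}
    for i in tree.preorder():
        if i == tree.root:
            continue
        use_shift = tree.names[i] in shift_branches
        c = shift_calc if use_shift else calc
        child = np.empty(length, dtype=int)
        for cat in range(rates.ncat):
            mask = cats == cat
            if not mask.any():
                continue
            pmat = c.probabilities(tree.branch_lengths[i] * float(rates.rates[cat]))
            child[mask] = _sample_children(states[tree.parent[i]][mask], pmat, rng)
        states[i] = child

    def seq(i: int) -> str:
        return "".join(AMINO_ACIDS[a] for a in states[i])

    ids = [tree.names[i] for i in range(tree.n_nodes) if tree.is_leaf[i]]
    rows = [seq(i) for i in range(tree.n_nodes) if tree.is_leaf[i]]
    ancestors = {
        tree.names[i]: seq(i) for i in range(tree.n_nodes) if not tree.is_leaf[i]
    }
    truth = SimulationTruth(
        tree=tree,
        true_ancestors=ancestors,
        shift_branches=shift_branches,
        shift_matrix=shift_matrix if shift_branches else None,
        seed=seed if seed is not None else -1,
    )
    return MultipleAlignment(ids, rows), truth


def inject_gaps(
    aln: MultipleAlignment,
    site_gap_profile,
    seq_gap_profile,
    seed: int | None = None,
) -> MultipleAlignment:
    """Insert gaps by independent Bernoulli draws.

    ``site_gap_profile`` (length n_sites) and ``seq_gap_profile`` (length
    n_sequences) give per-column and per-row gap probabilities; a cell gaps
    with probability 1 − (1 − p_site)(1 − p_seq).
    """
    ps = np.asarray(site_gap_profile, dtype=float)
    pq = np.asarray(seq_gap_profile, dtype=float)
    if ps.shape != (aln.length,) or pq.shape != (aln.n_sequences,):
        raise ValueError("gap profiles must match alignment dimensions")
    p = 1.0 - (1.0 - ps[None, :]) * (1.0 - pq[:, None])
    rng = np.random.default_rng(seed)
    mask = rng.random(p.shape) < p
    rows = [
        "".join("-" if mask[i, s] else row[s] for s in range(aln.length))
        for i, row in enumerate(aln.rows)
    ]
    return MultipleAlignment(list(aln.ids), rows)
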