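"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import stokeshift as ss
from stokeshift.epistasis import classify_branches
from stokeshift.structure import (
    classify_structural_branches,
    mock_predictor,
    score_tree_structure,
)


@pytest.fixture(scope="session")
def jtt() -> ss.ReversibleRateMatrix:
    return ss.ReversibleRateMatrix.jtt()


@pytest.fixture(scope="session")
def gamma6() -> ss.GammaRates:
    return ss.discrete_gamma(1.0, 6)


@pytest.fixture()
def small_alignment() -> ss.MultipleAlignment:
    return ss.MultipleAlignment(
        ["A", "B", "C", "D"],
        ["ACDEF", "ACDEW", "ACDKF", "GCDKF"],
    )


@pytest.fixture()
def small_tree() -> ss.PhyloTree:
    return ss.PhyloTree.from_newick(
        "((A:0.1,B:0.15):0.2,(C:0.12,D:0.08):0.1);"
    )


def make_profile(site_pps: list[dict[str, float]]) -> ss.AncestralProfile:
    """Build a one-node profile from per-site {amino acid: probability}
    mappings; unassigned mass is spread over the remaining amino acids."""
    arr = np.zeros((len(site_pps), 20))
    for s, pps in enumerate(site_pps):
        rest = 1.0 - sum(pps.values())
        others = [a for a in ss.io.AMINO_ACIDS if a not in pps]
        for a, p in pps.items():
            arr[s, ss.io.AA_INDEX[a]] = p
        if others:
            for a in others:
                arr[s, ss.io.AA_INDEX[a]] = rest / len(others)
    return ss.AncestralProfile({"node": arr})


def shift_replicate(
    seed: int,
    matrix: ss.ReversibleRateMatrix,
    rates: ss.GammaRates,
    n_taxa: int = 16,
    length: int = 300,
    with_shift: bool = True,
) -> dict:
    """One end-to-end replicate: simulate (optionally with a conversion
    event on a designated internal branch), reconstruct, score, classify.

    Returns the designated branch, the epistasis classification frame and
    the per-track structural classification frames.
    """
    tree = ss.simulate_yule_tree(n_taxa, seed=seed)
    target = ss.choose_shift_branch(tree, seed)
    shifts = frozenset({target}) if with_shift else frozenset()
    aln, truth = ss.simulate_evolution(
        tree, matrix, rates, length, seed=seed + 2**20, shift_branches=shifts
    )
    profile = ss.marginal_posteriors(aln, tree, matrix, rates)
    epi = classify_branches(ss.score_tree_epistasis(profile, tree, matrix))
    libraries = ss.generate_all_libraries(profile)
    freqs = score_tree_structure(libraries, tree, mock_predictor)
    struct = classify_structural_branches(freqs)
    return {
        "tree": tree,
        "target": target,
        "truth": truth,
        "profile": profile,
        "epistasis": epi,
        "structural": struct,
    }
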