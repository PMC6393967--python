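"""Branch-level rare-substitution (epistatic conversion) scoring.

A substitution a→b that is rare under the protein's own reversible
replacement matrix but well supported by the ancestral posteriors is the
signature of an evolutionary 'Stokes shift': the residue landscape around a
site has moved, entrenching states the global matrix considers unlikely.

Per substitution the score is

    d = PP_a · PP_b · 2 · NC,      NC = 1 / (1 + exp(200 · RF_ab)),

where PP_a and PP_b are the posterior probabilities of amino acids a (at the
branch's parent node) and b (at its child node), a ≠ b, and RF_ab is the
relative instantaneous rate of the a→b replacement in the unit-scaled
reversible matrix.  NC is at most 1/2 (attained as RF_ab → 0) and decays
steeply for common replacements, so d rewards confident, rare substitutions.
Per branch, d is summed over all sites and ordered pairs and the natural log
of the sum taken; log-sums are then compared nonparametrically across the
tree (percentile ranks, quartiles Q1–Q4, and a high-percentile flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (
    AA_INDEX,
    AncestralProfile,
    MISSING_CODE,
    MultipleAlignment,
    N_STATES,
    PhyloTree,
    ReversibleRateMatrix,
)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class DMeasureParams:
    """Constants of the d-measure.

    ``steepness`` is the coefficient on RF_ab inside the logistic NC term;
    ``factor`` the overall multiplier (2 keeps d within [0, 1]);
    ``pp_square_variant`` switches to the alternative reading
    d = PP_a · PP_b² · NC of the printed formula.
    """

    steepness: float = 200.0
    factor: float = 2.0
    pp_square_variant: bool = False

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


def nonconservation_weight(rf_ab: float, params: DMeasureParams = DMeasureParams()) -> float:
    """NC = 1/(1 + exp(steepness · RF_ab)) ∈ (0, 1/2]."""
    if rf_ab < 0:
        raise ValueError("relative rate must be non-negative")
    return 1.0 / (1.0 + math.exp(params.steepness * rf_ab))


def d_measure(
    pp_a: float, pp_b: float, rf_ab: float, params: DMeasureParams = DMeasureParams()
) -> float:
    """Posterior-weighted rarity score of one substitution a→b."""
    if not (0.0 <= pp_a <= 1.0 and 0.0 <= pp_b <= 1.0):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    nc = nonconservation_weight(rf_ab, params)
    if params.pp_square_variant:
        return pp_a * pp_b * pp_b * nc
    return pp_a * pp_b * params.factor * nc


def d_weight_matrix(
    matrix: ReversibleRateMatrix, params: DMeasureParams = DMeasureParams()
) -> np.ndarray:
    """20×20 weights w_ab = factor·NC(q_ab) off-diagonal, 0 on the diagonal.

    RF_ab is read directly from the unit-scaled generator, direction a→b
    (no symmetrization).
    """
    q = np.maximum(matrix.q, 0.0)
    w = 1.0 / (1.0 + np.exp(params.steepness * q))
    if not params.pp_square_variant:
        w = w * params.factor
    np.fill_diagonal(w, 0.0)
    return w


def branch_epistasis_logsum(
    parent_pp: np.ndarray,
    child_pp: np.ndarray,
    matrix: ReversibleRateMatrix,
    params: DMeasureParams = DMeasureParams(),
) -> float:
    """ln Σ_sites Σ_{a≠b} d(PP_parent(a), PP_child(b), RF_ab).

    ``parent_pp`` and ``child_pp`` are (n_sites, 20) posterior arrays over
    the same sites (a leaf contributes point-mass rows; all-zero rows, e.g.
    gapped leaf sites, simply contribute nothing).
    """
    parent_pp = np.asarray(parent_pp, dtype=float)
    child_pp = np.asarray(child_pp, dtype=float)
    if parent_pp.shape != child_pp.shape or parent_pp.ndim != 2:
        raise ScoringError("parent and child profiles must share (n_sites, 20) shape")
    if parent_pp.shape[0] == 0:
        raise ScoringError("zero-length profiles")
    w = d_weight_matrix(matrix, params)
    cc = child_pp * child_pp if params.pp_square_variant else child_pp
    total = float(np.einsum("sa,ab,sb->", parent_pp, w, cc))
    if total <= 0.0:
        raise ScoringError("d-measure sum is zero; log-sum undefined")
    return math.log(total)


def leaf_profile(aln: MultipleAlignment, leaf_id: str) -> np.ndarray:
    """Point-mass posterior rows for an observed sequence (gap/X rows zero)."""
    row = aln.rows[aln.ids.index(leaf_id)]
    pp = np.zeros((len(row), N_STATES))
    for s, ch in enumerate(row):
        code = AA_INDEX.get(ch, MISSING_CODE)
        if code < MISSING_CODE:
            pp[s, code] = 1.0
    return pp


def score_tree_epistasis(
    profile: AncestralProfile,
    tree: PhyloTree,
    matrix: ReversibleRateMatrix,
    params: DMeasureParams = DMeasureParams(),
    include_leaf_branches: bool = False,
    aln: MultipleAlignment | None = None,
) -> dict[tuple[str, str], float]:
    """Epistasis log-sums for every scored branch.

    By default only branches terminating in an inner node are scored; with
    ``include_leaf_branches`` leaf-terminated branches are added, their
    child profile being the observed sequence as point masses (requires
    ``aln``).
    """
    scores: dict[tuple[str, str], float] = {}
    for parent, child in tree.branches():
        child_idx = tree.index[child]
        if tree.is_leaf[child_idx]:
            if not include_leaf_branches:
                continue
            if aln is None:
                raise ScoringError("alignment required to score leaf branches")
            child_pp = leaf_profile(aln, child)
        else:
            child_pp = profile[child]
        scores[(parent, child)] = branch_epistasis_logsum(
            profile[parent], child_pp, matrix, params
        )
    return scores


# ---------------------------------------------------------------------------
# Nonparametric branch classification
# ---------------------------------------------------------------------------

def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Hazen percentile ranks, (rank − ½)/n · 100, midpoint ranks for ties."""
    values = np.asarray(values, dtype=float)
    ranks = rankdata(values, method="average")
    return (ranks - 0.5) / values.size * 100.0


def quartile_labels(percentiles: np.ndarray) -> list[str]:
    edges = np.array([25.0, 50.0, 75.0])
    return [f"Q{1 + int(np.sum(p > edges))}" for p in percentiles]


def classify_branches(
    scores: dict[tuple[str, str], float], flag_percentile: float = 95.0
) -> pd.DataFrame:
    """Percentile rank, quartile and flag for each scored branch.

    Flagging uses ``percentile >= flag_percentile``.  At least two branches
    are required; quartiles only become meaningful from four.
    """
    if len(scores) < 2:
        raise ScoringError("need at least 2 scored branches to classify")
    branches = list(scores)
    vals = np.array([scores[b] for b in branches], dtype=float)
    pct = percentile_ranks(vals)
    df = pd.DataFrame(
        {
            "parent": [b[0] for b in branches],
            "child": [b[1] for b in branches],
            "score": vals,
            "percentile": pct,
            "quartile": quartile_labels(pct),
            "flag": pct >= flag_percentile,
        }
    )
    return df
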