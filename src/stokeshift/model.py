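"""Protein-specific substitution-model estimation and discrete-gamma rates.

The relative-rate estimator recovers a reversible amino-acid replacement
matrix directly from an alignment: equilibrium frequencies come from residue
counts (one pseudocount per amino acid), replacement counts are pooled over
sequence pairs inside an identity window, corrected for multiple hits by a
matrix logarithm of the pooled replacement-probability matrix, and projected
back to the nearest valid reversible generator.  The resulting matrix is the
source of the relative rates RF(a,b) consumed by the rare-substitution
d-measure.

Rate heterogeneity across sites uses the standard discrete-gamma
approximation with equal-weight categories, each category taking the mean of
its gamma quantile bin (so the category mean is exactly one).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import logm
from scipy.stats import gamma as _gamma

from .io import (
    GammaRates,
    MISSING_CODE,
    MultipleAlignment,
    N_STATES,
    ReversibleRateMatrix,
)


class ModelEstimationError(ValueError):
    pass


def discrete_gamma(alpha: float, ncat: int) -> GammaRates:
    """Mean-one discrete-gamma rates: ``ncat`` equal-probability categories,
    each the mean of its quantile interval of Gamma(alpha, 1/alpha)."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return GammaRates(alpha, 1, np.array([1.0]), np.array([1.0]))
    edges = _gamma.ppf(np.linspace(0.0, 1.0, ncat + 1), a=alpha, scale=1.0 / alpha)
    # E[X | bin] * P(bin) = F_{alpha+1}(b) - F_{alpha+1}(a) for a mean-one gamma
    upper = _gamma.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = (upper[1:] - upper[:-1]) * ncat
    rates = rates / np.mean(rates)  # exact mean-one after discretization
    weights = np.full(ncat, 1.0 / ncat)
    return GammaRates(float(alpha), int(ncat), rates, weights)


def _pair_counts(
    codes: np.ndarray, min_pair_identity: float, max_pair_identity: float
) -> np.ndarray:
    """Symmetrized 20x20 replacement counts pooled over sequence pairs whose
    pairwise identity (over mutually resolved sites) lies in the window."""
    n = codes.shape[0]
    counts = np.zeros((N_STATES, N_STATES))
    used = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a < MISSING_CODE) & (b < MISSING_CODE)
            m = int(ok.sum())
            if m == 0:
                continue
            ident = float((a[ok] == b[ok]).mean())
            if not (min_pair_identity <= ident <= max_pair_identity):
                continue
            pair = a[ok] * N_STATES + b[ok]
            counts += np.bincount(pair, minlength=N_STATES * N_STATES).reshape(
                N_STATES, N_STATES
            )
            used += 1
    if used == 0:
        raise ModelEstimationError(
            "no sequence pairs fall inside the identity window "
            f"[{min_pair_identity}, {max_pair_identity}]; widen the window"
        )
    return (counts + counts.T) / 2.0


def estimate_relative_rates(
    aln: MultipleAlignment,
    min_pair_identity: float = 0.2,
    max_pair_identity: float = 0.95,
) -> ReversibleRateMatrix:
    """Estimate a protein-specific reversible replacement matrix.

    Multiple hits are corrected by taking the matrix logarithm of the pooled
    conditional replacement-probability matrix; negative off-diagonal entries
    of the log (sampling noise) are clamped to zero and the result is
    symmetrized into exchangeabilities against the empirical frequencies.
    """
    codes = aln.encode()
    resolved = codes[codes < MISSING_CODE]
    if resolved.size == 0:
        raise ModelEstimationError("alignment contains no resolved residues")
    pi = np.bincount(resolved, minlength=N_STATES).astype(float) + 1.0
    pi /= pi.sum()

    counts = _pair_counts(codes, min_pair_identity, max_pair_identity)
    off = ~np.eye(N_STATES, dtype=bool)
    if counts[off].sum() == 0:
        raise ModelEstimationError("no substitutions observed")

    rowsum = counts.sum(axis=1)
    prob = np.eye(N_STATES)
    nz = rowsum > 0
    prob[nz] = counts[nz] / rowsum[nz, None]
    gen = np.real(logm(prob))
    gen[off & (gen < 0)] = 0.0
    np.fill_diagonal(gen, 0.0)
    np.fill_diagonal(gen, -gen.sum(axis=1))

    with np.errstate(divide="ignore", invalid="ignore"):
        s = gen / pi[None, :]
    s = (s + s.T) / 2.0
    s[~np.isfinite(s)] = 0.0
    s[s < 0] = 0.0
    np.fill_diagonal(s, 0.0)
    if s.max() == 0:
        raise ModelEstimationError("no substitutions observed")
    return ReversibleRateMatrix(s, pi)


#: grid searched when the gamma shape is not supplied
ALPHA_GRID = (0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0)


def estimate_gamma_shape(
    aln: MultipleAlignment,
    tree,
    matrix: ReversibleRateMatrix,
    ncat: int = 6,
    grid: tuple[float, ...] = ALPHA_GRID,
) -> float:
    """Pick the gamma shape maximizing the tree likelihood over a grid."""
    from .reconstruct import log_likelihood

    best_alpha, best_ll = None, -np.inf
    for alpha in grid:
        ll = log_likelihood(aln, tree, matrix, discrete_gamma(alpha, ncat))
        if ll > best_ll:
            best_alpha, best_ll = alpha, ll
    return float(best_alpha)
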