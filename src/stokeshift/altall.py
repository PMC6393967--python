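"""Sequestered 'AltAll*N' ancestral libraries.

At each reconstructed node, every site has a ranked list of *plausible*
states — those with posterior probability strictly above a threshold
(default 0.1), the maximum-posterior state always included.  The library
holds N sequences, N being the largest plausible-state count over sites;
sequence k carries at each site the state of rank min(k, n_s), so sequence 1
is the maximum-posterior ancestor and later sequences progressively swap in
lower-ranked alternatives, clamping at each site's last plausible state.

Example: with three plausible states at one site and four at another (single
states elsewhere), the library has exactly four sequences, the fourth
combining the third-ranked state at the first site with the fourth-ranked at
the second.
"""

from __future__ import annotations

import numpy as np

from .io import (
    AMINO_ACIDS,
    AncestralLibrary,
    AncestralProfile,
    _ALPHA_ORDER_OF_INDEX,
)


def plausible_states(
    profile: AncestralProfile, node: str, site: int, threshold: float = 0.1
) -> list[tuple[str, float]]:
    """Ranked (amino acid, posterior) pairs with posterior > threshold.

    Sorted by posterior descending; exact ties broken alphabetically.  The
    maximum-posterior state is always included, so the list is never empty.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    pp = profile[node][site]
    order = np.lexsort((_ALPHA_ORDER_OF_INDEX, -pp))
    ranked = [(AMINO_ACIDS[i], float(pp[i])) for i in order]
    out = [ranked[0]] + [(a, p) for a, p in ranked[1:] if p > threshold]
    return out


def generate_altall_library(
    profile: AncestralProfile, node: str, threshold: float = 0.1
) -> AncestralLibrary:
    """Build the AltAll*N library for one node (see module docstring)."""
    length = profile.length
    per_site = [
        [a for a, _ in plausible_states(profile, node, s, threshold)]
        for s in range(length)
    ]
    n_lib = max(len(states) for states in per_site)
    sequences = []
    for k in range(1, n_lib + 1):
        seq = "".join(states[min(k, len(states)) - 1] for states in per_site)
        sequences.append(seq)
    return AncestralLibrary(node=node, sequences=sequences, provenance="altall")


def generate_all_libraries(
    profile: AncestralProfile, threshold: float = 0.1
) -> dict[str, AncestralLibrary]:
    return {
        node: generate_altall_library(profile, node, threshold)
        for node in profile.nodes
    }
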