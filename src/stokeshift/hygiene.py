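"""Gap-based alignment cleaning.

Two sequential filters applied before phylogenetic analysis: first drop
alignment columns in which *more than* 80% of the sequences carry a gap,
then drop sequences that carry *more than* 75% gaps over the columns that
survived.  Both thresholds are strict inequalities; ``X`` counts as a
residue, not a gap.  The filters are idempotent.
"""

from __future__ import annotations

import numpy as np

from .io import MultipleAlignment


class HygieneError(ValueError):
    pass


def filter_gappy_sites(
    aln: MultipleAlignment, max_gap_fraction: float = 0.8
) -> tuple[MultipleAlignment, list[int]]:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the filtered alignment and the original indices (0-based) of the
    columns that were kept.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    gaps = aln.gap_matrix()
    frac = gaps.mean(axis=0)
    kept = np.flatnonzero(~(frac > max_gap_fraction))
    if kept.size == 0:
        raise HygieneError("empty alignment after site filter")
    return aln.subset_sites(kept.tolist()), kept.tolist()


def filter_gappy_sequences(
    aln: MultipleAlignment, max_gap_fraction: float = 0.75
) -> tuple[MultipleAlignment, list[str]]:
    """Remove sequences whose gap fraction exceeds ``max_gap_fraction``.

    Returns the filtered alignment and the ids that were removed.  Intended
    to run after :func:`filter_gappy_sites` (pipeline ordering).
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    gaps = aln.gap_matrix()
    frac = gaps.mean(axis=1)
    removed = [sid for sid, f in zip(aln.ids, frac) if f > max_gap_fraction]
    keep = [sid for sid in aln.ids if sid not in set(removed)]
    if len(keep) < 4:
        raise HygieneError(
            f"only {len(keep)} sequences remain after the gap filter; "
            "at least 4 are needed to build an informative tree"
        )
    return aln.subset_sequences(keep), removed


def clean_alignment(
    aln: MultipleAlignment,
    max_site_gap: float = 0.8,
    max_seq_gap: float = 0.75,
) -> tuple[MultipleAlignment, list[int], list[str]]:
    """Sites-then-sequences cleaning; returns (alignment, kept_sites, removed_ids)."""
    aln, kept_sites = filter_gappy_sites(aln, max_site_gap)
    aln, removed_ids = filter_gappy_sequences(aln, max_seq_gap)
    return aln, kept_sites, removed_ids
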