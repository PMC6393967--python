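"""Structural annotation of ancestral libraries and branch change scoring.

Each ancestral sequence gets four per-residue tracks — 2-state disorder,
3- and 8-state secondary structure, and 3-state surface burial — from a
pluggable predictor.  Two predictors ship here: a deterministic mock whose
classes are a hash of the residue and its ±2 sequence neighbours (so a point
substitution perturbs at most five positions per track), and an adapter that
serves annotations precomputed by any external per-residue predictor from a
TSV.  Branch scores are, per track, the mean over all parent×child sequence
pairs of the fraction of positions whose track symbol differs; classification
into percentile ranks/quartiles reuses the epistasis machinery.
"""

from __future__ import annotations

import csv
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    AncestralLibrary,
    PhyloTree,
    StructureAnnotation,
    TRACKS,
    TRACK_ALPHABETS,
)
from .epistasis import ScoringError, classify_branches

PredictorInterface = Callable[[str], StructureAnnotation]

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE["X"] = 20
_PAD = 21
_POWERS = np.array([23**k for k in range(5)], dtype=np.uint64)
_SALTS = {
    "disorder2": np.uint64(0x9E3779B97F4A7C15),
    "ss3": np.uint64(0xBF58476D1CE4E5B9),
    "ss8": np.uint64(0x94D049BB133111EB),
    "surface3": np.uint64(0xD6E8FEB86659FD93),
}


def _mix(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def mock_predictor(seq: str) -> StructureAnnotation:
    """Deterministic window-hash structural predictor (test stand-in).

    Every residue's class on every track is a fixed hash of the residue and
    its two neighbours on either side, so annotations are translation
    invariant and a single substitution changes at most five positions.
    """
    codes = np.array([_CODE[c] for c in seq], dtype=np.uint64)
    padded = np.full(len(seq) + 4, _PAD, dtype=np.uint64)
    padded[2:-2] = codes
    windows = np.lib.stride_tricks.sliding_window_view(padded, 5)
    base = (windows * _POWERS[None, :]).sum(axis=1)
    tracks = {}
    for name in TRACKS:
        alpha = TRACK_ALPHABETS[name]
        h = _mix(base ^ _SALTS[name])
        cls = (h % np.uint64(len(alpha))).astype(int)
        tracks[name] = "".join(alpha[i] for i in cls)
    return StructureAnnotation(**tracks)


class TsvPredictor:
    """Serve precomputed per-residue annotations from a TSV.

    Dialect: columns ``sequence_id  position  aa  ss3  ss8  disorder
    surface`` (1-based positions).  Sequences are matched by content, so the
    predictor is usable wherever the mock is.
    """

    def __init__(self, path):
        rows: dict[str, list[tuple[int, str, str, str, str, str]]] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for rec in reader:
                rows.setdefault(rec["sequence_id"], []).append(
                    (
                        int(rec["position"]),
                        rec["aa"],
                        rec["ss3"],
                        rec["ss8"],
                        rec["disorder"],
                        rec["surface"],
                    )
                )
        self._by_sequence: dict[str, StructureAnnotation] = {}
        for sid, recs in rows.items():
            recs.sort()
            seq = "".join(r[1] for r in recs)
            self._by_sequence[seq] = StructureAnnotation(
                disorder2="".join(r[4] for r in recs),
                ss3="".join(r[2] for r in recs),
                ss8="".join(r[3] for r in recs),
                surface3="".join(r[5] for r in recs),
            )

    def __call__(self, seq: str) -> StructureAnnotation:
        try:
            return self._by_sequence[seq]
        except KeyError:
            raise KeyError(
                "no precomputed annotation for sequence "
                f"'{seq[:20]}...' ({len(seq)} aa)"
            ) from None


def annotate_library(
    lib: AncestralLibrary,
    predictor: PredictorInterface,
    cache: dict[str, StructureAnnotation] | None = None,
) -> list[StructureAnnotation]:
    """One annotation per library sequence; identical sequences predicted
    once (pass a shared ``cache`` to extend memoization across libraries)."""
    if cache is None:
        cache = {}
    out = []
    for seq in lib.sequences:
        if seq not in cache:
            anno = predictor(seq)
            if anno.length != len(seq):
                raise ScoringError(
                    f"predictor returned length {anno.length} for a "
                    f"{len(seq)}-residue sequence of node '{lib.node}'"
                )
            cache[seq] = anno
        out.append(cache[seq])
    return out


def change_frequency(
    parent_annos: Sequence[StructureAnnotation],
    child_annos: Sequence[StructureAnnotation],
    track: str,
) -> float:
    """Mean, over all parent×child pairs, of the per-pair fraction of
    positions whose ``track`` symbol differs."""
    if track not in TRACKS:
        raise ValueError(f"unknown track {track!r}")
    if not parent_annos or not child_annos:
        raise ScoringError("annotation lists must be non-empty")
    alpha = TRACK_ALPHABETS[track]
    sym = {c: i for i, c in enumerate(alpha)}

    def counts(annos: Sequence[StructureAnnotation]) -> np.ndarray:
        L = annos[0].length
        arr = np.zeros((L, len(alpha)))
        for a in annos:
            if a.length != L:
                raise ScoringError("annotation length mismatch")
            idx = np.fromiter((sym[c] for c in a.track(track)), dtype=int, count=L)
            arr[np.arange(L), idx] += 1
        return arr

    p = counts(parent_annos)
    c = counts(child_annos)
    if p.shape[0] != c.shape[0]:
        raise ScoringError("annotation length mismatch between libraries")
    np_, nc = len(parent_annos), len(child_annos)
    # mean pairwise mismatch at a position = 1 - sum_sym f_parent * f_child
    agree = (p / np_ * (c / nc)).sum(axis=1)
    return float(np.mean(1.0 - agree))


def score_tree_structure(
    libraries: Mapping[str, AncestralLibrary],
    tree: PhyloTree,
    predictor: PredictorInterface = mock_predictor,
    pairing: str = "cross",
) -> dict[str, dict[tuple[str, str], float]]:
    """Change frequencies for every inner–inner branch, per track.

    ``pairing='cross'`` averages over all parent×child library pairs;
    ``pairing='map'`` compares only the two first (maximum-posterior)
    sequences.
    """
    if pairing not in ("cross", "map"):
        raise ValueError("pairing must be 'cross' or 'map'")
    cache: dict[str, StructureAnnotation] = {}
    annos = {
        node: annotate_library(lib, predictor, cache)
        for node, lib in libraries.items()
    }
    freqs: dict[str, dict[tuple[str, str], float]] = {t: {} for t in TRACKS}
    for parent, child in tree.inner_branches():
        if parent not in annos or child not in annos:
            continue
        pa, ca = annos[parent], annos[child]
        if pairing == "map":
            pa, ca = pa[:1], ca[:1]
        for t in TRACKS:
            freqs[t][(parent, child)] = change_frequency(pa, ca, t)
    return freqs


def classify_structural_branches(
    freqs: Mapping[str, Mapping[tuple[str, str], float]],
    flag_percentile: float = 95.0,
) -> dict[str, pd.DataFrame]:
    """Independent percentile/quartile classification per structural track."""
    return {
        track: classify_branches(dict(track_freqs), flag_percentile)
        for track, track_freqs in freqs.items()
    }
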