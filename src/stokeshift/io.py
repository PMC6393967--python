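"""Core domain types and file I/O.

Containers for the objects the pipeline passes between stages — protein
alignments, rooted trees, reversible amino-acid rate matrices, discrete-gamma
rate categories, per-node posterior profiles, ancestral libraries, per-residue
structural annotations and per-branch score tables — plus readers/writers for
the plain-text formats that carry them (FASTA, Newick, PAML-style ``.dat``
rate-matrix files, TSV).

Amino acids are indexed throughout in the PAML order
``ARNDCQEGHILKMFPSTWYV``; ``-`` is a gap and ``X`` an unknown residue (both
treated as missing data by the likelihood machinery, but only ``-`` counts as
a gap for alignment-hygiene purposes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"
N_STATES = 20
#: integer code used for gap/unknown residues in encoded alignments
MISSING_CODE = 20

#: alphabetical rank of each amino-acid index, used as a deterministic
#: tie-break when posterior probabilities are exactly equal
_ALPHA_ORDER_OF_INDEX = np.array(
    [sorted(AMINO_ACIDS).index(aa) for aa in AMINO_ACIDS], dtype=int
)


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged rows, illegal characters...)."""


class TreeFormatError(ValueError):
    """Malformed or unsupported Newick input."""


class RateMatrixError(ValueError):
    """Malformed or invalid rate-matrix specification."""


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    """An aligned set of protein sequences (rows may contain gaps)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in count")
        if not self.rows:
            raise AlignmentFormatError("alignment has no sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise AlignmentFormatError(f"duplicate sequence ids: {sorted(dupes)}")
        length = len(self.rows[0])
        if length == 0:
            raise AlignmentFormatError("alignment has zero length")
        allowed = set(AMINO_ACIDS + GAP + UNKNOWN)
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentFormatError(
                    f"sequence '{sid}' has length {len(row)}, expected {length}"
                )
            for pos, ch in enumerate(row):
                if ch not in allowed:
                    raise AlignmentFormatError(
                        f"illegal character {ch!r} in sequence '{sid}' at position {pos + 1}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def encode(self) -> np.ndarray:
        """Integer codes, shape (n_sequences, length); gap/X -> MISSING_CODE."""
        table = np.full(128, -1, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            table[ord(aa)] = i
        table[ord(GAP)] = MISSING_CODE
        table[ord(UNKNOWN)] = MISSING_CODE
        raw = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return table[raw].reshape(self.n_sequences, self.length).astype(np.int64)

    def gap_matrix(self) -> np.ndarray:
        """Boolean (n_sequences, length): True where the residue is a gap.

        ``X`` counts as a residue here, not a gap.
        """
        raw = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return (raw == ord(GAP)).reshape(self.n_sequences, self.length)

    def subset_sites(self, site_indices: Sequence[int]) -> "MultipleAlignment":
        idx = list(site_indices)
        rows = ["".join(row[i] for i in idx) for row in self.rows]
        return MultipleAlignment(list(self.ids), rows)

    def subset_sequences(self, keep_ids: Iterable[str]) -> "MultipleAlignment":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        return MultipleAlignment([p[0] for p in pairs], [p[1] for p in pairs])


def read_alignment(path) -> MultipleAlignment:
    """Read a FASTA alignment, validating shape and alphabet."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentFormatError(f"no FASTA records found in {path}")
    return MultipleAlignment(ids, rows)


def write_alignment(aln: MultipleAlignment, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted tree with branch lengths, stored in post-order arrays.

    Nodes are indexed 0..n-1 in post-order (children before parents; the root
    is the last index).  Unlabeled inner nodes receive deterministic names
    ``N<post-order index>`` so that branch identifiers are stable across runs;
    labeled inner nodes keep their labels.  Polytomies are allowed.
    """

    def __init__(
        self,
        names: list[str],
        parent: np.ndarray,
        branch_lengths: np.ndarray,
        children: list[list[int]],
    ) -> None:
        self.names = names
        self.parent = parent
        self.branch_lengths = branch_lengths
        self.children = children
        self.n_nodes = len(names)
        self.root = self.n_nodes - 1
        self.is_leaf = np.array([len(c) == 0 for c in children])
        if len(set(names)) != len(names):
            raise TreeFormatError("duplicate node names in tree")
        self.index = {n: i for i, n in enumerate(names)}
        if np.any(branch_lengths[: self.root] < 0):
            raise TreeFormatError("negative branch length")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        order = list(dtree.postorder_node_iter())
        idx_of = {id(nd): i for i, nd in enumerate(order)}
        names: list[str] = []
        parent = np.full(len(order), -1, dtype=int)
        blen = np.zeros(len(order))
        children: list[list[int]] = [[] for _ in order]
        for i, nd in enumerate(order):
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if not label:
                    raise TreeFormatError("leaf without a label")
            else:
                label = nd.label if nd.label else f"N{i}"
            names.append(label)
            if nd.edge.length is not None:
                if nd.edge.length < 0:
                    raise TreeFormatError(
                        f"negative branch length {nd.edge.length} at node '{label}'"
                    )
                blen[i] = float(nd.edge.length)
            for ch in nd.child_nodes():
                j = idx_of[id(ch)]
                parent[j] = i
                children[i].append(j)
        return cls(names, parent, blen, children)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeFormatError(f"unparseable Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    # -- queries ------------------------------------------------------------

    def leaf_names(self) -> list[str]:
        return [n for n, lf in zip(self.names, self.is_leaf) if lf]

    def inner_names(self) -> list[str]:
        return [n for n, lf in zip(self.names, self.is_leaf) if not lf]

    def branches(self) -> list[tuple[str, str]]:
        """(parent_name, child_name) for every non-root node, post-order."""
        return [
            (self.names[self.parent[i]], self.names[i])
            for i in range(self.n_nodes)
            if self.parent[i] >= 0
        ]

    def inner_branches(self) -> list[tuple[str, str]]:
        """Branches whose child is an inner node (root excluded as child)."""
        return [
            (self.names[self.parent[i]], self.names[i])
            for i in range(self.n_nodes)
            if self.parent[i] >= 0 and not self.is_leaf[i]
        ]

    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        depth = np.zeros(self.n_nodes)
        for i in self.preorder():
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.branch_lengths[i]
        return float(depth[self.is_leaf].max())

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    # -- serialization ------------------------------------------------------

    def _subtree_newick(self, i: int, comments: dict[str, str] | None) -> str:
        name = self.names[i]
        com = f"[&{comments[name]}]" if comments and name in comments else ""
        if self.is_leaf[i]:
            core = name
        else:
            inner = ",".join(
                self._subtree_newick(c, comments) for c in self.children[i]
            )
            core = f"({inner}){name}"
        if i == self.root:
            return core + com
        return f"{core}:{float(self.branch_lengths[i])!r}{com}"

    def to_newick(self, comments: dict[str, str] | None = None) -> str:
        """Serialize with internal labels (and optional ``[&...]`` branch
        comments keyed by child-node name)."""
        return self._subtree_newick(self.root, comments) + ";"


def read_tree(path) -> PhyloTree:
    with open(path) as fh:
        text = fh.read()
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def prune_tree(tree: PhyloTree, keep_leaf_names: Iterable[str]) -> PhyloTree:
    """Restrict a tree to a subset of leaves (suppressing unifurcations)."""
    keep = set(keep_leaf_names)
    dtree = dendropy.Tree.get(
        data=tree.to_newick(),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    taxa = [t for t in dtree.taxon_namespace if t.label in keep]
    if len(taxa) < len(keep):
        missing = keep - {t.label for t in taxa}
        raise TreeFormatError(f"leaves not in tree: {sorted(missing)}")
    dtree.retain_taxa(taxa)
    return PhyloTree.from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Reversible rate matrix
# ---------------------------------------------------------------------------

class ReversibleRateMatrix:
    """A general time-reversible amino-acid replacement model.

    Built from symmetric exchangeabilities ``s_ab`` and equilibrium
    frequencies ``pi``; the generator ``q_ab = pi_b * s_ab`` (off-diagonal)
    is rescaled so the expected substitution rate at equilibrium is one,
    i.e. ``-sum_a pi_a q_aa = 1``.  Detailed balance ``pi_a q_ab = pi_b q_ba``
    holds by construction.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray):
        s = np.asarray(exchangeabilities, dtype=float).copy()
        pi = np.asarray(frequencies, dtype=float).copy()
        if s.shape != (N_STATES, N_STATES):
            raise RateMatrixError("exchangeabilities must be 20x20")
        if pi.shape != (N_STATES,):
            raise RateMatrixError("frequencies must have 20 entries")
        if np.any(s < 0) or np.any(pi < 0):
            raise RateMatrixError("negative entries in rate-matrix inputs")
        if abs(pi.sum() - 1.0) > 1e-3:
            raise RateMatrixError(
                f"frequencies sum to {pi.sum():.6f}, expected 1 within 1e-3"
            )
        pi = pi / pi.sum()
        if not np.allclose(s, s.T, rtol=0, atol=1e-12 * max(1.0, s.max())):
            raise RateMatrixError("exchangeabilities must be symmetric")
        np.fill_diagonal(s, 0.0)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(q)))
        if mu <= 0:
            raise RateMatrixError("no substitutions possible (zero rate matrix)")
        self.exchangeabilities = s / mu
        self.frequencies = pi
        self.q = q / mu

    # -- convenience --------------------------------------------------------

    def detailed_balance_error(self) -> float:
        flux = self.frequencies[:, None] * self.q
        off = ~np.eye(N_STATES, dtype=bool)
        return float(np.max(np.abs(flux - flux.T)[off]))

    def expected_rate(self) -> float:
        return -float(np.sum(self.frequencies * np.diag(self.q)))

    def lower_triangle(self) -> np.ndarray:
        """The 190 exchangeabilities, PAML lower-triangular order."""
        iu = np.tril_indices(N_STATES, k=-1)
        return self.exchangeabilities[iu]

    @classmethod
    def from_lower_triangle(
        cls, tri: np.ndarray, frequencies: np.ndarray
    ) -> "ReversibleRateMatrix":
        tri = np.asarray(tri, dtype=float)
        if tri.shape != (190,):
            raise RateMatrixError(f"expected 190 exchangeabilities, got {tri.size}")
        s = np.zeros((N_STATES, N_STATES))
        iu = np.tril_indices(N_STATES, k=-1)
        s[iu] = tri
        s = s + s.T
        return cls(s, frequencies)

    @classmethod
    def jtt(cls) -> "ReversibleRateMatrix":
        """The Jones–Taylor–Thornton (1992) replacement model."""
        tri = np.array([float(t) for t in _JTT_LOWER.split()])
        pi = np.array([float(t) for t in _JTT_FREQS.split()])
        return cls.from_lower_triangle(tri, pi)


# JTT exchangeabilities (lower triangle, ARNDCQEGHILKMFPSTWYV order) and
# equilibrium frequencies, as distributed with PAML (jones.dat).
_JTT_LOWER = """
58 54 81 56 57 105 179 27 36 30 35 54 15 194 378 475 9 11 298 45 16 113 310 29
137 328 22 38 646 44 5 74 101 64 126 20 17 528 34 86 58 81 391 47 12 263 30 10
15 503 232 8 70 16 10 49 767 130 112 11 7 26 15 4 15 59 38 4 46 31 9 5 59 69
17 23 7 31 78 14 223 42 115 209 62 323 26 597 9 72 292 43 4 164 53 51 18 24 20
119 26 12 9 181 18 5 18 30 32 10 7 45 23 6 6 27 14 5 24 201 33 55 8 47 16 56
45 33 40 115 73 46 8 573 11 229 21 479 89 10 40 245 9 32 961 14 388 248 102 59
25 52 24 180 65 4 21 47 103 10 8 14 43 16 29 226 24 18 323 17 92 12 53 536 62
285 118 6 10 23 477 35 63 38 12 21 112 71 25 16
"""
_JTT_FREQS = """
0.076748 0.051691 0.042645 0.051544 0.019803 0.040752 0.061830 0.073152
0.022944 0.053761 0.091904 0.058676 0.023826 0.040126 0.050901 0.068765
0.058565 0.014261 0.032102 0.066005
"""


def read_rate_matrix(path) -> ReversibleRateMatrix:
    """Parse a PAML-style ``.dat``: 190 lower-triangular exchangeabilities
    followed by 20 equilibrium frequencies (whitespace separated; ``#``
    comment lines ignored; trailing text after the 210 numbers ignored)."""
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                continue
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    if len(values) < 210:
                        raise RateMatrixError(
                            f"non-numeric token {tok!r} before 210 values were read"
                        ) from None
                    break
            if len(values) >= 210:
                break
    if len(values) < 210:
        raise RateMatrixError(
            f"rate-matrix file holds {len(values)} numbers; need 190 + 20"
        )
    tri = np.array(values[:190])
    pi = np.array(values[190:210])
    return ReversibleRateMatrix.from_lower_triangle(tri, pi)


def write_rate_matrix(matrix: ReversibleRateMatrix, path) -> None:
    tri = matrix.lower_triangle()
    with open(path, "w") as fh:
        pos = 0
        for row in range(1, N_STATES):
            vals = tri[pos : pos + row]
            pos += row
            fh.write(" ".join(f"{v:.8g}" for v in vals) + "\n")
        fh.write("\n")
        fh.write(" ".join(f"{f:.8g}" for f in matrix.frequencies) + "\n")


# ---------------------------------------------------------------------------
# Discrete-gamma rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaRates:
    """Discrete-gamma among-site rate variation (mean-one, equal weights)."""

    alpha: float
    ncat: int
    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")
        if abs(float(self.weights @ self.rates) - 1.0) > 1e-9:
            raise ValueError("gamma rates are not mean-one")

    @classmethod
    def constant(cls) -> "GammaRates":
        """A single rate class (no rate heterogeneity)."""
        return cls(float("inf"), 1, np.array([1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# Ancestral profiles and libraries
# ---------------------------------------------------------------------------

class AncestralProfile:
    """Per-node, per-site posterior distributions over the 20 amino acids."""

    def __init__(self, profiles: Mapping[str, np.ndarray]):
        self.profiles: dict[str, np.ndarray] = {}
        length = None
        for node, arr in profiles.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != N_STATES:
                raise ValueError(f"profile for '{node}' must be (n_sites, 20)")
            if length is None:
                length = arr.shape[0]
            elif arr.shape[0] != length:
                raise ValueError("profiles differ in site count")
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"posterior entries outside [0,1] for '{node}'")
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-9:
                raise ValueError(f"posteriors for '{node}' do not sum to 1")
            self.profiles[node] = np.clip(arr, 0.0, 1.0)
        if length is None:
            raise ValueError("empty profile set")
        self.length = length

    @property
    def nodes(self) -> list[str]:
        return list(self.profiles)

    def __getitem__(self, node: str) -> np.ndarray:
        return self.profiles[node]

    def __contains__(self, node: str) -> bool:
        return node in self.profiles

    def map_sequence(self, node: str) -> str:
        """Per-site maximum-posterior sequence (ties broken alphabetically)."""
        pp = self.profiles[node]
        # subtract an infinitesimal alphabetical penalty so exact ties pick
        # the alphabetically first amino acid
        keyed = pp - 1e-15 * _ALPHA_ORDER_OF_INDEX[None, :]
        idx = np.argmax(keyed, axis=1)
        return "".join(AMINO_ACIDS[i] for i in idx)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node, arr in self.profiles.items():
            df = pd.DataFrame(arr, columns=list(AMINO_ACIDS))
            df.insert(0, "site", np.arange(1, arr.shape[0] + 1))
            df.insert(0, "node", node)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class AncestralLibrary:
    """An ordered set of alternative ancestral sequences at one node."""

    node: str
    sequences: list[str]
    provenance: str  # "altall" | "sampled"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("ancestral library must be non-empty")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("library sequences differ in length")
        if self.provenance not in ("altall", "sampled"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sequences)


def write_library(lib: AncestralLibrary, path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{lib.node}.{lib.provenance}.{k + 1}", description="")
        for k, s in enumerate(lib.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Structural annotations
# ---------------------------------------------------------------------------

#: track name -> symbol alphabet
TRACK_ALPHABETS = {
    "disorder2": "OD",          # ordered / disordered
    "ss3": "CHE",               # coil / helix / strand
    "ss8": "CHGIEBTS",          # DSSP 8-state
    "surface3": "BIE",          # buried / intermediate / exposed
}
TRACKS = tuple(TRACK_ALPHABETS)


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-residue structural tracks for one (gap-free) protein sequence."""

    disorder2: str
    ss3: str
    ss8: str
    surface3: str

    def __post_init__(self) -> None:
        L = len(self.disorder2)
        for track in TRACKS:
            val = getattr(self, track)
            if len(val) != L:
                raise ValueError(f"track '{track}' length {len(val)} != {L}")
            bad = set(val) - set(TRACK_ALPHABETS[track])
            if bad:
                raise ValueError(f"track '{track}' has illegal symbols {bad}")

    @property
    def length(self) -> int:
        return len(self.disorder2)

    def track(self, name: str) -> str:
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Branch score table
# ---------------------------------------------------------------------------

METRICS = ("disorder2", "ss3", "ss8", "surface3", "epistasis")


class BranchScoreTable:
    """Per-branch metric values with percentile ranks, quartiles and flags.

    Thin wrapper over a DataFrame keyed by (parent, child); metric columns
    are the four structural change frequencies plus the epistasis log-sum,
    each accompanied by ``percentile_*``, ``quartile_*`` and ``flag_*``
    columns.  Metrics not computed for a branch are NaN/empty.
    """

    def __init__(self, df: pd.DataFrame):
        if not {"parent", "child"}.issubset(df.columns):
            raise ValueError("branch table needs 'parent' and 'child' columns")
        qcols = [c for c in df.columns if c.startswith("quartile_")]
        for c in qcols:
            bad = set(df[c].dropna()) - {"Q1", "Q2", "Q3", "Q4"}
            if bad:
                raise ValueError(f"illegal quartile labels in {c}: {bad}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def empty(cls) -> "BranchScoreTable":
        cols = ["parent", "child"]
        for m in METRICS:
            cols += [m, f"percentile_{m}", f"quartile_{m}", f"flag_{m}"]
        return cls(pd.DataFrame(columns=cols))

    def __len__(self) -> int:
        return len(self.df)


def write_branch_scores(table: BranchScoreTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_branch_scores(path) -> BranchScoreTable:
    df = pd.read_csv(path, sep="\t")
    for c in df.columns:
        if c.startswith("flag_"):
            df[c] = df[c].astype("boolean")
    return BranchScoreTable(df)


_COMMENT_RE = re.compile(r"&(.*)")


def write_annotated_tree(tree: PhyloTree, table: BranchScoreTable, path) -> None:
    """Write Newick with per-branch ``[&key=value,...]`` comments carrying
    every metric/percentile/quartile/flag column of the score table."""
    comments: dict[str, str] = {}
    datacols = [c for c in table.df.columns if c not in ("parent", "child")]
    for _, row in table.df.iterrows():
        parts = []
        for c in datacols:
            v = row[c]
            if isinstance(v, float) and np.isnan(v):
                continue
            if pd.isna(v):
                continue
            if isinstance(v, (bool, np.bool_)):
                v = int(v)
            elif isinstance(v, float):
                v = repr(v)
            parts.append(f"{c}={v}")
        if parts:
            comments[row["child"]] = ",".join(parts)
    with open(path, "w") as fh:
        fh.write(tree.to_newick(comments) + "\n")


def read_annotated_tree(path) -> tuple[PhyloTree, BranchScoreTable]:
    """Inverse of :func:`write_annotated_tree`."""
    with open(path) as fh:
        text = fh.read()
    stripped = re.sub(r"\[&[^\]]*\]", "", text)
    tree = PhyloTree.from_newick(stripped)
    # associate each comment with the node name preceding it
    rows = []
    for match in re.finditer(r"([A-Za-z0-9_.|-]+)(?::[0-9eE+.-]+)?\[&([^\]]*)\]", text):
        child, body = match.group(1), match.group(2)
        rec: dict[str, object] = {"child": child}
        pidx = tree.parent[tree.index[child]]
        rec["parent"] = tree.names[pidx] if pidx >= 0 else ""
        for kv in body.split(","):
            key, val = kv.split("=", 1)
            if key.startswith("flag_"):
                rec[key] = bool(int(val))
            elif key.startswith("quartile_"):
                rec[key] = val
            else:
                rec[key] = float(val)
        rows.append(rec)
    df = pd.DataFrame(rows)
    if not df.empty:
        lead = ["parent", "child"]
        df = df[lead + [c for c in df.columns if c not in lead]]
    return tree, BranchScoreTable(df)
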