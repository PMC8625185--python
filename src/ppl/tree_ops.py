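"""Tree-derived quantities: cophenetic and character distances, neighbor
joining, and Fitch/Hartigan parsimony scoring.

Trees are :class:`dendropy.Tree` objects throughout.  Distance matrices
are small labelled containers (`DistanceMatrix`) with NaN marking
entries flagged as missing (e.g. insufficient character overlap).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GAP, MISSING, Alignment, BinaryCharacterMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix; NaN flags missing entries."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-9:
            raise ValueError(f"matrix asymmetric by {asym}")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        present = ~np.isnan(self.values)
        if (self.values[present] < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def reorder(self, labels) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise ValueError("reorder requires the same label set")
        return self.submatrix(labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major — the shared pair order for tests."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls([str(l) for l in df.index], df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "DistanceMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))


# ---------------------------------------------------------------------------
# Cophenetic distances


def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (cophenetic) distances between all tip pairs.

    Labels are returned in sorted order regardless of tree layout.
    """
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node is not tree.seed_node:
            raise ValueError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    tips = sorted((leaf.taxon for leaf in tree.leaf_node_iter()),
                  key=lambda t: t.label)
    labels = [t.label for t in tips]
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(tips[i], tips[j])
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Character distances


def _encode_matrix(matrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (taxa, integer codes, valid mask); gaps/missing invalid."""
    if isinstance(matrix, Alignment):
        valid = ~matrix.missing_mask(count_gaps=True)
        codes = matrix.sites.view(np.uint32).reshape(matrix.sites.shape)
        return list(matrix.taxa), codes.astype(np.int64), valid
    if isinstance(matrix, BinaryCharacterMatrix):
        valid = ~np.isnan(matrix.states)
        codes = np.where(valid, matrix.states, -1).astype(np.int64)
        return list(matrix.taxa), codes, valid
    if isinstance(matrix, pd.DataFrame):
        vals = matrix.to_numpy(dtype=float)
        valid = ~np.isnan(vals)
        codes = np.where(valid, vals, -1).astype(np.int64)
        return [str(t) for t in matrix.index], codes, valid
    raise TypeError(f"unsupported matrix type {type(matrix).__name__}")


def character_distance_matrix(matrix, min_overlap: int = 1) -> DistanceMatrix:
    """Pairwise mismatch proportion over mutually non-missing characters.

    ``d(i, j)`` is the number of differing states divided by the number of
    columns where both taxa are scored; pairs with fewer than
    ``min_overlap`` comparable columns are flagged missing (NaN).
    """
    taxa, codes, valid = _encode_matrix(matrix)
    zero = np.flatnonzero(valid.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(
            f"taxon {taxa[int(zero[0])]!r} has no non-missing states"
        )
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        mism = (codes[i] != codes[i + 1:]) & both
        overlap = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(overlap >= max(min_overlap, 1),
                         mism.sum(axis=1) / np.maximum(overlap, 1), np.nan)
        d = np.where(overlap == 0, np.nan, d)
        values[i, i + 1:] = d
        values[i + 1:, i] = d
    return DistanceMatrix(taxa, values)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion pick the lexicographically smallest label
    pair (labels of internal nodes are the smallest tip label they
    contain).  Negative branch lengths are clamped to zero with the
    deficit transferred to the sister edge.  On additive input the
    generating topology and branch lengths are recovered exactly.
    """
    if not dm.is_complete():
        raise ValueError("neighbor joining requires a complete distance matrix")
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxon_namespace = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(label))
        nodes[label] = node

    D = {
        (a, b): float(dm.values[i, j])
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
        if i < j
    }

    def dist(a: str, b: str) -> float:
        return D[(a, b)] if (a, b) in D else D[(b, a)]

    def set_dist(a: str, b: str, v: float) -> None:
        D[(min(a, b), max(a, b))] = v

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
            logger.info("negative NJ branch clamped; deficit moved to sister")
        if lb < 0:
            la += lb
            lb = 0.0
            logger.info("negative NJ branch clamped; deficit moved to sister")
        return la, max(lb, 0.0)

    active = sorted(dm.labels)
    while len(active) > 3:
        r = len(active)
        R = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * dist(a, b) - R[a] - R[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        d_ab = dist(a, b)
        la = 0.5 * d_ab + (R[a] - R[b]) / (2 * (r - 2))
        lb = d_ab - la
        la, lb = clamp(la, lb)
        parent = dendropy.Node()
        child_a, child_b = sorted([(a, la), (b, lb)])
        for label, length in (child_a, child_b):
            nodes[label].edge.length = length
            parent.add_child(nodes[label])
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            set_dist(new_label, c, 0.5 * (dist(a, c) + dist(b, c) - d_ab))
        active = sorted(set(active) - {a, b} | {new_label})
        nodes[new_label] = parent

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    root = dendropy.Node()
    for label, length in ((a, la), (b, lb), (c, lc)):
        nodes[label].edge.length = max(length, 0.0)
        if length < 0:
            logger.info("negative terminal NJ branch clamped to 0")
        root.add_child(nodes[label])
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# Fitch / Hartigan parsimony scoring


def fitch_score(tree: dendropy.Tree, matrix: BinaryCharacterMatrix) -> int:
    """Small-parsimony length of a character matrix on a fixed tree.

    Uses Hartigan's generalization of the Fitch pass, which is exact on
    multifurcating trees: at each internal node the states attaining the
    maximum child-set count are kept and ``(n_children - max_count)``
    changes are added.  Missing states are uninformative (full state
    set).  The score is invariant under re-rooting.
    """
    tip_index = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing_taxa = [t for t in matrix.taxa if t not in tip_index]
    if missing_taxa:
        raise ValueError(f"matrix taxa absent from tree: {missing_taxa}")
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    full = frozenset((0.0, 1.0))
    total = 0
    for j in range(matrix.n_characters):
        observed = {
            v for v in matrix.states[:, j] if not np.isnan(v)
        }
        if len(observed) <= 1:
            continue
        changes = 0
        sets: dict[int, frozenset] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                if label in row_of:
                    v = matrix.states[row_of[label], j]
                    sets[id(node)] = full if np.isnan(v) else frozenset((v,))
                else:
                    sets[id(node)] = full
            else:
                children = [sets[id(c)] for c in node.child_nodes()]
                counts = {s: sum(s in cs for cs in children) for s in full}
                best = max(counts.values())
                sets[id(node)] = frozenset(s for s, c in counts.items() if c == best)
                changes += len(children) - best
        total += changes
    return total


# ---------------------------------------------------------------------------
# Small helpers used by several analyses


def tree_from_taxa(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Pruned copy of the tree keeping only the given tips."""
    keep = set(labels)
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(sorted(keep))
    return sub
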