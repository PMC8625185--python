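"""Placement of unsampled taxa and machine-derived identification keys.

Two tools for putting names on taxa:

* **k-NN placement** — a query taxon scored for (some of) the same
  characters as a labelled reference matrix is assigned the majority
  label of its k nearest references under the mismatch-proportion
  distance, with a character-bootstrap confidence (proportion of
  resampled-character replicates reproducing the full-data label).
* **Recursive partitioning** — greedy CART-style binary splits on
  morphological characters minimizing Gini impurity, rendered as a
  numbered dichotomous key.  Repeated runs exclude previously used
  characters to surface additional diagnostic characters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BinaryCharacterMatrix

logger = logging.getLogger(__name__)

HIGH_CONFIDENCE = 0.90


# ---------------------------------------------------------------------------
# Character-space helpers


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, BinaryCharacterMatrix):
        return matrix.to_dataframe()
    return pd.DataFrame(matrix).astype(float)


def _mismatch_distances(q_vals, q_valid, r_vals, r_valid, weights=None):
    """Distances of one query row to all reference rows.

    Mismatch proportion over characters scored in both rows, optionally
    with per-character multiplicities (bootstrap weights).  Returns NaN
    where there is no overlap.
    """
    both = q_valid & r_valid
    mism = (q_vals != r_vals) & both
    if weights is None:
        overlap = both.sum(axis=1)
        mcount = mism.sum(axis=1)
    else:
        overlap = both @ weights
        mcount = mism @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(overlap > 0, mcount / np.maximum(overlap, 1e-300), np.nan)
    return d


# ---------------------------------------------------------------------------
# k-NN placement


@dataclass
class PlacementResult:
    """Per-query predicted labels, bootstrap confidence and neighbors.

    ``table`` is indexed by query taxon with columns ``predicted_label``,
    ``confidence`` (NaN until a bootstrap is run) and ``high_confidence``
    (confidence > 0.90).  ``neighbors`` maps each query to its k nearest
    reference taxa with distances, nearest first.
    """

    table: pd.DataFrame
    neighbors: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    k: int = 5


def _majority_label(labels, distances):
    """Majority vote; ties by summed inverse distance, then alphabetical."""
    counts = Counter(labels)
    top = max(counts.values())
    tied = sorted(l for l, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    inv = {}
    for lab in tied:
        ds = [d for l, d in zip(labels, distances) if l == lab]
        inv[lab] = sum(np.inf if d == 0 else 1.0 / d for d in ds)
    best = max(inv.values())
    return sorted(l for l in tied if inv[l] == best)[0]


def _predict_one(dist_row, ref_taxa, ref_labels, k):
    order = np.lexsort((np.array(ref_taxa), dist_row))
    order = [i for i in order if not np.isnan(dist_row[i])][:k]
    labels = [ref_labels[i] for i in order]
    dists = [float(dist_row[i]) for i in order]
    return _majority_label(labels, dists), [(ref_taxa[i], float(dist_row[i]))
                                            for i in order]


def knn_place(reference, labels, queries, k: int = 5) -> PlacementResult:
    """Assign each query taxon the majority label of its k nearest
    labelled references.

    ``reference`` and ``queries`` share a character space (missing
    states allowed); the distance is the mismatch proportion over
    mutually scored characters.  A query overlapping no reference taxon
    is an error naming it.
    """
    ref = _as_frame(reference)
    qry = _as_frame(queries)
    qry = qry.reindex(columns=ref.columns)
    lab = pd.Series(labels).reindex(ref.index)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])
        raise ValueError(f"reference taxa without labels: {missing}")
    if k < 1 or k > len(ref):
        raise ValueError(f"k must be in [1, {len(ref)}]")

    r_vals = ref.to_numpy(dtype=float)
    r_valid = ~np.isnan(r_vals)
    ref_taxa = [str(t) for t in ref.index]
    ref_labels = [str(l) for l in lab]

    rows = {}
    neighbors = {}
    for taxon, row in zip(qry.index, qry.to_numpy(dtype=float)):
        q_valid = ~np.isnan(row)
        d = _mismatch_distances(row, q_valid, r_vals, r_valid)
        if np.isnan(d).all():
            raise ValueError(
                f"query {taxon!r} shares no scored characters with any "
                f"reference taxon"
            )
        pred, nbrs = _predict_one(d, ref_taxa, ref_labels, k)
        rows[str(taxon)] = pred
        neighbors[str(taxon)] = nbrs
    table = pd.DataFrame({
        "predicted_label": pd.Series(rows),
        "confidence": np.nan,
        "high_confidence": False,
    })
    return PlacementResult(table=table, neighbors=neighbors, k=k)


def placement_confidence(
    reference, labels, queries, k: int = 5, n_bootstrap: int = 1000,
    seed: int = 0,
) -> PlacementResult:
    """k-NN placement with character-bootstrap confidence.

    Characters (columns) are resampled with replacement ``n_bootstrap``
    times; a query's confidence is the proportion of replicates whose
    k-NN prediction matches the full-data prediction.  Placements with
    confidence above 0.90 are flagged high-confidence.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    result = knn_place(reference, labels, queries, k=k)
    ref = _as_frame(reference)
    qry = _as_frame(queries).reindex(columns=ref.columns)
    lab = pd.Series(labels).reindex(ref.index)
    r_vals = ref.to_numpy(dtype=float)
    r_valid = ~np.isnan(r_vals)
    ref_taxa = [str(t) for t in ref.index]
    ref_labels = [str(l) for l in lab]
    n_chars = r_vals.shape[1]
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(n_chars, np.full(n_chars, 1.0 / n_chars),
                              size=n_bootstrap).T.astype(float)

    confidences = {}
    for taxon, row in zip(qry.index, qry.to_numpy(dtype=float)):
        q_valid = ~np.isnan(row)
        both = q_valid & r_valid
        mism = ((row != r_vals) & both).astype(float)
        overlap_w = both.astype(float) @ weights  # (n_ref, n_bootstrap)
        mism_w = mism @ weights
        with np.errstate(invalid="ignore", divide="ignore"):
            dists = np.where(overlap_w > 0, mism_w / np.maximum(overlap_w, 1e-300),
                             np.nan)
        full_pred = result.table.loc[str(taxon), "predicted_label"]
        hits = 0
        for b in range(n_bootstrap):
            d = dists[:, b]
            if np.isnan(d).all():
                continue
            pred, _ = _predict_one(d, ref_taxa, ref_labels, k)
            if pred == full_pred:
                hits += 1
        confidences[str(taxon)] = hits / n_bootstrap
    result.table["confidence"] = pd.Series(confidences)
    result.table["high_confidence"] = result.table["confidence"] > HIGH_CONFIDENCE
    return result


def leave_one_out_accuracy(reference, labels, k: int = 5) -> float:
    """Proportion of reference taxa recovering their own label when held
    out and re-placed by k-NN against the remaining references."""
    ref = _as_frame(reference)
    lab = pd.Series(labels).reindex(ref.index)
    vals = ref.to_numpy(dtype=float)
    valid = ~np.isnan(vals)
    taxa = [str(t) for t in ref.index]
    labs = [str(l) for l in lab]
    hits = 0
    for i in range(len(taxa)):
        others = [j for j in range(len(taxa)) if j != i]
        d = _mismatch_distances(vals[i], valid[i], vals[others], valid[others])
        pred, _ = _predict_one(d, [taxa[j] for j in others],
                               [labs[j] for j in others], k)
        if pred == labs[i]:
            hits += 1
    return hits / len(taxa)


# ---------------------------------------------------------------------------
# Recursive partitioning (CART-style identification keys)


@dataclass
class KeyNode:
    """One split (internal) or leaf of a partition tree.

    Internal nodes test ``character <= threshold`` (numeric) or
    ``character == 0`` (binary, phrased as state absent); rows satisfying
    the test go left.  Missing values follow the majority branch
    recorded at fit time.
    """

    character: str | None = None
    threshold: float | None = None
    is_binary_split: bool = False
    missing_goes_left: bool = True
    left: "KeyNode | None" = None
    right: "KeyNode | None" = None
    leaf_label: str | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.leaf_label is not None


@dataclass
class KeyTree:
    """A fitted partition tree with bookkeeping for key rendering."""

    root: KeyNode
    characters_used: set[str]
    resub_error: float
    classes: list[str]
    n_training: int

    def predict_row(self, row: pd.Series) -> str:
        node = self.root
        while not node.is_leaf:
            v = row.get(node.character, np.nan)
            if pd.isna(v):
                go_left = node.missing_goes_left
            elif node.is_binary_split:
                go_left = v == 0
            else:
                go_left = v <= node.threshold
            node = node.left if go_left else node.right
        return node.leaf_label

    def predict(self, matrix) -> pd.Series:
        df = _as_frame(matrix)
        return pd.Series(
            {str(t): self.predict_row(df.loc[t]) for t in df.index},
            name="predicted",
        )


def _gini(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - (p**2).sum())


@dataclass(frozen=True)
class PartitionParams:
    """Stopping rules for tree growth.

    ``min_node``: smallest node size still eligible for splitting;
    ``min_gain``: minimum Gini decrease, as a fraction of the root
    impurity; ``max_depth``: maximum number of splits on any path.
    """

    min_node: int = 4
    min_gain: float = 0.01
    max_depth: int = 10


def _best_split(df, y, classes, min_gain_abs):
    """Best (gain, character, threshold, is_binary) split of one node."""
    n = len(y)
    class_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_idx[v] for v in y])
    parent_counts = np.bincount(y_idx, minlength=len(classes))
    parent_gini = _gini(parent_counts)
    best = None
    for name in df.columns:
        col = df[name].to_numpy(dtype=float)
        scored = ~np.isnan(col)
        if scored.sum() < 2:
            continue
        vals = np.unique(col[scored])
        if len(vals) < 2:
            continue
        binary = set(vals) <= {0.0, 1.0}
        thresholds = [0.5] if binary else (vals[:-1] + vals[1:]) / 2
        for thr in thresholds:
            left_mask = scored & (col <= thr)
            right_mask = scored & (col > thr)
            missing_left = left_mask.sum() >= right_mask.sum()
            if missing_left:
                left_mask = left_mask | ~scored
            else:
                right_mask = right_mask | ~scored
            nl, nr = left_mask.sum(), right_mask.sum()
            if nl == 0 or nr == 0:
                continue
            lc = np.bincount(y_idx[left_mask], minlength=len(classes))
            rc = np.bincount(y_idx[right_mask], minlength=len(classes))
            gain = parent_gini - (nl * _gini(lc) + nr * _gini(rc)) / n
            key = (-gain, str(name), float(thr))
            if gain >= min_gain_abs and (best is None or key < best[0]):
                best = (key, name, float(thr), binary, missing_left)
    return best


def _majority_class(y) -> tuple[str, dict[str, int]]:
    counts = Counter(y)
    top = max(counts.values())
    label = sorted(c for c, v in counts.items() if v == top)[0]
    return label, dict(counts)


def _grow(df, y, classes, params, min_gain_abs, depth) -> KeyNode:
    label, counts = _majority_class(y)
    if (
        len(set(y)) == 1
        or len(y) < params.min_node
        or depth >= params.max_depth
    ):
        return KeyNode(leaf_label=label, class_counts=counts)
    found = _best_split(df, y, classes, min_gain_abs)
    if found is None:
        return KeyNode(leaf_label=label, class_counts=counts)
    _, name, thr, binary, missing_left = found
    col = df[name].to_numpy(dtype=float)
    scored = ~np.isnan(col)
    left_mask = scored & (col <= thr)
    right_mask = scored & (col > thr)
    if missing_left:
        left_mask |= ~scored
    else:
        right_mask |= ~scored
    node = KeyNode(
        character=str(name), threshold=thr, is_binary_split=binary,
        missing_goes_left=missing_left, class_counts=counts,
    )
    node.left = _grow(df[left_mask], [v for v, m in zip(y, left_mask) if m],
                      classes, params, min_gain_abs, depth + 1)
    node.right = _grow(df[right_mask], [v for v, m in zip(y, right_mask) if m],
                       classes, params, min_gain_abs, depth + 1)
    return node


def grow_partition_tree(
    matrix, labels, params: PartitionParams | None = None
) -> KeyTree:
    """Fit a CART-style binary partition tree on (binary and/or numeric)
    characters.

    Splits greedily minimize weighted Gini impurity.  Binary characters
    split on state, numeric ones on midpoints between sorted distinct
    values; missing values follow the branch with more scored training
    rows at that node.  A single-class input yields a one-leaf tree (not
    an error).
    """
    params = params or PartitionParams()
    df = _as_frame(matrix)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError("empty character matrix")
    lab = pd.Series(labels).reindex(df.index)
    if lab.isna().any():
        raise ValueError("every training taxon needs a label")
    y = [str(v) for v in lab]
    classes = sorted(set(y))
    if len(classes) == 1:
        logger.info("single-class input; returning a one-leaf tree")
    class_idx = np.array([classes.index(v) for v in y])
    root_gini = _gini(np.bincount(class_idx, minlength=len(classes)))
    min_gain_abs = params.min_gain * root_gini if root_gini > 0 else np.inf
    root = _grow(df, y, classes, params, min_gain_abs, 0)
    tree = KeyTree(root=root, characters_used=set(), resub_error=0.0,
                   classes=classes, n_training=len(y))
    used = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            used.add(node.character)
            stack.extend([node.left, node.right])
    tree.characters_used = used
    pred = tree.predict(df)
    tree.resub_error = float(np.mean([p != t for p, t in zip(pred, y)]))
    return tree


def iterate_partition_runs(
    matrix, labels, n_runs: int = 3, params: PartitionParams | None = None
) -> list[KeyTree]:
    """Repeated partition-tree fits, each excluding characters used before.

    Surfaces successive layers of diagnostic characters; stops early with
    a warning if no characters remain.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    df = _as_frame(matrix)
    trees = []
    excluded: set[str] = set()
    for run in range(n_runs):
        remaining = [c for c in df.columns if str(c) not in excluded]
        if not remaining:
            logger.warning("no characters left after %d run(s); stopping", run)
            break
        trees.append(grow_partition_tree(df[remaining], labels, params))
        excluded |= trees[-1].characters_used
    return trees


# ---------------------------------------------------------------------------
# Dichotomous key rendering


def _condition_text(node: KeyNode, branch: str) -> str:
    if node.is_binary_split:
        state = "absent" if branch == "a" else "present"
        return f"{node.character} {state}"
    thr = float(f"{node.threshold:.3g}")
    cmp_ = "at most" if branch == "a" else "more than"
    return f"{node.character} {cmp_} {thr:g}"


def render_key(tree: KeyTree) -> str:
    """Render a partition tree as a numbered dichotomous key.

    One couplet ("Na./Nb.") per internal node, numbered by pre-order
    traversal; each lead ends in a class name or a forward reference to
    another couplet.  Rendering is deterministic.
    """
    if tree.root.is_leaf:
        return f"1. single group . . . {tree.root.leaf_label}\n"
    numbers: dict[int, int] = {}
    counter = [0]

    def number(node: KeyNode) -> None:
        if node.is_leaf:
            return
        counter[0] += 1
        numbers[id(node)] = counter[0]
        number(node.left)
        number(node.right)

    number(tree.root)
    lines = []

    def target(node: KeyNode) -> str:
        if node.is_leaf:
            return node.leaf_label
        return str(numbers[id(node)])

    def emit(node: KeyNode) -> None:
        if node.is_leaf:
            return
        num = numbers[id(node)]
        for branch, child in (("a", node.left), ("b", node.right)):
            cond = _condition_text(node, branch)
            lines.append(f"{num}{branch}. {cond} . . . {target(child)}")
        emit(node.left)
        emit(node.right)

    emit(tree.root)
    return "\n".join(lines) + "\n"
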