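"""Congruence among distance matrices (CADM).

Kendall's coefficient of concordance W is computed over the ranked
upper triangles of two or more distance matrices sharing a taxon set,
together with its chi-square-scaled form (Friedman's statistic,
``chi2 = m * (n - 1) * W`` for ``m`` matrices ranking ``n`` pairwise
distances).  Significance comes from a permutation test in which the
taxon order of every matrix except the first is permuted independently;
the p-value uses the add-one estimator, whose smallest attainable value
is ``1 / (n_permutations + 1)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .tree_ops import DistanceMatrix


@dataclass
class CADMResult:
    """Outcome of the concordance test.

    ``W`` lies in (0, 1]; 1 means all matrices rank the taxon pairs
    identically.  ``friedman_chi2 = m * (n_objects - 1) * W`` exactly.
    """

    W: float
    friedman_chi2: float
    p_value: float
    n_permutations: int
    m: int
    n_objects: int


def _aligned_rank_vectors(matrices) -> tuple[list[str], np.ndarray]:
    """Validate label sets and return per-matrix midranks of the upper
    triangles in a shared (sorted-label) pair order."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 distance matrices")
    labels = sorted(matrices[0].labels)
    for dm in matrices[1:]:
        if set(dm.labels) != set(labels):
            missing = set(labels) ^ set(dm.labels)
            raise ValueError(f"label sets differ; symmetric difference: "
                             f"{sorted(missing)}")
    ranks = []
    for dm in matrices:
        if not dm.is_complete():
            raise ValueError("CADM requires complete distance matrices")
        vec = dm.reorder(labels).condensed()
        ranks.append(rankdata(vec))
    return labels, np.vstack(ranks)


def _w_from_ranks(ranks: np.ndarray) -> float:
    """Kendall's W with the tie-correction term, from midrank rows."""
    m, n = ranks.shape
    totals = ranks.sum(axis=0)
    s = float(((totals - totals.mean()) ** 2).sum())
    correction = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        correction += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * correction
    if denom <= 0:
        raise ValueError("degenerate ranking: all distances tied")
    return 12.0 * s / denom


def friedman_chi2(w: float, m: int, n_objects: int) -> float:
    """Friedman's chi-square scaling of W: ``m * (n_objects - 1) * W``."""
    return m * (n_objects - 1) * w


def kendall_w(matrices) -> tuple[float, float]:
    """Concordance W and Friedman chi-square for >= 2 distance matrices.

    For two matrices W equals ``(1 + rho_s) / 2`` where ``rho_s`` is the
    Spearman correlation of the two distance vectors.
    """
    _, ranks = _aligned_rank_vectors(matrices)
    w = _w_from_ranks(ranks)
    return w, friedman_chi2(w, ranks.shape[0], ranks.shape[1])


def _pair_index_matrix(n: int) -> np.ndarray:
    """(n, n) matrix mapping a taxon pair to its condensed-vector slot."""
    P = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    P[iu] = np.arange(len(iu[0]))
    return P + P.T


def _permuted_w(ranks, tie_corrections, perms_per_matrix, pair_index, iu):
    """W values for a batch of taxon permutations of matrices 2..m.

    ``perms_per_matrix``: array (m-1, n_perm, n_taxa) of taxon orders.
    Permuting taxa only re-pairs existing distances, so each permuted
    rank vector is a gather of the original one; tie corrections are
    invariant.
    """
    m, n_pairs = ranks.shape
    n_perm = perms_per_matrix.shape[1]
    totals = np.broadcast_to(ranks[0], (n_perm, n_pairs)).copy()
    for k in range(1, m):
        sigma = perms_per_matrix[k - 1]
        slots = pair_index[sigma[:, iu[0]], sigma[:, iu[1]]]
        totals += ranks[k][slots]
    s = ((totals - totals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    denom = m**2 * (n_pairs**3 - n_pairs) - m * tie_corrections
    return 12.0 * s / denom


def cadm_test(
    matrices,
    n_permutations: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
) -> CADMResult:
    """CADM permutation test of concordance among distance matrices.

    The null hypothesis is incongruence (independent rankings).  Matrices
    2..m have their taxon order permuted independently; the first stays
    fixed.  ``p = (1 + #{W_perm >= W_obs}) / (n_permutations + 1)``.

    With ``exhaustive=True`` all ``(n!)**(m-1)`` joint permutations are
    enumerated (tiny inputs only) and the p-value is the exact fraction
    of permutations, identity included, with ``W_perm >= W_obs``.
    """
    labels, ranks = _aligned_rank_vectors(matrices)
    m, n_pairs = ranks.shape
    n = len(labels)
    w_obs = _w_from_ranks(ranks)
    tie_corr = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_corr += float((counts**3 - counts).sum())
    pair_index = _pair_index_matrix(n)
    iu = np.triu_indices(n, k=1)

    if exhaustive:
        if math.factorial(n) ** (m - 1) > 200000:
            raise ValueError("exhaustive enumeration infeasible at this size")
        all_perms = list(itertools.permutations(range(n)))
        count = 0
        total = 0
        for combo in itertools.product(all_perms, repeat=m - 1):
            sigma = np.array(combo)[:, None, :]
            w = _permuted_w(ranks, tie_corr, sigma, pair_index, iu)[0]
            total += 1
            if w >= w_obs - 1e-12:
                count += 1
        p = count / total
        return CADMResult(w_obs, friedman_chi2(w_obs, m, n_pairs), p,
                          total, m, n_pairs)

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    exceed = 0
    block = max(1, min(2000, 5_000_000 // max(n_pairs, 1)))  # memory cap
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perms = np.empty((m - 1, b, n), dtype=np.int64)
        for k in range(m - 1):
            perms[k] = np.argsort(rng.random((b, n)), axis=1)
        w_perm = _permuted_w(ranks, tie_corr, perms, pair_index, iu)
        exceed += int((w_perm >= w_obs - 1e-12).sum())
        done += b
    p = (exceed + 1) / (n_permutations + 1)
    return CADMResult(w_obs, friedman_chi2(w_obs, m, n_pairs), p,
                      n_permutations, m, n_pairs)
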