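"""High-level study steps composed from the core modules.

These are the units the numbered analysis drivers (and the acceptance
script) run: marker-wise congruence, the molecular-vs-morphological
Procrustes comparison, masked-taxon placement experiments, and null
calibration of the two permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import leave_one_out_accuracy, placement_confidence
from .congruence import CADMResult, cadm_test
from .io_formats import Alignment
from .morph_integration import (
    ProcrustesResult,
    classical_mds,
    procrustes_superimpose,
    protest,
)
from .synthetic import StudyBundle, simulate_yule_tree
from .tree_ops import DistanceMatrix, character_distance_matrix, cophenetic_distances


def marker_distance_matrices(aln: Alignment) -> dict[str, DistanceMatrix]:
    """Per-marker mismatch distance matrices over the common sequenced taxa.

    Taxa missing an entire marker (union fill-in) are dropped from every
    matrix so the congruence test compares identical label sets.
    """
    keep = [
        t for i, t in enumerate(aln.taxa)
        if all((aln.sites[i, s:e] != "?").any()
               for s, e in aln.partitions.values())
    ]
    if len(keep) < 4:
        raise ValueError("fewer than 4 taxa sequenced for every marker")
    rows = [aln.taxa.index(t) for t in keep]
    out = {}
    for name, (s, e) in sorted(aln.partitions.items(), key=lambda kv: kv[1]):
        sub = Alignment(list(keep), aln.sites[np.ix_(rows, range(s, e))])
        out[name] = character_distance_matrix(sub)
    return out


def study_congruence(
    bundle: StudyBundle, n_permutations: int = 10_000, seed: int = 0
) -> CADMResult:
    """CADM test among the bundle's marker distance matrices."""
    dms = list(marker_distance_matrices(bundle.alignment).values())
    return cadm_test(dms, n_permutations=n_permutations, seed=seed)


@dataclass
class IntegrationResult:
    """Molecular vs morphological diversity comparison."""

    protest: ProcrustesResult
    molecular_ordination: object
    morphological_ordination: object


def study_procrustes(
    bundle: StudyBundle, n_permutations: int = 999, seed: int = 0
) -> IntegrationResult:
    """PROTEST between 2-D embeddings of molecular and morphological
    distances over the bundle's taxa.

    Restricted to taxa sequenced for every marker so the molecular
    distance matrix is complete (block missingness can otherwise leave
    taxon pairs with no comparable sites)."""
    aln = bundle.alignment
    keep = [
        t for i, t in enumerate(aln.taxa)
        if all((aln.sites[i, s:e] != "?").any()
               for s, e in aln.partitions.values())
    ]
    rows = [aln.taxa.index(t) for t in keep]
    mol_dm = character_distance_matrix(
        Alignment(list(keep), aln.sites[rows]))
    morph_df = bundle.morphology.to_dataframe().loc[keep]
    morph_dm = character_distance_matrix(morph_df)
    mol = classical_mds(mol_dm, dims=2)
    morph = classical_mds(morph_dm, dims=2)
    res = protest(mol, morph, n_permutations=n_permutations, seed=seed)
    return IntegrationResult(res, mol, morph)


@dataclass
class MaskedPlacementResult:
    """Placement of taxa whose molecular data was withheld."""

    accuracy: float
    mean_confidence: float
    majority_baseline: float
    n_queries: int


def masked_placement_experiment(
    bundle: StudyBundle,
    mask_fraction: float = 0.2,
    k: int = 5,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> MaskedPlacementResult:
    """Hide the molecular data of a random subset of taxa and re-place
    them into sections from morphology alone.

    The reference is the combined (molecular + morphological) matrix of
    the remaining taxa; queries retain only their morphological
    characters.  Accuracy is measured against the clade-derived section
    labels, alongside the majority-class baseline.
    """
    rng = np.random.default_rng(seed)
    taxa = list(bundle.morphology.taxa)
    n_mask = max(1, int(round(mask_fraction * len(taxa))))
    masked = sorted(rng.choice(taxa, size=n_mask, replace=False))
    kept = [t for t in taxa if t not in set(masked)]

    # encode nucleotides as integer codes for mismatch distances
    codes = bundle.alignment.sites.view(np.uint32).reshape(
        bundle.alignment.sites.shape).astype(float)
    codes[bundle.alignment.missing_mask(count_gaps=True)] = np.nan
    mol = pd.DataFrame(codes, index=bundle.alignment.taxa,
                       columns=[f"site{j}" for j in range(codes.shape[1])])
    morph = bundle.morphology.to_dataframe()
    combined = mol.join(morph)

    reference = combined.loc[kept]
    queries = combined.loc[masked].copy()
    queries.loc[:, mol.columns] = np.nan  # molecular data withheld

    labels = bundle.sections
    res = placement_confidence(reference, labels.loc[kept], queries, k=k,
                               n_bootstrap=n_bootstrap, seed=seed)
    predicted = res.table["predicted_label"]
    truth = labels.loc[masked]
    accuracy = float((predicted.loc[masked] == truth).mean())
    baseline = float(labels.loc[kept].value_counts(normalize=True).iloc[0])
    return MaskedPlacementResult(
        accuracy=accuracy,
        mean_confidence=float(res.table["confidence"].mean()),
        majority_baseline=baseline,
        n_queries=n_mask,
    )


def section_loo_accuracy(bundle: StudyBundle, k: int = 5) -> float:
    """Leave-one-out k-NN accuracy of morphology against section labels."""
    return leave_one_out_accuracy(bundle.morphology.to_dataframe(),
                                  bundle.sections, k=k)


# ---------------------------------------------------------------------------
# Null calibration of the permutation tests


def cadm_rejection_rate(
    n_simulations: int = 1000,
    n_taxa: int = 12,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical size of the CADM test on independent random trees.

    Two cophenetic matrices from independent topologies are, under the
    permutation null, exchangeable in taxon order; a calibrated test
    rejects at level alpha about alpha of the time.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_simulations + 1)
    rejections = 0
    for i in range(n_simulations):
        a = cophenetic_distances(
            simulate_yule_tree(n_taxa, seed=int(seeds[2 * i]) % 2**31))
        b = cophenetic_distances(
            simulate_yule_tree(n_taxa, seed=int(seeds[2 * i + 1]) % 2**31))
        res = cadm_test([a, b], n_permutations=n_permutations,
                        seed=int(seeds[-1] + i) % 2**31)
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_simulations


def protest_rejection_rate(
    n_simulations: int = 1000,
    n_points: int = 12,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical size of PROTEST on independent Gaussian configurations."""
    from .morph_integration import Ordination

    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_points)]
    rejections = 0
    for i in range(n_simulations):
        X = Ordination(labels, rng.standard_normal((n_points, 2)), np.array([]))
        Y = Ordination(labels, rng.standard_normal((n_points, 2)), np.array([]))
        res = protest(X, Y, n_permutations=n_permutations,
                      seed=int(rng.integers(2**31)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_simulations
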