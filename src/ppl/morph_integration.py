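"""Molecular <-> morphological comparison machinery.

* replication of the morphological block to approximate parity with the
  molecular characters before building a combined matrix;
* principal-coordinates (classical MDS) embedding of cophenetic
  distances and 2-D binned-kernel density surfaces over the ordination;
* Procrustes superimposition of two ordinations with the PROTEST
  permutation test (correlation = sqrt(1 - m12^2));
* per-character "molecular weights": bootstrap Spearman correlation of a
  character's pairwise dissimilarities with reference (cophenetic)
  distances;
* chi-square association tests with the bias-corrected Cramér's V.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import chi2_contingency, rankdata

from .io_formats import BinaryCharacterMatrix
from .tree_ops import DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Replication to parity


def replicate_to_parity(
    morph: BinaryCharacterMatrix, n_molecular_chars: int
) -> BinaryCharacterMatrix:
    """Duplicate every morphological column to approach molecular parity.

    The replication factor is ``r = max(1, round(n_mol / n_morph))``;
    names get a copy-index suffix.  Because mismatch-proportion distances
    scale numerator and denominator equally, replication changes no
    distance computed on the morphological block alone — it only
    re-weights morphology inside a combined matrix.
    """
    if morph.n_characters == 0:
        raise ValueError("empty morphological matrix")
    if n_molecular_chars < 1:
        raise ValueError("n_molecular_chars must be >= 1")
    r = max(1, int(round(n_molecular_chars / morph.n_characters)))
    states = np.tile(morph.states, (1, r))
    names = [f"{name}_c{k + 1}" for k in range(r) for name in morph.characters]
    return BinaryCharacterMatrix(list(morph.taxa), names, states,
                                 name=morph.name)


# ---------------------------------------------------------------------------
# Classical MDS (principal coordinates)


@dataclass
class Ordination:
    """A centered low-dimensional embedding (2-D in all the analyses)."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.labels):
            raise ValueError("one coordinate row per label required")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> Ordination:
    """Principal-coordinates embedding of a distance matrix.

    Double-centers ``-D**2 / 2``, keeps the top ``dims`` eigenpairs and
    scales eigenvectors by the square roots of their eigenvalues.
    Negative eigenvalues (non-Euclidean input) are dropped with a logged
    warning; asking for more dimensions than there are positive
    eigenvalues is an error.
    """
    if not dm.is_complete():
        raise ValueError("MDS requires a complete distance matrix")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = dm.n
    d2 = dm.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * abs(eigval[0])) if n else 0.0
    n_pos = int((eigval > tol).sum())
    if (eigval < -tol).any():
        logger.warning(
            "distance matrix is non-Euclidean: %d negative eigenvalues "
            "(most negative %.3g) dropped", int((eigval < -tol).sum()),
            float(eigval.min()),
        )
    if dims > n_pos:
        raise ValueError(
            f"requested {dims} dimensions but only {n_pos} positive "
            f"eigenvalues"
        )
    coords = eigvec[:, :dims] * np.sqrt(eigval[:dims])
    return Ordination(list(dm.labels), coords, eigval[:n_pos])


# ---------------------------------------------------------------------------
# Density surfaces


@dataclass
class DensitySurface:
    """Gridded 2-D kernel density; integrates to 1 over the grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    density: np.ndarray
    bandwidth: tuple[float, float]

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.grid_y,
                                               axis=1), self.grid_x))


def _normal_reference_bandwidth(x: np.ndarray) -> float:
    # 1-D normal reference rule, h = 1.06 * sigma * n^(-1/5)
    return 1.06 * float(np.std(x, ddof=1)) * len(x) ** (-0.2)


def density_surface(
    config: Ordination, grid_size: int = 128, bandwidth=None
) -> DensitySurface:
    """Binned 2-D Gaussian kernel density over an ordination.

    Points are binned on a ``grid_size`` x ``grid_size`` lattice spanning
    the data range padded by three bandwidths, the counts are convolved
    with a Gaussian kernel, and the surface is normalized to unit
    integral.  The default per-axis bandwidth is the normal reference
    rule.
    """
    pts = config.coordinates[:, :2]
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError(
            "zero variance on an ordination axis; jitter the points or "
            "drop the axis"
        )
    if bandwidth is None:
        bw = (_normal_reference_bandwidth(pts[:, 0]),
              _normal_reference_bandwidth(pts[:, 1]))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1]))
    if min(bw) <= 0:
        raise ValueError("bandwidths must be positive")
    lo = pts.min(axis=0) - 3 * np.asarray(bw)
    hi = pts.max(axis=0) + 3 * np.asarray(bw)
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[grid_size, grid_size],
                                  range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    cell = ((hi - lo) / (grid_size - 1))
    sigma_cells = (bw[0] / cell[0], bw[1] / cell[1])
    dens = ndimage.gaussian_filter(counts, sigma=sigma_cells, mode="constant")
    surf = DensitySurface(gx, gy, dens, bw)
    total = surf.integral()
    if total <= 0:
        raise ValueError("degenerate density surface")
    surf.density = dens / total
    return surf


# ---------------------------------------------------------------------------
# Procrustes / PROTEST


@dataclass
class ProcrustesResult:
    """Procrustes superimposition of configuration Y onto X.

    ``correlation = sqrt(1 - m12_squared)``; ``residuals`` are per-taxon
    displacement lengths after fitting (the arrow lengths on an overlay
    plot).  ``p_value`` is None until a permutation test is run.
    """

    correlation: float
    m12_squared: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residuals: pd.Series
    p_value: float | None = None
    n_permutations: int | None = None


def _normalized(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    center = coords.mean(axis=0)
    x = coords - center
    norm = float(np.sqrt((x**2).sum()))
    if norm == 0:
        raise ValueError("degenerate configuration: all points identical")
    return x / norm, center, norm


def procrustes_superimpose(
    X: Ordination, Y: Ordination, allow_reflection: bool = True
) -> ProcrustesResult:
    """Least-squares superimposition of Y onto X (translation, rotation,
    optional reflection, uniform scaling).

    Both configurations are centered and scaled to unit total sum of
    squares, the convention under which ``m12_squared`` lies in [0, 1]
    and is symmetric in its arguments.  Taxa are matched by label.
    """
    if set(X.labels) != set(Y.labels):
        diff = set(X.labels) ^ set(Y.labels)
        raise ValueError(f"label sets differ: {sorted(diff)}")
    order = [Y.labels.index(l) for l in X.labels]
    xn, x_center, x_norm = _normalized(X.coordinates)
    yn, y_center, y_norm = _normalized(Y.coordinates[order])
    M = xn.T @ yn
    U, svals, Vt = np.linalg.svd(M)
    R = Vt.T @ U.T  # maps yn onto xn
    if not allow_reflection and np.linalg.det(R) < 0:
        flip = np.ones(len(svals))
        flip[-1] = -1.0
        R = (Vt.T * flip) @ U.T
        svals = svals.copy()
        svals[-1] *= -1.0
    trace = float(svals.sum())
    m12sq = max(0.0, 1.0 - trace**2)
    scale = trace * x_norm / y_norm
    fitted = (yn @ R) * trace
    residuals = np.linalg.norm(xn - fitted, axis=1)
    translation = x_center - scale * (y_center @ R)
    return ProcrustesResult(
        correlation=float(np.sqrt(max(0.0, 1.0 - m12sq))),
        m12_squared=float(m12sq),
        rotation=R,
        scale=float(scale),
        translation=translation,
        residuals=pd.Series(residuals, index=list(X.labels)),
    )


def _batch_procrustes_correlation(xn, yn, perms, allow_reflection=True) -> np.ndarray:
    """Procrustes correlations of xn vs row-permuted yn, batched.

    ``perms``: (n_perm, n) integer row orders.  The correlation equals
    the sum of singular values of the cross-covariance of the unit-SS
    configurations; permuting rows of a centered matrix keeps it
    centered, so only a gather is needed.  Restricted to proper
    rotations, a negative-determinant cross-covariance loses twice its
    smallest singular value."""
    Y = yn[perms]  # (n_perm, n, d) still centered & unit-SS
    M = np.einsum("ni,bnj->bij", xn, Y)
    svals = np.linalg.svd(M, compute_uv=False)
    corr = svals.sum(axis=1)
    if not allow_reflection:
        dets = np.linalg.det(M)
        corr = np.where(dets < 0, corr - 2 * svals.min(axis=1), corr)
    return corr


def protest(
    X: Ordination, Y: Ordination, n_permutations: int = 999, seed: int = 0,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """PROTEST: permutation significance for the Procrustes correlation.

    The null permutes the row (taxon) assignment of Y; the p-value uses
    the add-one estimator, so 999 permutations floor at 0.001.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = procrustes_superimpose(X, Y, allow_reflection=allow_reflection)
    order = [Y.labels.index(l) for l in X.labels]
    xn, _, _ = _normalized(X.coordinates)
    yn, _, _ = _normalized(Y.coordinates[order])
    rng = np.random.default_rng(seed)
    n = xn.shape[0]
    exceed = 0
    block = 4000
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        corr = _batch_procrustes_correlation(xn, yn, perms, allow_reflection)
        exceed += int((corr >= result.correlation - 1e-12).sum())
        done += b
    result.p_value = (exceed + 1) / (n_permutations + 1)
    result.n_permutations = n_permutations
    return result


# ---------------------------------------------------------------------------
# Character "molecular weights"


@dataclass
class CharacterWeightTable:
    """Per-character bootstrap Spearman correlations with a reference
    distance matrix ('molecular weights')."""

    table: pd.DataFrame  # columns: median_rho, max_rho
    n_bootstrap: int

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("median_rho", ascending=False)


def _pairwise_character_dissimilarity(values: np.ndarray, ii, jj) -> np.ndarray:
    """Per-pair dissimilarity of one character column (NaN for missing)."""
    return np.abs(values[ii] - values[jj])


def _spearman_vs_reference(char_pairs: np.ndarray, ref_pairs: np.ndarray) -> float:
    ok = ~np.isnan(char_pairs) & ~np.isnan(ref_pairs)
    x = char_pairs[ok]
    y = ref_pairs[ok]
    if len(x) < 3 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return np.nan
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def character_weights(
    matrix, reference: DistanceMatrix, n_bootstrap: int = 1000, seed: int = 0,
) -> CharacterWeightTable:
    """Bootstrap Spearman correlation of each character with reference
    distances.

    For each character, its pairwise dissimilarity vector (0/1 mismatch
    for binary states, absolute difference for continuous traits) is
    rank-correlated with the matching reference (cophenetic) distances.
    Taxa are resampled with replacement ``n_bootstrap`` times (self-pairs
    dropped) and the median and maximum of the bootstrap rho distribution
    are reported per character.  Characters with fewer than two distinct
    non-missing states yield NaN with a warning.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if isinstance(matrix, BinaryCharacterMatrix):
        df = matrix.to_dataframe()
    else:
        df = pd.DataFrame(matrix).astype(float)
    taxa = [str(t) for t in df.index]
    if set(taxa) - set(reference.labels):
        raise ValueError("reference distance matrix does not cover all taxa")
    ref = reference.submatrix(taxa)
    values = df.to_numpy(dtype=float)
    n = len(taxa)
    rng = np.random.default_rng(seed)

    degenerate = [
        name for name, col in zip(df.columns, values.T)
        if len(np.unique(col[~np.isnan(col)])) < 2
    ]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} character(s) with <2 distinct states; "
            f"their rho is reported as NaN", stacklevel=2,
        )

    rhos = np.full((n_bootstrap, values.shape[1]), np.nan)
    ii, jj = np.triu_indices(n, k=1)
    for b in range(n_bootstrap):
        sample = rng.integers(n, size=n)
        si, sj = sample[ii], sample[jj]
        keep = si != sj
        si, sj = si[keep], sj[keep]
        ref_pairs = ref.values[si, sj]
        for c in range(values.shape[1]):
            if df.columns[c] in degenerate:
                continue
            char_pairs = _pairwise_character_dissimilarity(values[:, c], si, sj)
            rhos[b, c] = _spearman_vs_reference(char_pairs, ref_pairs)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pd.DataFrame(
            {
                "median_rho": np.nanmedian(rhos, axis=0),
                "max_rho": np.nanmax(rhos, axis=0),
            },
            index=[str(c) for c in df.columns],
        )
    table.loc[degenerate, :] = np.nan
    return CharacterWeightTable(table=table, n_bootstrap=n_bootstrap)


# ---------------------------------------------------------------------------
# Association tests


@dataclass
class AssociationResult:
    """Pearson chi-square with the bias-corrected Cramér's V effect size."""

    chi2: float
    df: int
    p_value: float
    cramers_v_corrected: float
    table: pd.DataFrame


def association_test(labels_a, labels_b) -> AssociationResult:
    """Chi-square association of two categorical labelings of taxa.

    Missing labels are dropped pairwise.  The effect size is Cramér's V
    with the Bergsma small-sample bias correction:
    ``phi2_corr = max(0, chi2/n - (r-1)(c-1)/(n-1))`` with shrunken
    ``r' = r - (r-1)^2/(n-1)`` and ``c'`` likewise.
    """
    a = pd.Series(labels_a).astype("object")
    b = pd.Series(labels_b).astype("object")
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    ok = a.notna() & b.notna()
    table = pd.crosstab(a[ok], b[ok])
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError(
            f"degenerate {r}x{c} contingency table; need >=2 categories "
            f"on both axes"
        )
    n = int(table.to_numpy().sum())
    chi2, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
    phi2 = chi2 / n
    phi2_corr = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    r_corr = r - (r - 1) ** 2 / (n - 1)
    c_corr = c - (c - 1) ** 2 / (n - 1)
    denom = min(r_corr - 1, c_corr - 1)
    v = float(np.sqrt(phi2_corr / denom)) if denom > 0 else 0.0
    return AssociationResult(
        chi2=float(chi2), df=int(dof), p_value=float(p),
        cramers_v_corrected=v, table=table,
    )
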