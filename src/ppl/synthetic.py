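"""Synthetic study-data generator.

Emits everything the downstream analyses consume — an ultrametric tree,
Jukes–Cantor sequence partitions, Mk2 binary morphology, Brownian-motion
morphometrics, clade-derived section labels, and structured missing
data — so the whole pipeline is exercisable without any external
download.  Two preset configurations mirror the shapes of the study's
real supermatrices: a "tall" one (273 taxa, ITS2 + trnL-F = 2062 bp, 18%
missing) and a "broad" one (87 taxa, five markers = 4188 bp, 23%
missing), each with 114 binary morphological characters and the seven
standard morphometric traits.

All generators are pure functions of their arguments plus an integer
seed (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .io_formats import MISSING, Alignment, BinaryCharacterMatrix

NUCLEOTIDES = np.array(["A", "C", "G", "T"])

#: The seven morphometric traits measured on herbarium samples: petiole,
#: leaf, spike and scape lengths, maximal leaf width, presence of a
#: taproot and presence of gaps in the inflorescence.
MORPHOMETRIC_TRAITS = ("PET.L", "LEAF.L", "SPIKE", "STALK", "LEAF.W",
                       "TAPROOT", "GAP")
BINARY_TRAITS = frozenset({"TAPROOT", "GAP"})


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic study bundle.

    Rates are expressed per unit branch length; trees are scaled to unit
    root-to-tip height, so ``subst_rate`` is the expected number of
    substitutions per site from root to tip.
    """

    n_taxa: int = 87
    birth_rate: float = 1.0
    n_sites: int = 4188
    subst_rate: float = 0.3
    n_binary_chars: int = 114
    char_rate: float = 0.5
    n_sections: int = 7
    missing_fraction: float = 0.23
    seed: int = 0
    markers: dict[str, int] = field(default_factory=dict)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_sites < 1 or self.n_binary_chars < 1:
            raise ValueError("counts must be at least 1 (taxa at least 2)")
        if self.birth_rate <= 0 or self.subst_rate <= 0 or self.char_rate <= 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.markers and sum(self.markers.values()) != self.n_sites:
            raise ValueError("marker lengths must sum to n_sites")


#: Shape of the study's two-marker, densely sampled supermatrix.
TALL_CONFIG = SimulationConfig(
    n_taxa=273, n_sites=2062, markers={"ITS2": 497, "trnL-F": 1565},
    missing_fraction=0.18,
)

#: Shape of the study's five-marker, data-rich supermatrix.
BROAD_CONFIG = SimulationConfig(
    n_taxa=87, n_sites=4188,
    markers={"COI": 656, "ITS2": 497, "rbcL": 561, "trnL-F": 1565,
             "matK": 909},
    missing_fraction=0.23,
)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trees


def simulate_yule_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    scale_height: float | None = 1.0,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_taxa`` tips.

    Lineages split after exponential waiting times; the process stops at
    the ``n_taxa``-th lineage and runs one further exponential increment
    so no tip sits exactly on a split.  The result is binary, rooted and
    ultrametric.  With ``scale_height`` set (default 1.0) all branch
    lengths are rescaled so the root-to-tip height equals that value,
    which makes substitution rates directly interpretable as expected
    changes per unit of tree height.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)
    width = len(str(n_taxa))
    taxon_namespace = dendropy.TaxonNamespace(
        [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    )
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            birth_time[id(child)] = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_taxa))
    order = rng.permutation(n_taxa)
    for k, leaf in enumerate(active):
        leaf.taxon = taxon_namespace[int(order[k])]
        leaf.edge.length = t - birth_time[id(leaf)]
    for node in tree.preorder_node_iter():
        if node is root:
            node.edge.length = 0.0
        elif not node.is_leaf():
            child = node.child_nodes()[0]
            node.edge.length = birth_time[id(child)] - birth_time[id(node)]
    first_split = birth_time[id(root.child_nodes()[0])]
    height = t - first_split  # root-to-tip distance (root sits at 1st split)
    if scale_height is not None and height > 0:
        factor = scale_height / height
        for edge in tree.preorder_edge_iter():
            if edge.length:
                edge.length *= factor
    return tree


def yule_tip_count(duration: float, birth_rate: float, rng) -> int:
    """Number of lineages after running a pure-birth process for ``duration``.

    Starts from a single lineage; E[count] = exp(birth_rate * duration).
    """
    t, n = 0.0, 1
    while True:
        t += rng.exponential(1.0 / (birth_rate * n))
        if t > duration:
            return n
        n += 1


# ---------------------------------------------------------------------------
# Characters on trees


def _simulate_markov_tips(tree, n_chars, flip_prob, root_states, rng):
    """Evolve 2-state symmetric characters down the tree; returns tip rows."""
    states = {id(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_states = states[id(node.parent_node)]
        p = flip_prob(node.edge.length or 0.0)
        flips = rng.random(n_chars) < p
        states[id(node)] = np.where(flips, 1 - parent_states, parent_states)
    return {
        leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def simulate_binary_characters(
    tree: dendropy.Tree, n_chars: int, char_rate: float, seed: int = 0,
    prefix: str = "m",
) -> BinaryCharacterMatrix:
    """Binary characters evolved under the symmetric 2-state Markov model.

    Each character evolves independently from a stationary (1/2, 1/2)
    root; the flip probability over a branch of length ``t`` is
    ``(1 - exp(-2 * char_rate * t)) / 2`` (``char_rate`` is the rate of
    each of the two transitions).
    """
    if char_rate <= 0:
        raise ValueError("char_rate must be positive")
    rng = _rng(seed)
    root = (rng.random(n_chars) < 0.5).astype(float)
    tips = _simulate_markov_tips(
        tree, n_chars,
        lambda t: 0.5 * (1.0 - np.exp(-2.0 * char_rate * t)),
        root, rng,
    )
    taxa = sorted(tips)
    states = np.vstack([tips[t] for t in taxa])
    width = len(str(n_chars))
    names = [f"{prefix}{j + 1:0{width}d}" for j in range(n_chars)]
    return BinaryCharacterMatrix(taxa, names, states, name="morphology")


def simulate_sequences(
    tree: dendropy.Tree, n_sites: int, subst_rate: float, seed: int = 0,
    partition_name: str = "seq",
) -> Alignment:
    """Nucleotide alignment evolved under Jukes–Cantor.

    The probability that a site differs from its parent after a branch of
    length ``t`` is ``(3/4) * (1 - exp(-4 * subst_rate * t / 3))``; a
    changed site picks uniformly among the three other bases.
    """
    if subst_rate <= 0:
        raise ValueError("subst_rate must be positive")
    rng = _rng(seed)
    states = {id(tree.seed_node): rng.integers(4, size=n_sites)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_change = 0.75 * (1.0 - np.exp(-4.0 * subst_rate * t / 3.0))
        change = rng.random(n_sites) < p_change
        shift = rng.integers(1, 4, size=n_sites)
        states[id(node)] = np.where(change, (parent + shift) % 4, parent)
    tips = {leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()}
    taxa = sorted(tips)
    sites = NUCLEOTIDES[np.vstack([tips[t] for t in taxa])]
    return Alignment(taxa, sites, {partition_name: (0, n_sites)})


def simulate_morphometrics(
    tree: dendropy.Tree,
    trait_names=MORPHOMETRIC_TRAITS,
    sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Morphometric table simulated by Brownian motion on the tree.

    Continuous traits diffuse from a root value of 0 with variance
    ``sigma**2`` per unit branch length.  The binary traits (TAPROOT,
    GAP) threshold an identically simulated Brownian liability at 0
    (state 1 iff liability > 0).
    """
    unknown = [t for t in trait_names if t not in MORPHOMETRIC_TRAITS]
    if unknown:
        raise ValueError(f"unknown trait names: {unknown}; "
                         f"choose from {list(MORPHOMETRIC_TRAITS)}")
    rng = _rng(seed)
    n = len(trait_names)
    values = {id(tree.seed_node): np.zeros(n)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        step = rng.standard_normal(n) * sigma * np.sqrt(t)
        values[id(node)] = values[id(node.parent_node)] + step
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    taxa = sorted(tips)
    table = pd.DataFrame(
        np.vstack([tips[t] for t in taxa]), index=taxa, columns=list(trait_names)
    )
    for trait in trait_names:
        if trait in BINARY_TRAITS:
            table[trait] = (table[trait] > 0).astype(float)
    return table


# ---------------------------------------------------------------------------
# Section labels


def _clade_tips(node) -> list[str]:
    return sorted(leaf.taxon.label for leaf in node.leaf_iter())


def assign_sections(tree: dendropy.Tree, n_sections: int) -> pd.Series:
    """Monophyletic section labels obtained by cutting the rooted tree.

    Greedy rule: repeatedly split the clade with the most tips at its
    root node (replacing it by its children); ties pick the clade whose
    alphabetically smallest tip comes first.  Labels S01, S02, ... are
    assigned to the resulting clades ordered by their smallest tip.
    """
    tips = _clade_tips(tree.seed_node)
    if not 2 <= n_sections <= len(tips):
        raise ValueError(
            f"n_sections must be in [2, {len(tips)}], got {n_sections}"
        )
    clades = [tree.seed_node]
    while len(clades) < n_sections:
        splittable = [c for c in clades if not c.is_leaf()]
        if not splittable:
            raise ValueError("tree cannot be cut into that many clades")
        largest = max(
            splittable,
            key=lambda c: (len(_clade_tips(c)),),
        )
        # break size ties by smallest contained tip name
        size = len(_clade_tips(largest))
        candidates = [c for c in splittable if len(_clade_tips(c)) == size]
        largest = min(candidates, key=lambda c: _clade_tips(c)[0])
        children = largest.child_nodes()
        if len(clades) - 1 + len(children) > n_sections:
            raise ValueError(
                f"cannot reach exactly {n_sections} sections: splitting a "
                f"{len(children)}-furcation overshoots"
            )
        clades.remove(largest)
        clades.extend(children)
    clades = sorted(clades, key=lambda c: _clade_tips(c)[0])
    width = max(2, len(str(n_sections)))
    labels = {}
    for k, clade in enumerate(clades):
        for tip in _clade_tips(clade):
            labels[tip] = f"S{k + 1:0{width}d}"
    return pd.Series(labels).sort_index().rename("section")


# ---------------------------------------------------------------------------
# Missing data


def inject_missing(matrix, fraction: float, seed: int = 0):
    """Blank exactly ``round(fraction * n_cells)`` cells uniformly at random.

    Works on :class:`Alignment` (cells become ``?``),
    :class:`BinaryCharacterMatrix` and numeric DataFrames (cells become
    NaN).  One random non-missing cell per row is reserved so no taxon is
    ever blanked completely; if the requested count cannot be placed an
    error is raised.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = _rng(seed)

    if isinstance(matrix, Alignment):
        cells = matrix.sites.copy()
        nonmissing = ~(cells == MISSING)
        n_cells = cells.size
    elif isinstance(matrix, BinaryCharacterMatrix):
        cells = matrix.states.copy()
        nonmissing = ~np.isnan(cells)
        n_cells = cells.size
    elif isinstance(matrix, pd.DataFrame):
        cells = matrix.to_numpy(dtype=float).copy()
        nonmissing = ~np.isnan(cells)
        n_cells = cells.size
    else:
        raise TypeError(f"unsupported matrix type {type(matrix).__name__}")

    k = int(np.rint(fraction * n_cells))
    if k == 0:
        return matrix

    n_rows = cells.shape[0]
    rows, cols = np.nonzero(nonmissing)  # row-major, rows sorted
    reserved = np.zeros(len(rows), dtype=bool)
    bounds = np.searchsorted(rows, np.arange(n_rows + 1))
    for r in range(n_rows):
        lo, hi = bounds[r], bounds[r + 1]
        if hi > lo:
            reserved[lo + int(rng.integers(hi - lo))] = True
    eligible = np.flatnonzero(~reserved)
    if k > eligible.size:
        raise ValueError(
            f"cannot blank {k} cells without fully blanking a row "
            f"({eligible.size} eligible cells)"
        )
    chosen = rng.choice(eligible, size=k, replace=False)
    blank_value = MISSING if isinstance(matrix, Alignment) else np.nan
    cells[rows[chosen], cols[chosen]] = blank_value

    if isinstance(matrix, Alignment):
        return Alignment(list(matrix.taxa), cells, dict(matrix.partitions))
    if isinstance(matrix, BinaryCharacterMatrix):
        return BinaryCharacterMatrix(
            list(matrix.taxa), list(matrix.characters), cells, name=matrix.name
        )
    return pd.DataFrame(cells, index=matrix.index, columns=matrix.columns)


def inject_missing_blocks(aln: Alignment, fraction: float, seed: int = 0) -> Alignment:
    """Blank whole (taxon, partition) blocks to approximate ``fraction``.

    Emulates the block-structured missingness of real supermatrices,
    where a taxon lacks entire markers rather than scattered cells.  At
    least one partition per taxon is retained.  Because blocks are
    atomic, the achieved fraction undershoots the target by at most one
    smallest-block share of the matrix.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if len(aln.partitions) < 2 and fraction > 0:
        raise ValueError("block-wise injection needs at least 2 partitions")
    rng = _rng(seed)
    cells = aln.sites.copy()
    target = fraction * cells.size
    parts = sorted(aln.partitions.items())
    candidates = [
        (i, name, s, e)
        for i in range(aln.n_taxa)
        for name, (s, e) in parts
    ]
    order = rng.permutation(len(candidates))
    blanked = 0.0
    kept = {i: len(parts) for i in range(aln.n_taxa)}
    for idx in order:
        i, _, s, e = candidates[idx]
        size = e - s
        if kept[i] <= 1 or blanked + size > target:
            continue
        cells[i, s:e] = MISSING
        kept[i] -= 1
        blanked += size
    return Alignment(list(aln.taxa), cells, dict(aln.partitions))


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class StudyBundle:
    """One self-consistent synthetic study: every table shares the tree's tips."""

    config: SimulationConfig
    tree: dendropy.Tree
    alignment: Alignment
    morphology: BinaryCharacterMatrix
    morphometrics: pd.DataFrame
    sections: pd.Series


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a complete synthetic study bundle from one config.

    Sequences are simulated per marker partition (independent seeds
    derived from ``config.seed``), concatenated, then blanked block-wise
    to the configured missing fraction; morphology is blanked cell-wise
    at the same fraction.  Section labels are clade-derived from the same
    tree that generated all characters.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(6 + max(len(config.markers), 1))]
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, seed=seeds[0])
    markers = config.markers or {"seq": config.n_sites}
    parts = []
    for k, (name, length) in enumerate(sorted(markers.items())):
        parts.append(
            simulate_sequences(tree, length, config.subst_rate,
                               seed=seeds[6 + k], partition_name=name)
        )
    alignment = parts[0]
    if len(parts) > 1:
        from .io_formats import concatenate_supermatrix

        alignment, _ = concatenate_supermatrix(parts, taxon_policy="union")
    if config.missing_fraction > 0:
        if len(markers) > 1:
            alignment = inject_missing_blocks(
                alignment, config.missing_fraction, seed=seeds[1]
            )
        else:
            alignment = inject_missing(
                alignment, config.missing_fraction, seed=seeds[1]
            )
    morphology = simulate_binary_characters(
        tree, config.n_binary_chars, config.char_rate, seed=seeds[2]
    )
    if config.missing_fraction > 0:
        morphology = inject_missing(
            morphology, config.missing_fraction, seed=seeds[3]
        )
    morphometrics = simulate_morphometrics(
        tree, sigma=config.sigma, seed=seeds[4]
    )
    sections = assign_sections(tree, config.n_sections)
    return StudyBundle(
        config=config,
        tree=tree,
        alignment=alignment,
        morphology=morphology,
        morphometrics=morphometrics,
        sections=sections,
    )


def scaled_config(config: SimulationConfig, n_taxa: int, n_sites: int | None = None,
                  **overrides) -> SimulationConfig:
    """A smaller copy of a preset config, markers rescaled proportionally."""
    changes = dict(n_taxa=n_taxa, **overrides)
    if n_sites is not None and config.markers:
        factor = n_sites / config.n_sites
        markers = {k: max(1, int(round(v * factor)))
                   for k, v in config.markers.items()}
        changes["markers"] = markers
        changes["n_sites"] = sum(markers.values())
    elif n_sites is not None:
        changes["n_sites"] = n_sites
    return replace(config, **changes)
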