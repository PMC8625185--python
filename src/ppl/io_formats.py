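"""Readers, writers and supermatrix construction.

The pipeline moves between four plain-text formats: FASTA (aligned
sequences), NEXUS / CSV (binary morphological matrices), Newick (trees)
and CSV (distance matrices, labels, morphometrics).  Everything is held
in small labelled containers so downstream code never touches raw file
syntax.

State alphabet conventions
--------------------------
* Sequences use the IUPAC nucleotide alphabet plus ``-`` (gap) and ``?``
  (missing).  ``N`` and blank are normalized to ``?`` on input.
* ``-`` stays distinct inside an :class:`Alignment` because indel coding
  needs gap extents, but it counts as missing for distance computations.
* Binary morphology uses ``0``/``1`` with ``NaN`` for missing.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = "?"
GAP = "-"


class AlignmentError(ValueError):
    """Raised when sequence records cannot form a rectangular alignment."""


class ParseError(ValueError):
    """Raised for malformed matrix or tree files."""


@dataclass
class Alignment:
    """A taxa x sites molecular character matrix with named partitions.

    Parameters
    ----------
    taxa : list of str
        Unique taxon identifiers, row order preserved.
    sites : ndarray of shape (n_taxa, n_sites), dtype ``<U1``
        Single-character states.
    partitions : dict
        Marker name -> half-open 0-based ``(start, end)`` interval.  The
        intervals must tile ``[0, n_sites)`` without overlap.
    """

    taxa: list[str]
    sites: np.ndarray
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype="<U1")
        if self.sites.ndim != 2:
            raise AlignmentError("sites must be a 2-D character matrix")
        if len(self.taxa) != self.sites.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxa but {self.sites.shape[0]} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon identifiers: {dupes}")
        if not self.partitions:
            self.partitions = {"all": (0, self.n_sites)}
        self._check_partitions()

    def _check_partitions(self) -> None:
        ivals = sorted(self.partitions.values())
        pos = 0
        for start, end in ivals:
            if start != pos or end < start:
                raise AlignmentError(
                    f"partitions {sorted(self.partitions.items())} do not "
                    f"tile [0, {self.n_sites})"
                )
            pos = end
        if pos != self.n_sites:
            raise AlignmentError(
                f"partitions cover [0, {pos}) but alignment has "
                f"{self.n_sites} sites"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.sites[self.taxa.index(taxon)]

    def missing_mask(self, count_gaps: bool = True) -> np.ndarray:
        """Boolean mask of cells treated as missing for distances/reports."""
        mask = self.sites == MISSING
        if count_gaps:
            mask |= self.sites == GAP
        return mask


@dataclass
class BinaryCharacterMatrix:
    """Taxa x binary (0/1/missing) morphological characters.

    ``states`` is a float array with values 0.0, 1.0 or NaN (missing).
    """

    taxa: list[str]
    characters: list[str]
    states: np.ndarray
    name: str = "binary"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ParseError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ParseError("duplicate taxon identifiers")
        valid = np.isnan(self.states) | (self.states == 0) | (self.states == 1)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ParseError(
                f"state {self.states[i, j]!r} at taxon {self.taxa[i]!r}, "
                f"character {self.characters[j]!r} is not in {{0, 1, ?}}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.taxa, columns=self.characters)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "binary"):
        return cls(
            taxa=[str(t).strip() for t in df.index],
            characters=[str(c) for c in df.columns],
            states=df.to_numpy(dtype=float),
            name=name,
        )


@dataclass
class MissingReport:
    """Missing-data accounting for a (super)matrix.

    ``fraction_missing`` equals the cell-weighted mean of the
    per-partition fractions by construction.
    """

    fraction_missing: float
    per_taxon: pd.Series
    per_partition: pd.Series


def missing_report(aln: Alignment, count_gaps: bool = False) -> MissingReport:
    """Count missing cells overall, per taxon and per partition.

    Gaps are not counted as missing by default: the report mirrors the
    usual "% missing data" bookkeeping for supermatrices, where ``?``
    marks unsequenced cells and ``-`` marks aligned indels.
    """
    mask = aln.missing_mask(count_gaps=count_gaps)
    per_taxon = pd.Series(mask.mean(axis=1), index=aln.taxa)
    per_part = {}
    for name, (s, e) in aln.partitions.items():
        per_part[name] = float(mask[:, s:e].mean()) if e > s else 0.0
    return MissingReport(
        fraction_missing=float(mask.mean()),
        per_taxon=per_taxon,
        per_partition=pd.Series(per_part),
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(path, partition_name: str | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    All records must have equal length.  States are upper-cased and
    ``N``/blank normalized to ``?``.  The single partition is named after
    the file stem unless ``partition_name`` is given.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    taxa = []
    rows = []
    length = len(records[0].seq)
    for rec in records:
        name = rec.id.strip()
        if name in taxa:
            raise AlignmentError(f"{path}: duplicate taxon {name!r}")
        if len(rec.seq) != length:
            raise AlignmentError(
                f"{path}: record {name!r} has length {len(rec.seq)}, "
                f"expected {length}"
            )
        taxa.append(name)
        rows.append(list(str(rec.seq).upper().replace("N", MISSING)))
    if partition_name is None:
        stem = str(path).rsplit("/", 1)[-1]
        partition_name = stem.rsplit(".", 1)[0]
    return Alignment(taxa, np.array(rows, dtype="<U1"),
                     {partition_name: (0, length)})


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.sites):
            fh.write(f">{taxon}\n{''.join(row)}\n")


# ---------------------------------------------------------------------------
# Binary matrices (NEXUS standard datatype / CSV)


def read_binary_matrix(path, dialect: str = "csv") -> BinaryCharacterMatrix:
    """Read a binary character matrix from NEXUS or CSV.

    CSV layout: header row of character names, first column taxon names.
    ``?`` and blank map to missing.  Any state outside {0, 1, ?} is a
    parse error naming the offending cell.
    """
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0, dtype=str)
        states = np.full(df.shape, np.nan)
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                raw = df.iat[i, j]
                cell = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
                if cell in ("", MISSING):
                    continue
                if cell not in ("0", "1"):
                    raise ParseError(
                        f"{path}: state {cell!r} at row {df.index[i]!r}, "
                        f"column {df.columns[j]!r} is not in {{0, 1, ?}}"
                    )
                states[i, j] = float(cell)
        return BinaryCharacterMatrix(
            taxa=[str(t).strip() for t in df.index],
            characters=[str(c) for c in df.columns],
            states=states,
        )
    if dialect == "nexus":
        try:
            mat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        except Exception as exc:  # dendropy raises assorted error types
            raise ParseError(f"{path}: NEXUS parse failed: {exc}") from exc
        taxa = [t.label.strip() for t in mat.taxon_namespace]
        n_chars = max(len(mat[t]) for t in mat.taxon_namespace)
        characters = [f"char{j + 1}" for j in range(n_chars)]
        states = np.full((len(taxa), n_chars), np.nan)
        for i, taxon in enumerate(mat.taxon_namespace):
            for j, cell in enumerate(mat[taxon]):
                sym = str(cell.symbol)
                if sym in (MISSING, GAP):
                    continue
                if sym not in ("0", "1"):
                    raise ParseError(
                        f"{path}: state {sym!r} at taxon {taxa[i]!r}, "
                        f"character {j + 1} is not in {{0, 1, ?}}"
                    )
                states[i, j] = float(sym)
        return BinaryCharacterMatrix(taxa=taxa, characters=characters, states=states)
    raise ValueError(f"unknown dialect {dialect!r}; use 'nexus' or 'csv'")


def write_binary_matrix(mat: BinaryCharacterMatrix, path, dialect: str = "csv") -> None:
    if dialect == "csv":
        df = mat.to_dataframe()
        out = df.map(lambda v: MISSING if np.isnan(v) else str(int(v)))
        out.to_csv(path)
        return
    if dialect == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={mat.n_taxa} NCHAR={mat.n_characters};\n")
            fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
            fh.write("  MATRIX\n")
            width = max(len(t) for t in mat.taxa) + 2
            for taxon, row in zip(mat.taxa, mat.states):
                cells = "".join(MISSING if np.isnan(v) else str(int(v)) for v in row)
                fh.write(f"    {quote_nexus_label(taxon):<{width}} {cells}\n")
            fh.write("  ;\nEND;\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}; use 'nexus' or 'csv'")


def quote_nexus_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}/\\,;:=*'\"`<>^"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path_or_string, default_branch_length: float = 1.0) -> dendropy.Tree:
    """Read a Newick tree; edges without lengths default to 1.0.

    With the default, cophenetic distances on a length-free tree reduce
    to node counts along the path.  Duplicate tip labels are an error.
    """
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        get = dict(data=src, schema="newick")
    else:
        get = dict(path=src, schema="newick")
    try:
        tree = dendropy.Tree.get(
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            **get,
        )
    except Exception as exc:
        raise ParseError(f"Newick parse failed: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.head_node is tree.seed_node else default_branch_length
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True, real_value_format_specifier=".10g")


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Supermatrix concatenation


def _as_char_block(block) -> tuple[list[str], np.ndarray, dict[str, tuple[int, int]]]:
    """Normalize a block to (taxa, char rows, partitions)."""
    if isinstance(block, Alignment):
        return block.taxa, block.sites, block.partitions
    if isinstance(block, BinaryCharacterMatrix):
        chars = np.full(block.states.shape, MISSING, dtype="<U1")
        chars[block.states == 0] = "0"
        chars[block.states == 1] = "1"
        return block.taxa, chars, {block.name: (0, block.n_characters)}
    raise TypeError(f"cannot concatenate block of type {type(block).__name__}")


def concatenate_supermatrix(
    blocks, taxon_policy: str = "union"
) -> tuple[Alignment, MissingReport]:
    """Concatenate alignments / binary matrices into one supermatrix.

    Under the ``union`` policy a taxon absent from a block is filled with
    ``?`` across that block's sites; ``intersection`` keeps only taxa
    present in every block.  Partition names come from the source blocks
    (suffixed on collision) and column order follows block order.
    """
    if not blocks:
        raise ValueError("need at least one block to concatenate")
    if taxon_policy not in ("union", "intersection"):
        raise ValueError(f"unknown taxon_policy {taxon_policy!r}")
    parsed = [_as_char_block(b) for b in blocks]

    if taxon_policy == "union":
        taxa: list[str] = []
        for btaxa, _, _ in parsed:
            for t in btaxa:
                if t not in taxa:
                    taxa.append(t)
    else:
        common = set(parsed[0][0])
        for btaxa, _, _ in parsed[1:]:
            common &= set(btaxa)
        if not common:
            raise ValueError("intersection taxon policy yields no shared taxa")
        taxa = [t for t in parsed[0][0] if t in common]

    total_sites = sum(chars.shape[1] for _, chars, _ in parsed)
    sites = np.full((len(taxa), total_sites), MISSING, dtype="<U1")
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for btaxa, chars, parts in parsed:
        index = {t: i for i, t in enumerate(btaxa)}
        for i, t in enumerate(taxa):
            if t in index:
                sites[i, offset:offset + chars.shape[1]] = chars[index[t]]
        for pname, (s, e) in sorted(parts.items(), key=lambda kv: kv[1]):
            name = pname
            k = 2
            while name in partitions:
                name = f"{pname}_{k}"
                k += 1
            partitions[name] = (offset + s, offset + e)
        offset += chars.shape[1]

    supermatrix = Alignment(taxa, sites, partitions)
    return supermatrix, missing_report(supermatrix)


# ---------------------------------------------------------------------------
# Simple indel coding


def gap_extents(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of '-' in one aligned row, as half-open intervals."""
    extents = []
    start = None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            extents.append((start, i))
            start = None
    if start is not None:
        extents.append((start, len(row)))
    return extents


def simple_indel_coding(aln: Alignment) -> BinaryCharacterMatrix:
    """Code gaps as binary presence/absence characters (simple indel coding).

    One character per distinct gap extent ``(start, end)`` observed in the
    alignment.  A taxon scores 1 when it bears exactly that extent, 0 when
    residues (or non-containing gaps) span the region, and missing when
    one of its gaps strictly contains the region, or the region overlaps
    missing data.
    """
    per_taxon = [gap_extents(row) for row in aln.sites]
    all_extents = sorted({e for extents in per_taxon for e in extents})
    states = np.zeros((aln.n_taxa, len(all_extents)))
    for i, extents in enumerate(per_taxon):
        own = set(extents)
        row = aln.sites[i]
        for j, (s, e) in enumerate(all_extents):
            if (s, e) in own:
                states[i, j] = 1.0
            elif any(gs <= s and ge >= e and (gs, ge) != (s, e)
                     for gs, ge in extents):
                states[i, j] = np.nan
            elif MISSING in row[s:e]:
                states[i, j] = np.nan
            else:
                states[i, j] = 0.0
    names = [f"indel_{s}_{e}" for s, e in all_extents]
    return BinaryCharacterMatrix(list(aln.taxa), names, states, name="indels")
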