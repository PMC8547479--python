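"""Readers, writers and validated containers for all external formats.

Formats handled
---------------
* count tables: delimited text, one ID axis in the header row, one in the
  first column (samples-by-taxa by default, transposed on request);
* phylogenies: newick with branch lengths (parsed with scikit-bio);
* per-sample metadata: delimited table with mandatory ``sample_id``,
  ``well_id`` and ``collection_day`` columns;
* square pairwise matrices: CSV with identical ID header row and ID first
  column, as in deposited betaNTI / RCbray matrices.

All containers validate their invariants on construction, and
:func:`align_inputs` cross-references the three primary inputs so the
numerical modules can assume consistent IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "FormatError",
    "ValidationError",
    "CountTable",
    "SampleMetadata",
    "PairwiseMatrix",
    "MATRIX_KINDS",
    "read_count_table",
    "write_count_table",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
    "read_square_matrix",
    "write_square_matrix",
    "align_inputs",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


#: numeric metadata columns recognised by :func:`read_metadata`
METADATA_NUMERIC = (
    "collection_day",
    "pH",
    "temperature",
    "conductance",
    "DO",
    "ORP",
    "DIC",
    "depth",
)

MATRIX_KINDS = ("bnti", "rcbray", "dissimilarity", "distance", "env_difference")

#: matrix kinds whose diagonal must be zero (others may leave it NaN)
_ZERO_DIAG_KINDS = ("dissimilarity", "distance", "env_difference")

_SYMMETRY_TOL = 1e-8


def _infer_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_delimited(path: Path, **kwargs) -> pd.DataFrame:
    import csv

    try:
        return pd.read_csv(path, sep=None, engine="python", **kwargs)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"could not parse delimited file {path}: {exc}") from exc


@dataclass(frozen=True)
class CountTable:
    """A samples x taxa matrix of non-negative abundances.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample ID, columns by taxon ID.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon IDs: {dups}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("count table contains missing values")
        if (values < 0).any():
            bad = df.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts in samples: {bad}")
        totals = values.sum(axis=1)
        if (totals <= 0).any():
            bad = df.index[totals <= 0].tolist()
            raise ValidationError(f"samples with zero total abundance: {bad}")
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.data.index)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(str(t) for t in self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as a float array, samples x taxa."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def relative_abundance(self) -> np.ndarray:
        """Within-sample relative abundances (rows sum to 1)."""
        x = self.matrix
        return x / x.sum(axis=1, keepdims=True)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids) -> "CountTable":
        return CountTable(self.data[list(taxon_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample environmental and design metadata.

    Wraps a DataFrame indexed by sample ID. Missing measurements are NaN,
    never zero. ``well_id`` and ``collection_day`` are always present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
        for col in ("well_id", "collection_day"):
            if col not in df.columns:
                raise FormatError(f"metadata is missing mandatory column {col!r}")
        if "pH" in df.columns:
            ph = pd.to_numeric(df["pH"], errors="coerce")
            bad = df.index[(ph < 0) | (ph > 14)].tolist()
            if bad:
                raise ValidationError(f"pH outside [0, 14] for samples: {bad}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.data.index)

    def variable(self, name: str) -> pd.Series:
        """Numeric values of one variable, NaN where missing."""
        if name not in self.data.columns:
            raise KeyError(f"metadata has no variable {name!r}")
        return pd.to_numeric(self.data[name], errors="coerce")

    def select_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class PairwiseMatrix:
    """A square symmetric matrix over sample (or taxon) IDs.

    ``kind`` records the semantics: ``bnti`` and ``rcbray`` scores may have
    NaN diagonals (self-comparison is undefined); dissimilarities and
    distances have zero diagonals.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"matrix is not square: shape {v.shape}")
        if v.shape[0] != len(ids):
            raise ValidationError("matrix shape does not match number of IDs")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate IDs in pairwise matrix")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        both_nan = np.isnan(v) != np.isnan(v.T)
        if both_nan.any():
            raise ValidationError("NaN pattern is not symmetric")
        if v.size and asym > _SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetric beyond tolerance ({asym:.3g} > {_SYMMETRY_TOL})"
            )
        if self.kind in _ZERO_DIAG_KINDS:
            diag = np.diag(v)
            if np.nanmax(np.abs(diag)) > _SYMMETRY_TOL:
                raise ValidationError(f"{self.kind} matrix must have a zero diagonal")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def loc(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])

    def select(self, ids) -> "PairwiseMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return PairwiseMatrix(
            tuple(str(i) for i in ids), self.values[np.ix_(idx, idx)], self.kind
        )

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (i > j) order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path: str | Path, orientation_hint: str | None = None) -> CountTable:
    """Read a delimited count table.

    Parameters
    ----------
    path : str or Path
        TSV/CSV file with IDs in the header row and first column.
    orientation_hint : {'samples_by_taxa', 'taxa_by_samples', None}
        Force the orientation. When None, rows are assumed to be samples
        (the layout written by :func:`write_count_table`).
    """
    path = Path(path)
    df = _read_delimited(path, index_col=0)
    if df.empty and df.shape[1] == 0:
        raise FormatError(f"count table has no data columns: {path}")
    if orientation_hint not in (None, "samples_by_taxa", "taxa_by_samples"):
        raise ValueError(f"unknown orientation hint {orientation_hint!r}")
    if orientation_hint == "taxa_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric entries in count table {path}: {exc}") from exc
    return CountTable(df)


def write_count_table(counts: CountTable, path: str | Path) -> None:
    """Write a count table as delimited text (samples as rows)."""
    counts.data.to_csv(path, sep=_infer_sep(path), float_format="%.12g", index_label="sample_id")


# ---------------------------------------------------------------------------
# trees


def _validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValidationError("tree must have at least 2 tips")
    if any(t is None for t in tips):
        raise ValidationError("tree has unnamed tips")
    seen: set[str] = set()
    for name in tips:
        if name in seen:
            raise ValidationError(f"duplicate tip label in tree: {name!r}")
        seen.add(name)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def read_newick(source: str | Path) -> skbio.TreeNode:
    """Read and validate a newick tree (file path or newick string)."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.rstrip().endswith(";")):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = skbio.TreeNode.read(StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"could not parse newick: {exc}") from exc
    return _validate_tree(tree)


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path, sample_id_column: str = "sample_id") -> SampleMetadata:
    """Read a per-sample metadata table.

    The join key defaults to ``sample_id`` but is configurable because
    composite well+date naming conventions vary between datasets.
    """
    path = Path(path)
    df = _read_delimited(path)
    if sample_id_column not in df.columns:
        raise FormatError(
            f"metadata is missing the sample ID column {sample_id_column!r} "
            f"(columns: {list(df.columns)})"
        )
    df = df.set_index(sample_id_column)
    df.index = df.index.astype(str)
    for col in METADATA_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, sep=_infer_sep(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# square pairwise matrices


def read_square_matrix(path: str | Path, kind: str) -> PairwiseMatrix:
    """Read a square CSV matrix with identical row/column IDs."""
    path = Path(path)
    df = _read_delimited(path, index_col=0)
    row_ids = [str(i).strip().strip('"') for i in df.index]
    col_ids = [str(c).strip().strip('"') for c in df.columns]
    if row_ids != col_ids:
        raise FormatError(
            f"row/column ID mismatch in {path}: rows {row_ids[:3]}..., columns {col_ids[:3]}..."
        )
    return PairwiseMatrix(tuple(row_ids), df.to_numpy(dtype=float), kind)


def write_square_matrix(matrix: PairwiseMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# cross-referencing


@dataclass
class AlignmentReport:
    """IDs dropped while aligning counts, tree and metadata."""

    dropped_taxa: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
    pruned_tips: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        return (
            f"dropped {len(self.dropped_taxa)} taxa, "
            f"{len(self.dropped_samples)} samples; "
            f"pruned {len(self.pruned_tips)} tree tips"
        )


def align_inputs(
    counts: CountTable,
    tree: skbio.TreeNode,
    metadata: SampleMetadata | None = None,
    strict: bool = True,
) -> tuple[CountTable, skbio.TreeNode, SampleMetadata | None, AlignmentReport]:
    """Restrict counts/tree/metadata to their common IDs.

    In strict mode (default) any count-table taxon absent from the tree is
    an error, because silently dropping taxa hides upstream ID bugs. In
    permissive mode unmatched taxa and samples are dropped and reported.
    The tree is pruned to the count-table taxa in both modes.
    """
    report = AlignmentReport()
    tip_names = {t.name for t in tree.tips()}
    taxa = list(counts.taxon_ids)
    missing_taxa = [t for t in taxa if t not in tip_names]
    if missing_taxa:
        if strict:
            raise ValidationError(
                f"{len(missing_taxa)} count-table taxa absent from tree "
                f"(strict mode): {missing_taxa[:10]}"
            )
        report.dropped_taxa = missing_taxa
        taxa = [t for t in taxa if t in tip_names]
    if not taxa:
        raise ValidationError("no taxa shared between count table and tree")

    samples = list(counts.sample_ids)
    if metadata is not None:
        meta_ids = set(metadata.sample_ids)
        missing_samples = [s for s in samples if s not in meta_ids]
        if missing_samples:
            if strict:
                raise ValidationError(
                    f"{len(missing_samples)} count-table samples absent from "
                    f"metadata (strict mode): {missing_samples[:10]}"
                )
            report.dropped_samples = missing_samples
            samples = [s for s in samples if s in meta_ids]
        if not samples:
            raise ValidationError("no samples shared between count table and metadata")

    sub = counts.data.loc[samples, taxa]
    # dropping taxa can empty a sample; such samples are removed with a report
    empty = sub.index[sub.sum(axis=1) <= 0].tolist()
    if empty:
        if strict:
            raise ValidationError(f"samples emptied by taxon restriction: {empty}")
        report.dropped_samples = report.dropped_samples + empty
        sub = sub.drop(index=empty)
        samples = [s for s in samples if s not in empty]
    if sub.empty:
        raise ValidationError("alignment left no samples")
    aligned_counts = CountTable(sub)

    extra_tips = sorted(tip_names - set(taxa))
    if extra_tips:
        tree = tree.shear(taxa)
        tree.prune()
        report.pruned_tips = extra_tips
    aligned_meta = metadata.select_samples(samples) if metadata is not None else None
    return aligned_counts, tree, aligned_meta, report
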