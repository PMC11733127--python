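"""Data model and IO for culturomics profiling output.

The pipeline consumes five plain-text artifacts produced downstream of
shotgun-metagenome profiling: a samples x mOTU abundance table, a
samples x KO functional table, per-sample metadata (donor, medium
modification, stool vs. culture), an mOTU taxonomy (phylum..species)
and an optional rooted Newick phylogeny over the mOTUs.

Tables are thin wrappers around :class:`pandas.DataFrame`; trees are
:class:`skbio.TreeNode`; distance matrices are
:class:`skbio.DistanceMatrix`.  All writers emit deterministic,
lexicographically ordered columns so outputs are byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import DataValueError, TableFormatError, UsageError

#: Taxonomic ranks, coarsest to finest.
RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: Label used for features missing from a taxonomy map.
UNASSIGNED = "unassigned"

#: Reserved modification id for the unmodified base medium.
BASE_MODIFICATION = "Base"

#: Valid table modes.  ``counts`` holds non-negative integers;
#: ``fraction`` holds closed compositions (rows sum to 1 or are all
#: zero); ``functional`` holds non-negative reals with no row-sum
#: constraint (e.g. KO abundances built as unnormalized sums of
#: carrier fractions).
MODES = ("counts", "fraction", "functional")

_CLOSE_TOL = 1e-9


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequenced sample.

    ``modification_id`` is empty only for stool samples; culture
    samples always name the medium modification they grew on
    (``"Base"`` for the unmodified base medium).
    """

    sample_id: str
    donor_id: str
    modification_id: str
    sample_type: str  # "stool" | "culture"
    dilution: str | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("stool", "culture"):
            raise DataValueError(
                f"sample_type must be 'stool' or 'culture', got {self.sample_type!r}"
            )
        if self.sample_type == "culture" and not self.modification_id:
            raise DataValueError(
                f"culture sample {self.sample_id!r} must name a modification"
            )


@dataclass(frozen=True)
class TaxonLineage:
    """Taxonomic assignment of one feature across the six fixed ranks."""

    feature_id: str
    ranks: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(RANKS) - set(self.ranks)
        if missing:
            raise DataValueError(
                f"lineage for {self.feature_id!r} missing ranks: {sorted(missing)}"
            )


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix with an explicit mode.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with feature-id columns.
    mode:
        One of :data:`MODES`.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise UsageError(f"unknown table mode {self.mode!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise TableFormatError("duplicate sample or feature ids")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise TableFormatError("missing values in abundance table")
        if (values < 0).any():
            raise DataValueError("abundance values must be non-negative")
        if self.mode == "counts":
            if not np.allclose(values, np.round(values)):
                raise DataValueError("counts mode requires integer-valued cells")
        elif self.mode == "fraction":
            sums = values.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=_CLOSE_TOL) | (sums == 0))
            if bad.any():
                raise DataValueError(
                    "fraction mode requires rows summing to 1 (or all-zero); "
                    f"offending samples: {list(self.data.index[bad][:5])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, mode: str = "counts") -> AbundanceTable:
    """Read a TSV abundance table (first column = sample ids)."""
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        raise TableFormatError(f"duplicate column ids in {path}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.isna().to_numpy().any():
        raise TableFormatError(f"ragged or incomplete rows in {path}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric cell in {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    return AbundanceTable(frame, mode=mode)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write TSV with lexicographic feature order; lossless round-trip."""
    frame = table.data.reindex(columns=sorted(table.data.columns))
    if table.mode == "counts":
        frame = frame.astype(np.int64)
    frame.index.name = "sample_id"
    # repr-based float formatting round-trips exactly through the reader
    frame.to_csv(path, sep="\t", float_format=None)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV into a frame indexed by sample id."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    if frame.index.has_duplicates:
        raise TableFormatError("duplicate sample ids in metadata")
    required = {"donor_id", "modification_id", "sample_type"}
    missing = required - set(frame.columns)
    if missing:
        raise TableFormatError(f"metadata missing columns: {sorted(missing)}")
    for sid, row in frame.iterrows():
        SampleRecord(
            sample_id=str(sid),
            donor_id=row["donor_id"],
            modification_id=row["modification_id"],
            sample_type=row["sample_type"],
        )
    frame.index.name = "sample_id"
    return frame


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def records_to_metadata(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = {
        r.sample_id: {
            "donor_id": r.donor_id,
            "modification_id": r.modification_id,
            "sample_type": r.sample_type,
        }
        for r in records
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a feature-id x rank taxonomy TSV (columns phylum..species)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        raise TableFormatError("duplicate feature ids in taxonomy")
    missing = set(RANKS) - set(frame.columns)
    if missing:
        raise TableFormatError(f"taxonomy missing ranks: {sorted(missing)}")
    frame.index.name = "feature_id"
    return frame[list(RANKS)].fillna(UNASSIGNED)


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# table algebra
# ---------------------------------------------------------------------------

def close_composition(table: AbundanceTable) -> AbundanceTable:
    """Close each row to sum 1 (relative abundances).

    All-zero rows are preserved as all-zero with a warning — empty
    plates are real observations, not errors.  Idempotent.
    """
    values = table.values()
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample(s) left unclosed: "
            f"{list(table.data.index[zero][:5])}",
            stacklevel=2,
        )
    out = np.zeros_like(values)
    np.divide(values, sums[:, None], out=out, where=~zero[:, None])
    frame = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(frame, mode="fraction")


def aggregate_by_rank(
    table: AbundanceTable, taxonomy: pd.DataFrame, rank: str
) -> AbundanceTable:
    """Sum features into their taxon label at ``rank``.

    Features absent from the taxonomy fall into an explicit
    ``"unassigned"`` bucket; per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise UsageError(f"unknown rank {rank!r}; choose from {RANKS}")
    labels = [
        str(taxonomy.at[f, rank]) if f in taxonomy.index else UNASSIGNED
        for f in table.data.columns
    ]
    grouped = table.data.T.groupby(pd.Index(labels, name=rank)).sum().T
    grouped = grouped.reindex(columns=sorted(grouped.columns))
    return AbundanceTable(grouped, mode=table.mode)


def detect(table: AbundanceTable, min_fraction: float = 0.0) -> pd.DataFrame:
    """Boolean presence table: fraction strictly above ``min_fraction``."""
    if table.mode == "counts":
        raise UsageError("detect() requires fractions; call close_composition first")
    if min_fraction < 0:
        raise UsageError("min_fraction must be >= 0")
    return table.data > min_fraction


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> TreeNode:
    """Parse a rooted Newick tree; missing branch lengths default to 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise TableFormatError(f"cannot parse Newick in {path}: {exc}") from exc
    defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            defaulted += 1
    if tree.length is None:
        tree.length = 0.0
    if defaulted:
        warnings.warn(
            f"{defaulted} branch(es) without length defaulted to 0", stacklevel=2
        )
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise TableFormatError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (same semantics as :func:`read_newick`)."""
    import io

    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise TableFormatError(f"cannot parse Newick string: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    return tree
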