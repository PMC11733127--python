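"""Per-sample diversity and fold-change summaries.

Covers species richness, Faith's phylogenetic diversity, the Hellinger
transform/distance used throughout the pipeline, log10 fold-change
heatmaps of family abundances over the base medium, and the Venn-style
presence-set summaries comparing stool with cultivation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import DataValueError, UsageError
from .tables_io import BASE_MODIFICATION, AbundanceTable

#: Fraction corresponding to the 0.001 % detection floor used in
#: fold-change calculations.
DEFAULT_FLOOR = 1e-5


def richness(presence: pd.DataFrame) -> pd.Series:
    """Number of detected features per sample (row sums of booleans)."""
    if presence.dtypes.apply(lambda d: d != bool).any():
        raise UsageError("richness expects a boolean presence table")
    return presence.sum(axis=1).astype(int)


def faith_pd(
    tree: TreeNode, present: Iterable[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a set of present leaves.

    Sum of branch lengths over the union of root-to-leaf paths for the
    present taxa.  ``include_root=True`` (default) keeps the edges
    connecting the set's ancestor to the tree root, which matches the
    convention of common ecology libraries; with ``False`` only edges
    below the most recent common ancestor are counted.  The empty set
    has PD 0.
    """
    present = set(present)
    if not present:
        return 0.0
    leaf_map = {t.name: t for t in tree.tips()}
    unknown = present - set(leaf_map)
    if unknown:
        raise UsageError(f"unknown leaf id(s): {sorted(unknown)[:5]}")
    visited: set[int] = set()
    union_nodes = []
    for name in present:
        node = leaf_map[name]
        while node.parent is not None and id(node) not in visited:
            visited.add(id(node))
            union_nodes.append(node)
            node = node.parent
    if include_root or len(present) == 0:
        return float(sum(n.length or 0.0 for n in union_nodes))
    # exclude the chain above the MRCA of the present set
    if len(present) == 1:
        return 0.0
    mrca = tree.lca([leaf_map[n] for n in present])
    chain = set()
    node = mrca
    while node.parent is not None:
        chain.add(id(node))
        node = node.parent
    return float(
        sum(n.length or 0.0 for n in union_nodes if id(n) not in chain)
    )


def hellinger_transform(row: Sequence[float] | np.ndarray) -> np.ndarray:
    """Square root of the closed composition; unit sum of squares."""
    vec = np.asarray(row, dtype=float)
    if (vec < 0).any():
        raise DataValueError("negative abundance in Hellinger transform")
    total = vec.sum()
    if total == 0:
        raise DataValueError("all-zero vector has no Hellinger transform")
    return np.sqrt(vec / total)


def hellinger_distance(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> float:
    """Euclidean distance between Hellinger-transformed compositions.

    Bounded by sqrt(2), attained on disjoint supports; insensitive to
    double zeros, which suits sparse ecological tables.
    """
    tx, ty = hellinger_transform(x), hellinger_transform(y)
    return float(np.linalg.norm(tx - ty))


def _hellinger_matrix(data: pd.DataFrame) -> np.ndarray:
    values = data.to_numpy(dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    return np.sqrt(values / sums)


def pairwise_hellinger(table: AbundanceTable) -> DistanceMatrix:
    """All-pairs Hellinger distances between samples.

    All-zero samples are dropped with a warning (no valid transform);
    at least two usable samples are required.
    """
    if table.mode == "counts":
        raise UsageError("pairwise_hellinger requires fractions; close first")
    sums = table.values().sum(axis=1)
    keep = sums > 0
    if keep.sum() < 2:
        raise UsageError("need at least 2 non-empty samples for distances")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero sample(s) from distances",
            stacklevel=2,
        )
    data = table.data.loc[keep]
    transformed = _hellinger_matrix(data)
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(transformed, metric="euclidean"))
    return DistanceMatrix(dm, ids=list(data.index))


def log10_fc_vs_base(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Mean log10 fold-change of each feature over the base medium.

    For each donor: log10(max(f_mod, floor) / max(f_base, floor)),
    then the arithmetic mean across donors.  The floor (default 1e-5,
    i.e. 0.001 %) keeps ratios finite for undetected features; donors
    without a Base culture sample are excluded with a warning.
    Returns features x modifications.
    """
    if floor <= 0:
        raise UsageError("floor must be positive")
    if table.mode == "counts":
        raise UsageError("log10_fc_vs_base requires fractions; close first")
    culture = metadata[metadata["sample_type"] == "culture"]
    mods = sorted(m for m in culture["modification_id"].unique()
                  if m != BASE_MODIFICATION)
    per_donor: list[pd.DataFrame] = []
    for donor, group in culture.groupby("donor_id"):
        base_samples = group.index[group["modification_id"] == BASE_MODIFICATION]
        if len(base_samples) == 0:
            warnings.warn(
                f"donor {donor} has no Base sample; excluded from fold-change",
                stacklevel=2,
            )
            continue
        base = np.maximum(
            table.data.loc[base_samples[0]].to_numpy(dtype=float), floor
        )
        cols = {}
        for mod in mods:
            mod_samples = group.index[group["modification_id"] == mod]
            if len(mod_samples) == 0:
                continue
            f_mod = np.maximum(
                table.data.loc[mod_samples[0]].to_numpy(dtype=float), floor
            )
            cols[mod] = np.log10(f_mod / base)
        per_donor.append(
            pd.DataFrame(cols, index=table.data.columns)
        )
    if not per_donor:
        raise UsageError("no donor has a Base sample")
    stacked = pd.concat(per_donor, keys=range(len(per_donor)))
    return stacked.groupby(level=1, sort=False).mean().reindex(
        index=table.data.columns
    )


def venn_counts(named_sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Exclusive-region counts for 2 or 3 named presence sets.

    Region keys join member names with ``&`` in the caller's order
    (e.g. ``"stool"``, ``"stool&culture"``).  Regions partition the
    union, so their counts sum to its size.
    """
    names = list(named_sets)
    if len(names) not in (2, 3):
        raise UsageError("venn_counts supports exactly 2 or 3 sets")
    sets = {n: set(named_sets[n]) for n in names}
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(
                set(), *(sets[m] for m in names if m not in members)
            )
            regions["&".join(members)] = len(inside - outside)
    return regions


def shared_fraction_summary(shared: int, subset: int) -> int:
    """Percentage of a shared pool captured by a subset, as printed.

    ``round(100 * subset / shared)`` with halves away from zero, the
    convention matching e.g. 54/105 -> 51 %.
    """
    if shared <= 0:
        raise DataValueError("shared pool must be positive")
    if not 0 <= subset <= shared:
        raise DataValueError("subset must lie within [0, shared]")
    return int(math.floor(100.0 * subset / shared + 0.5))
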