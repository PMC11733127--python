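"""Growth profiles across media modifications and their phylogenetic
association.

A taxon's growth profile is its mean relative abundance across
modifications (averaged over donors).  Comparing profiles within each
taxonomic rank quantifies whether related taxa prefer similar media:
when growth preference carries phylogenetic signal, the median
pairwise profile distance shrinks from phylum toward species.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import UsageError
from .tables_io import RANKS, AbundanceTable, aggregate_by_rank
from .diversity import hellinger_distance


def build_profiles(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str,
    per_donor: bool = False,
) -> pd.DataFrame:
    """Taxa x modifications growth profiles at a taxonomic rank.

    Culture samples are aggregated to ``rank`` and averaged over
    donors per modification (``per_donor=True`` instead keeps one
    column per donor x modification).  Taxa never observed anywhere
    are dropped with a warning.
    """
    if rank not in RANKS:
        raise UsageError(f"unknown rank {rank!r}")
    if table.mode == "counts":
        raise UsageError("build_profiles requires fractions; close first")
    culture = metadata[metadata["sample_type"] == "culture"]
    if culture.empty:
        raise UsageError("no culture samples in metadata")
    sub = AbundanceTable(table.data.loc[culture.index], mode="functional")
    agg = aggregate_by_rank(sub, taxonomy, rank)
    long = agg.data.copy()
    long["modification_id"] = culture["modification_id"]
    long["donor_id"] = culture["donor_id"]
    if per_donor:
        grouped = long.groupby(["donor_id", "modification_id"]).mean()
        profiles = grouped.T
        profiles.columns = [f"{d}|{m}" for d, m in profiles.columns]
    else:
        profiles = long.drop(columns="donor_id").groupby("modification_id").mean().T
    empty = profiles.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} taxa with all-zero profiles",
            stacklevel=2,
        )
        profiles = profiles.loc[~empty]
    profiles.index.name = rank
    return profiles


def profile_distances(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise Hellinger distances between profile rows."""
    transformed = np.sqrt(
        profiles.to_numpy(dtype=float)
        / profiles.sum(axis=1).to_numpy()[:, None]
    )
    return pdist(transformed, metric="euclidean")


def rank_distance_distribution(
    profiles_by_rank: Mapping[str, pd.DataFrame],
) -> dict[str, np.ndarray]:
    """Pairwise Hellinger distances within each taxonomic rank.

    Ranks with fewer than two profiles are excluded with a warning.
    """
    out: dict[str, np.ndarray] = {}
    for rank, profiles in profiles_by_rank.items():
        if len(profiles) < 2:
            warnings.warn(
                f"rank {rank!r} has < 2 profiles; excluded", stacklevel=2
            )
            continue
        out[rank] = profile_distances(profiles)
    return out


def rank_distance_medians(
    distances_by_rank: Mapping[str, np.ndarray],
) -> dict[str, float]:
    return {rank: float(np.median(d)) for rank, d in distances_by_rank.items()}


def relatedness_distance_distribution(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    taxonomy: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Profile distances between species, stratified by relatedness.

    The direct test of "more closely related taxa have more similar
    growth profiles": pairwise Hellinger distances between
    species-level growth profiles, grouped by the taxonomic rank the
    pair shares — pairs within one phylum, one family, one genus, and
    (across donors) one species.  Under phylogenetic signal the
    medians decrease from phylum to species; without signal the
    phylum/family/genus strata are exchangeable.

    Note this is distinct from :func:`rank_distance_distribution`,
    which compares profiles *aggregated* at each rank: aggregation
    averages many taxa into smooth, mutually similar profiles, so its
    medians are dominated by the smoothing itself rather than by
    relatedness.

    The species stratum compares the same taxon's profile between
    donor pairs (taxa absent in either donor are skipped), so it
    reflects within-species reproducibility across communities.
    """
    mean_profiles = build_profiles(table, metadata, taxonomy, "species")
    transformed = np.sqrt(
        mean_profiles.to_numpy(dtype=float)
        / mean_profiles.sum(axis=1).to_numpy()[:, None]
    )
    frame = pd.DataFrame(transformed, index=mean_profiles.index)

    out: dict[str, np.ndarray] = {}
    for rank in ("phylum", "family", "genus"):
        dists: list[float] = []
        for _, members in taxonomy.groupby(rank).groups.items():
            present = [m for m in members if m in frame.index]
            if len(present) < 2:
                continue
            arr = frame.loc[present].to_numpy()
            dists.extend(pdist(arr, metric="euclidean"))
        if len(dists) < 1:
            warnings.warn(f"no within-{rank} pairs; stratum excluded", stacklevel=2)
            continue
        out[rank] = np.asarray(dists)

    donor_profiles = build_profiles(table, metadata, taxonomy, "species", per_donor=True)
    donors = sorted({c.split("|")[0] for c in donor_profiles.columns})
    dists = []
    for i, a in enumerate(donors):
        cols_a = [c for c in donor_profiles.columns if c.startswith(a + "|")]
        pa = donor_profiles[cols_a]
        pa = pa.set_axis([c.split("|", 1)[1] for c in cols_a], axis=1)
        for b in donors[i + 1:]:
            cols_b = [c for c in donor_profiles.columns if c.startswith(b + "|")]
            pb = donor_profiles[cols_b]
            pb = pb.set_axis([c.split("|", 1)[1] for c in cols_b], axis=1)
            mods = sorted(set(pa.columns) & set(pb.columns))
            shared = pa.index[(pa[mods].sum(axis=1) > 0)].intersection(
                pb.index[(pb[mods].sum(axis=1) > 0)]
            )
            if len(shared) == 0:
                continue
            ta = np.sqrt(
                pa.loc[shared, mods].to_numpy()
                / pa.loc[shared, mods].sum(axis=1).to_numpy()[:, None]
            )
            tb = np.sqrt(
                pb.loc[shared, mods].to_numpy()
                / pb.loc[shared, mods].sum(axis=1).to_numpy()[:, None]
            )
            dists.extend(np.linalg.norm(ta - tb, axis=1).tolist())
    if dists:
        out["species"] = np.asarray(dists)
    return out


def media_per_motu(
    presence: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Modifications sustaining growth per (donor, feature).

    Returns the donor x feature count matrix (distinct modifications
    where the feature is detected) and, per donor, the number of
    features detected in exactly one modification.
    """
    culture = metadata[metadata["sample_type"] == "culture"]
    if culture.empty:
        raise UsageError("no culture samples in metadata")
    sub = presence.loc[culture.index]
    donors = sorted(culture["donor_id"].unique())
    counts = pd.DataFrame(0, index=donors, columns=presence.columns)
    for donor in donors:
        rows = culture.index[culture["donor_id"] == donor]
        per_mod = (
            sub.loc[rows]
            .groupby(culture.loc[rows, "modification_id"])
            .any()
        )
        counts.loc[donor] = per_mod.sum(axis=0).astype(int)
    counts.index.name = "donor_id"
    singletons = (counts == 1).sum(axis=1)
    singletons.name = "features_in_exactly_one_modification"
    return counts, singletons
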