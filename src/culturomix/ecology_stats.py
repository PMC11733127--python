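"""Ordination, permutation tests, variance ratios and clustering.

The permutation machinery (Mantel, PERMANOVA, PERMDISP) is implemented
here rather than delegated so that every test shares one seeded RNG
protocol, the exact Monte-Carlo p estimator (exceedances+1)/(perms+1),
and an exhaustive-enumeration mode for small n.  Established
implementations (scikit-bio) are used as independent cross-checks in
the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .errors import DataValueError, UsageError
from .tables_io import AbundanceTable
from .diversity import _hellinger_matrix

DEFAULT_PERMUTATIONS = 999


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a seeded permutation test.

    Monte-Carlo p-values use (exceedances + 1) / (permutations + 1)
    and are therefore never zero; exhaustive mode reports the exact
    tail probability over the full enumeration (identity included).
    """

    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise DataValueError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pca_hellinger(table: AbundanceTable) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of Hellinger-transformed compositions.

    Rows are square-root transformed after closure, columns centered,
    then decomposed by SVD.  Returns (coordinates, explained-variance
    ratios); ratios are non-increasing and sum to <= 1.  Euclidean
    distances between full-rank coordinates equal the pairwise
    Hellinger distances.
    """
    if table.mode == "counts":
        raise UsageError("pca_hellinger requires fractions; close first")
    if table.shape[0] < 3:
        raise UsageError("PCA needs at least 3 samples")
    sums = table.values().sum(axis=1)
    if (sums == 0).any():
        raise UsageError("all-zero samples cannot be ordinated; drop them first")
    from sklearn.decomposition import PCA

    transformed = _hellinger_matrix(table.data)
    n_comp = min(transformed.shape[0] - 1, transformed.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(transformed)
    frame = pd.DataFrame(
        coords,
        index=table.data.index,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    return frame, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return squareform(dm.data, checks=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise DataValueError("zero-variance distance vector in Mantel test")
    return float((xc * yc).sum() / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int | str = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided Mantel test (Pearson r over upper-triangle entries).

    Matrices are aligned by label.  Significance comes from jointly
    permuting rows and columns of the second matrix; pass
    ``n_permutations="exact"`` to enumerate all n! relabelings
    (feasible for n <= 8).
    """
    if set(d1.ids) != set(d2.ids):
        raise UsageError("distance matrices must share the same labels")
    n = len(d1.ids)
    if n < 3:
        raise UsageError("Mantel test needs at least 3 objects")
    m2 = d2.filter(d1.ids).data  # align label order
    m1 = d1.data
    x = squareform(m1, checks=False)
    r_obs = _pearson(x, squareform(m2, checks=False))

    if n_permutations == "exact":
        exceed = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.asarray(perm)
            r = _pearson(x, squareform(m2[np.ix_(perm, perm)], checks=False))
            exceed += abs(r) >= abs(r_obs) - 1e-12
            total += 1
        return PermutationResult(r_obs, exceed / total, total, seed, "mantel-exact")

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(n)
        r = _pearson(x, squareform(m2[np.ix_(perm, perm)], checks=False))
        exceed += abs(r) >= abs(r_obs) - 1e-12
    p = (exceed + 1) / (int(n_permutations) + 1)
    return PermutationResult(r_obs, p, int(n_permutations), seed, "mantel")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within == 0:
        return math.inf
    return (ss_among / df_among) / (ss_within / df_within)


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(list(groups)))
    return codes.astype(np.int64), len(uniques)


def _distinct_relabelings(codes: np.ndarray):
    """All distinct label assignments (multiset permutations)."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm, dtype=np.int64)


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int | str = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F is built from sums of squared distances: SS_T = (1/N)
    sum_{i<j} d_ij^2, SS_W summed per group with the group-size
    divisor, SS_A = SS_T - SS_W.  Significance by permuting group
    labels; ``"exact"`` enumerates every distinct labeling.
    """
    codes, n_groups = _group_codes(groups)
    n = len(codes)
    if n != dm.shape[0]:
        raise UsageError("group labels must match distance-matrix size")
    if n_groups < 2:
        raise UsageError("PERMANOVA needs at least 2 groups")
    if n <= n_groups:
        raise UsageError("PERMANOVA needs more samples than groups")
    d2 = dm.data**2
    f_obs = _permanova_f(d2, codes, n_groups)

    if n_permutations == "exact":
        exceed = 0
        total = 0
        for perm in _distinct_relabelings(codes):
            f = _permanova_f(d2, perm, n_groups)
            exceed += f >= f_obs - 1e-12
            total += 1
        return PermutationResult(
            f_obs, exceed / total, total, seed, "permanova-exact"
        )

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        f = _permanova_f(d2, rng.permutation(codes), n_groups)
        exceed += f >= f_obs - 1e-12
    p = (exceed + 1) / (int(n_permutations) + 1)
    return PermutationResult(f_obs, p, int(n_permutations), seed, "permanova")


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _pcoa_coords(dm: DistanceMatrix) -> np.ndarray:
    """Principal-coordinate embedding; negative eigenvalues truncated."""
    d2 = dm.data**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > max(1e-10, 1e-10 * abs(eigvals).max())
    return eigvecs[:, keep] * np.sqrt(eigvals[keep])


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        sub = values[codes == g]
        ssb += len(sub) * (sub.mean() - grand) ** 2
        ssw += ((sub - sub.mean()) ** 2).sum()
    if ssw == 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def permdisp(
    dm: DistanceMatrix,
    groups,
    n_permutations: int | str = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermutationResult:
    """Homogeneity of multivariate dispersions (distance to centroid).

    Samples are embedded by PCoA (negative eigenvalue axes dropped),
    each sample's Euclidean distance to its group centroid is
    computed once, and the one-way ANOVA F on those distances is
    permuted over group labels.  Singleton groups contribute a zero
    centroid distance.
    """
    codes, n_groups = _group_codes(groups)
    n = len(codes)
    if n != dm.shape[0]:
        raise UsageError("group labels must match distance-matrix size")
    if n_groups < 2:
        raise UsageError("PERMDISP needs at least 2 groups")
    if n <= n_groups:
        raise UsageError("PERMDISP needs more samples than groups")
    coords = _pcoa_coords(dm)
    dists = np.empty(n)
    for g in range(n_groups):
        idx = codes == g
        centroid = coords[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    f_obs = _anova_f(dists, codes, n_groups)

    if n_permutations == "exact":
        exceed = 0
        total = 0
        for perm in _distinct_relabelings(codes):
            exceed += _anova_f(dists, perm, n_groups) >= f_obs - 1e-12
            total += 1
        return PermutationResult(
            f_obs, exceed / total, total, seed, "permdisp-exact"
        )

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        exceed += _anova_f(dists, rng.permutation(codes), n_groups) >= f_obs - 1e-12
    p = (exceed + 1) / (int(n_permutations) + 1)
    return PermutationResult(f_obs, p, int(n_permutations), seed, "permdisp")


# ---------------------------------------------------------------------------
# variance ratio
# ---------------------------------------------------------------------------

def variance_ratio(table: AbundanceTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Within-donor vs. between-modification variance, per modification.

    W_m sums, over features, the unbiased variance of abundances
    across donors at modification m.  B sums, over features, the
    variance across modifications of the donor-mean profile.  The
    ratio W_m / B is small when a modification pushes all donors to a
    similar composition relative to how much modifications differ
    from each other.  B = 0 flags all ratios undefined (NaN).
    """
    culture = metadata[metadata["sample_type"] == "culture"]
    mods = sorted(culture["modification_id"].unique())
    donors = sorted(culture["donor_id"].unique())
    if len(donors) < 2 or len(mods) < 2:
        raise UsageError("variance_ratio needs >= 2 donors and >= 2 modifications")
    # (donor, modification) -> sample row; exactly one sample expected
    cube = np.full((len(donors), len(mods), table.shape[1]), np.nan)
    for di, donor in enumerate(donors):
        for mi, mod in enumerate(mods):
            sel = culture.index[
                (culture["donor_id"] == donor)
                & (culture["modification_id"] == mod)
            ]
            if len(sel) != 1:
                raise UsageError(
                    f"expected exactly one sample for (donor={donor}, "
                    f"modification={mod}); found {len(sel)}"
                )
            cube[di, mi] = table.data.loc[sel[0]].to_numpy(dtype=float)
    within = cube.var(axis=0, ddof=1).sum(axis=1)  # per modification
    donor_mean = cube.mean(axis=0)  # modifications x features
    between = donor_mean.var(axis=0, ddof=1).sum()
    result = pd.DataFrame(
        {
            "within_donor_variance": within,
            "between_modification_variance": between,
            "ratio": within / between if between > 0 else np.nan,
        },
        index=pd.Index(mods, name="modification_id"),
    )
    result["undefined"] = between == 0
    return result


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class DendrogramResult:
    """UPGMA merge tree with its cophenetic fit to the input distances."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]  # lexicographically sorted leaf order
    cophenetic_correlation: float

    def cophenetic_matrix(self) -> DistanceMatrix:
        coph = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(squareform(coph), ids=self.labels)

    def to_newick(self) -> str:
        """Serialize the dendrogram with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        inner = walk(tree, tree.dist)
        # strip the root's zero-length suffix
        return f"{inner.rsplit(':', 1)[0]};"


def average_linkage_cluster(dm: DistanceMatrix) -> DendrogramResult:
    """UPGMA clustering with cophenetic correlation.

    Labels are sorted lexicographically before clustering so merge
    order (and hence tie-breaking) is deterministic.
    """
    if dm.shape[0] < 3:
        raise UsageError("clustering needs at least 3 objects")
    labels = sorted(dm.ids)
    data = dm.filter(labels).data
    condensed = squareform(data, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    coph_corr, _ = hierarchy.cophenet(linkage, condensed)
    return DendrogramResult(
        linkage=linkage,
        labels=labels,
        cophenetic_correlation=float(coph_corr),
    )
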