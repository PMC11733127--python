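"""Ordination, Mantel/PERMANOVA/PERMDISP, variance ratios, UPGMA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, pearsonr
from skbio import DistanceMatrix

import culturomix as cx
from culturomix.errors import DataValueError, UsageError
from culturomix.ecology_stats import _pcoa_coords


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = ids or [f"o{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestPcaHellinger:
    def test_duplicated_samples_identical_coordinates(self):
        frame = pd.DataFrame(
            [[0.2, 0.8], [0.2, 0.8], [0.7, 0.3], [0.5, 0.5]],
            index=list("wxyz"), columns=list("ab"),
        )
        coords, _ = cx.pca_hellinger(cx.AbundanceTable(frame, mode="fraction"))
        np.testing.assert_allclose(coords.loc["w"], coords.loc["x"], atol=1e-12)

    def test_explained_variance_sorted_and_bounded(self, small_fractions):
        _, evr = cx.pca_hellinger(small_fractions)
        assert all(b <= a + 1e-12 for a, b in zip(evr, evr[1:]))
        assert evr.sum() <= 1 + 1e-9

    def test_full_rank_coordinates_preserve_hellinger_distances(self):
        rng = np.random.default_rng(12)
        values = rng.random((6, 4))
        values /= values.sum(axis=1, keepdims=True)
        frame = pd.DataFrame(
            values, index=[f"s{i}" for i in range(6)], columns=list("abcd")
        )
        table = cx.AbundanceTable(frame, mode="fraction")
        coords, _ = cx.pca_hellinger(table)
        dm = cx.pairwise_hellinger(table)
        np.testing.assert_allclose(
            squareform(pdist(coords.to_numpy())), dm.data, atol=1e-9
        )

    def test_too_few_samples_rejected(self):
        frame = pd.DataFrame(
            [[0.5, 0.5], [0.1, 0.9]], index=["s1", "s2"], columns=list("ab")
        )
        with pytest.raises(UsageError):
            cx.pca_hellinger(cx.AbundanceTable(frame, mode="fraction"))


class TestMantel:
    def _random_dm(self, seed, n=6):
        rng = np.random.default_rng(seed)
        return euclidean_dm(rng.random((n, 3)))

    def test_identical_matrices_r_one(self):
        dm = self._random_dm(0)
        result = cx.mantel(dm, dm, n_permutations=99, seed=1)
        assert result.statistic == pytest.approx(1.0)

    def test_anticorrelated_matrices_r_minus_one(self):
        dm = self._random_dm(1)
        flipped = dm.data.max() - dm.data
        np.fill_diagonal(flipped, 0.0)
        d2 = DistanceMatrix((flipped + flipped.T) / 2, ids=dm.ids)
        result = cx.mantel(dm, d2, n_permutations=99, seed=1)
        assert result.statistic == pytest.approx(-1.0)

    def test_exact_p_matches_full_enumeration_at_n4(self):
        """Independent oracle: enumerate all 24 relabelings directly."""
        rng = np.random.default_rng(7)
        d1 = euclidean_dm(rng.random((4, 2)))
        d2 = euclidean_dm(rng.random((4, 2)), ids=list(d1.ids))
        result = cx.mantel(d1, d2, n_permutations="exact")
        x = squareform(d1.data, checks=False)
        r_obs = pearsonr(x, squareform(d2.data, checks=False)).statistic
        exceed = 0
        for perm in itertools.permutations(range(4)):
            perm = np.asarray(perm)
            permuted = d2.data[np.ix_(perm, perm)]
            r = pearsonr(x, squareform(permuted, checks=False)).statistic
            exceed += abs(r) >= abs(r_obs) - 1e-12
        assert result.n_permutations == 24
        assert result.p_value == pytest.approx(exceed / 24)
        assert result.statistic == pytest.approx(r_obs)

    def test_invariant_to_simultaneous_relabeling(self):
        d1 = self._random_dm(3)
        d2 = self._random_dm(4)
        base = cx.mantel(d1, d2, n_permutations=99, seed=5)
        perm = np.random.default_rng(0).permutation(len(d1.ids))
        ids = [d1.ids[i] for i in perm]
        d1p = d1.filter(ids)
        d2p = d2.filter(ids)
        shuffled = cx.mantel(d1p, d2p, n_permutations=99, seed=5)
        assert shuffled.statistic == pytest.approx(base.statistic)

    def test_agrees_with_reference_library_statistic(self):
        from skbio.stats.distance import mantel as skbio_mantel

        d1 = self._random_dm(8)
        d2 = self._random_dm(9)
        d2 = DistanceMatrix(d2.data, ids=list(d1.ids))
        expected = skbio_mantel(d1, d2, permutations=0)
        result = cx.mantel(d1, d2, n_permutations=9, seed=0)
        assert result.statistic == pytest.approx(float(expected[0]))

    def test_label_mismatch_rejected(self):
        d1 = self._random_dm(0)
        d2 = euclidean_dm(np.random.default_rng(1).random((6, 2)),
                          ids=[f"x{i}" for i in range(6)])
        with pytest.raises(UsageError):
            cx.mantel(d1, d2)

    def test_zero_variance_rejected(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(DataValueError):
            cx.mantel(dm, dm, n_permutations=9)


class TestPermanova:
    def test_univariate_toy_equals_classic_anova_f(self):
        """{0, 0.1} vs {1, 1.1} gives pseudo-F = classic F = 200."""
        values = np.array([0.0, 0.1, 1.0, 1.1])
        groups = ["a", "a", "b", "b"]
        result = cx.permanova(euclidean_dm(values), groups, n_permutations=99, seed=0)
        classic = f_oneway(values[:2], values[2:]).statistic
        assert result.statistic == pytest.approx(200.0, rel=1e-9)
        assert result.statistic == pytest.approx(classic, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_anova_f_on_random_univariate_data(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = int(rng.integers(2, 4))
        sizes = rng.integers(2, 6, size=n_groups)
        values = rng.normal(size=sizes.sum())
        groups = np.repeat([f"g{i}" for i in range(n_groups)], sizes)
        result = cx.permanova(euclidean_dm(values), groups, n_permutations=9, seed=0)
        chunks = [values[groups == g] for g in np.unique(groups)]
        assert result.statistic == pytest.approx(
            f_oneway(*chunks).statistic, rel=1e-9
        )

    def test_no_between_group_signal_gives_f_zero(self):
        values = np.array([0.0, 1.0, 0.0, 1.0])
        groups = ["a", "a", "b", "b"]
        result = cx.permanova(euclidean_dm(values), groups, n_permutations=19, seed=0)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_exact_p_matches_enumeration_of_label_splits(self):
        """n=6, two groups of 3: all 20 distinct splits enumerated."""
        rng = np.random.default_rng(5)
        values = rng.normal(size=6)
        groups = ["a"] * 3 + ["b"] * 3
        result = cx.permanova(euclidean_dm(values), groups, n_permutations="exact")
        assert result.n_permutations == 20

        def pseudo_f(labels):
            chunks = [values[np.asarray(labels) == g] for g in ("a", "b")]
            return f_oneway(*chunks).statistic

        f_obs = pseudo_f(groups)
        distinct = {p for p in itertools.permutations(groups)}
        exceed = sum(pseudo_f(list(p)) >= f_obs - 1e-12 for p in distinct)
        assert result.p_value == pytest.approx(exceed / len(distinct))

    def test_agrees_with_reference_library(self, small_fractions, small_experiment):
        from skbio.stats.distance import permanova as skbio_permanova

        dm = cx.pairwise_hellinger(small_fractions)
        donors = small_experiment.metadata.loc[list(dm.ids), "donor_id"]
        ours = cx.permanova(dm, donors, n_permutations=99, seed=0)
        theirs = skbio_permanova(dm, donors.to_numpy(), permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_single_group_rejected(self):
        dm = euclidean_dm([0.0, 1.0, 2.0])
        with pytest.raises(UsageError):
            cx.permanova(dm, ["a", "a", "a"])


class TestPermdisp:
    def test_mirror_image_groups_f_near_zero(self):
        points = np.array(
            [[1.0, 0.0], [2.0, 1.0], [3.0, -1.0],
             [-1.0, 0.0], [-2.0, 1.0], [-3.0, -1.0]]
        )
        groups = ["a"] * 3 + ["b"] * 3
        result = cx.permdisp(euclidean_dm(points), groups, n_permutations=99, seed=0)
        assert result.statistic == pytest.approx(0.0, abs=1e-9)

    def test_tight_vs_dispersed_cluster_detected(self):
        rng = np.random.default_rng(3)
        tight = rng.normal(0, 0.1, size=(10, 2))
        loose = rng.normal(5, 1.0, size=(10, 2))
        groups = ["tight"] * 10 + ["loose"] * 10
        result = cx.permdisp(
            euclidean_dm(np.vstack([tight, loose])), groups,
            n_permutations=999, seed=1,
        )
        assert result.statistic > 10
        assert result.p_value < 0.05

    def test_singleton_group_handled(self):
        points = np.array([[0.0], [1.0], [5.0], [6.0]])
        groups = ["a", "a", "a", "b"]
        result = cx.permdisp(euclidean_dm(points), groups, n_permutations=19, seed=0)
        assert math.isfinite(result.statistic) or result.statistic == math.inf

    def test_agrees_with_reference_library_statistic(self):
        from skbio.stats.distance import permdisp as skbio_permdisp

        rng = np.random.default_rng(17)
        points = rng.normal(size=(9, 3))
        groups = np.array(["a"] * 4 + ["b"] * 5)
        dm = euclidean_dm(points)
        ours = cx.permdisp(dm, groups, n_permutations=9, seed=0)
        theirs = skbio_permdisp(
            dm, groups, permutations=9, test="centroid",
            number_of_dimensions=8,
        )
        assert ours.statistic == pytest.approx(
            theirs["test statistic"], rel=1e-6
        )


class TestPermutationPValues:
    def test_monte_carlo_p_never_zero(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 5), rng.normal(50, 1, 5)])
        groups = ["a"] * 5 + ["b"] * 5
        result = cx.permanova(euclidean_dm(values), groups,
                              n_permutations=99, seed=0)
        # the complement labeling reproduces the same partition, so a
        # permutation can tie the observed F; p stays small but never 0
        assert 0 < result.p_value <= 0.05


class TestVarianceRatio:
    def _build(self, cube, donors, mods, genera):
        rows, meta = {}, {}
        for di, d in enumerate(donors):
            for mi, m in enumerate(mods):
                sid = f"{d}.{m}"
                rows[sid] = cube[di][mi]
                meta[sid] = {"donor_id": d, "modification_id": m,
                             "sample_type": "culture"}
        table = cx.AbundanceTable(
            pd.DataFrame.from_dict(rows, orient="index", columns=genera),
            mode="functional",
        )
        return table, pd.DataFrame.from_dict(meta, orient="index")

    def test_identical_donors_ratio_zero(self):
        cube = [[[0.2, 0.8], [0.5, 0.5]]] * 3  # 3 donors, same everywhere
        table, meta = self._build(cube, ["D1", "D2", "D3"], ["M1", "M2"], ["g1", "g2"])
        result = cx.variance_ratio(table, meta)
        np.testing.assert_allclose(result["ratio"], 0.0, atol=1e-12)

    def test_identical_modifications_flags_undefined(self):
        cube = [[[0.2, 0.8]] * 2, [[0.6, 0.4]] * 2]  # donors differ, mods same
        table, meta = self._build(cube, ["D1", "D2"], ["M1", "M2"], ["g1", "g2"])
        result = cx.variance_ratio(table, meta)
        assert result["undefined"].all()
        assert result["ratio"].isna().all()

    def test_toy_case_matches_hand_computation(self):
        # 3 donors x 3 modifications x 2 genera, spreadsheet-style oracle
        rng = np.random.default_rng(42)
        cube = rng.random((3, 3, 2))
        donors, mods, genera = ["D1", "D2", "D3"], ["M1", "M2", "M3"], ["g1", "g2"]
        table, meta = self._build(cube.tolist(), donors, mods, genera)
        result = cx.variance_ratio(table, meta)
        arr = cube
        for mi, mod in enumerate(mods):
            w = sum(np.var(arr[:, mi, g], ddof=1) for g in range(2))
            donor_mean = arr.mean(axis=0)
            b = sum(np.var(donor_mean[:, g], ddof=1) for g in range(2))
            assert result.loc[mod, "within_donor_variance"] == pytest.approx(w)
            assert result.loc[mod, "ratio"] == pytest.approx(w / b)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        cube = rng.random((3, 3, 2))
        table, meta = self._build(
            cube.tolist(), ["D1", "D2", "D3"], ["M1", "M2", "M3"], ["g1", "g2"]
        )
        scaled, _ = self._build(
            (cube * 7.5).tolist(), ["D1", "D2", "D3"], ["M1", "M2", "M3"],
            ["g1", "g2"],
        )
        np.testing.assert_allclose(
            cx.variance_ratio(table, meta)["ratio"],
            cx.variance_ratio(scaled, meta)["ratio"],
        )


class TestAverageLinkage:
    def test_hand_traced_three_point_case(self):
        data = np.array(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float
        )
        dm = DistanceMatrix(data, ids=["A", "B", "C"])
        result = cx.average_linkage_cluster(dm)
        # first merge is {A,B} at height 1; C joins at mean distance 10
        assert result.linkage[0, 2] == pytest.approx(1.0)
        coph = result.cophenetic_matrix()
        assert coph["A", "C"] == pytest.approx(10.0)

    def test_ultrametric_input_perfect_cophenetic_fit(self):
        # distances generated from a tree are exactly reproduced
        data = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
            dtype=float,
        )
        dm = DistanceMatrix(data, ids=list("abcd"))
        result = cx.average_linkage_cluster(dm)
        assert result.cophenetic_correlation == pytest.approx(1.0)

    def test_cophenetic_matrix_reproduces_merge_heights(self):
        rng = np.random.default_rng(4)
        points = rng.random((6, 3))
        dm = euclidean_dm(points)
        result = cx.average_linkage_cluster(dm)
        coph = result.cophenetic_matrix()
        from scipy.cluster.hierarchy import fcluster

        # brute force: the cophenetic distance of a pair equals the
        # smallest merge height at which they share a cluster
        for i, a in enumerate(result.labels):
            for b in result.labels[i + 1:]:
                expected = min(
                    h for h in result.linkage[:, 2]
                    if fcluster(result.linkage, h, criterion="distance")[
                        result.labels.index(a)
                    ]
                    == fcluster(result.linkage, h, criterion="distance")[
                        result.labels.index(b)
                    ]
                )
                assert coph[a, b] == pytest.approx(expected)

    def test_newick_export_roundtrips_leaf_set(self):
        dm = euclidean_dm(np.random.default_rng(1).random((5, 2)),
                          ids=list("edcba"))
        result = cx.average_linkage_cluster(dm)
        tree = cx.tables_io.parse_newick(result.to_newick())
        assert sorted(t.name for t in tree.tips()) == sorted(dm.ids)


class TestPcoa:
    def test_embedding_preserves_euclidean_distances(self):
        rng = np.random.default_rng(2)
        points = rng.random((7, 3))
        coords = _pcoa_coords(euclidean_dm(points))
        np.testing.assert_allclose(
            squareform(pdist(coords)), squareform(pdist(points)), atol=1e-8
        )
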