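"""Mantel test, group permutation test, classical MDS, convergence fit."""

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from cbdist import (
    DistanceMatrix,
    classical_mds,
    fit_convergence_curve,
    group_permutation_test,
    mantel_test,
)
from cbdist.stats import group_exhaustive_p, mantel_exhaustive_p


def random_distance_matrix(n, seed, labels=None):
    """A symmetric zero-diagonal matrix of i.i.d. uniform distances."""
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    values[i, j] = rng.uniform(0.05, 1.0, size=i.size)
    values += values.T
    return DistanceMatrix(labels or [f"s{k}" for k in range(n)], values)


def euclidean_matrix(points, labels=None):
    points = np.asarray(points, dtype=float)
    return DistanceMatrix(
        labels or [f"p{k}" for k in range(len(points))],
        squareform(pdist(points)),
    )


def two_community_matrix(n=10, within=0.2, between=0.9, noise=0.02, seed=0,
                         split=None):
    # an unequal split avoids the group-swap symmetry of a 50/50 design,
    # which would inflate the tie count in the permutation null
    rng = np.random.default_rng(seed)
    half = split if split is not None else (n + 1) // 2 + 1
    groups = {f"s{k}": ("g1" if k < half else "g2") for k in range(n)}
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within if (i < half) == (j < half) else between
            values[i, j] = values[j, i] = base + rng.uniform(-noise, noise)
    return DistanceMatrix(list(groups), values), groups


class TestMantel:
    def test_self_comparison_r_is_one(self):
        a = random_distance_matrix(8, seed=1)
        res = mantel_test(a, a, replicates=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.permutation.p_value <= 0.05

    def test_scale_invariance(self):
        a = random_distance_matrix(8, seed=2)
        doubled = DistanceMatrix(list(a.labels), 2.0 * a.values)
        assert mantel_test(a, doubled, replicates=9, seed=0).r == pytest.approx(1.0)

    def test_label_alignment_not_order(self):
        a = random_distance_matrix(6, seed=3)
        perm = [3, 1, 5, 0, 2, 4]
        shuffled = DistanceMatrix(
            [a.labels[i] for i in perm], a.values[np.ix_(perm, perm)]
        )
        assert mantel_test(a, shuffled, replicates=9, seed=0).r == pytest.approx(1.0)

    def test_sampled_p_matches_exhaustive_enumeration_at_n4(self):
        a = random_distance_matrix(4, seed=4)
        b = random_distance_matrix(4, seed=5)
        exact = mantel_exhaustive_p(a, b)
        sampled = mantel_test(a, b, replicates=2000, seed=6).permutation.p_value
        # binomial Monte-Carlo error at 2000 replicates
        assert sampled == pytest.approx(exact, abs=4 * np.sqrt(exact * (1 - exact) / 2000))

    def test_r_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        a = random_distance_matrix(7, seed=7)
        b = random_distance_matrix(7, seed=8)
        r_ours = mantel_test(a, b, replicates=9, seed=0).r
        r_ref, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a.values, a.labels),
            skbio_distance.DistanceMatrix(b.values, b.labels),
            method="pearson", permutations=0,
        )
        assert r_ours == pytest.approx(float(r_ref), abs=1e-12)

    def test_seed_reproducibility(self):
        a = random_distance_matrix(6, seed=9)
        b = random_distance_matrix(6, seed=10)
        r1 = mantel_test(a, b, replicates=99, seed=11)
        r2 = mantel_test(a, b, replicates=99, seed=11)
        assert r1.permutation.p_value == r2.permutation.p_value
        assert np.array_equal(r1.permutation.null_values,
                              r2.permutation.null_values)
        assert r1.permutation.p_value >= 1 / 100

    def test_label_mismatch_rejected(self):
        a = random_distance_matrix(5, seed=12)
        b = random_distance_matrix(5, seed=13,
                                   labels=[f"t{k}" for k in range(5)])
        with pytest.raises(ValueError, match="label"):
            mantel_test(a, b, replicates=9)

    def test_constant_matrix_rejected(self):
        labels = [f"s{k}" for k in range(5)]
        const = DistanceMatrix(labels, 0.5 * (1 - np.eye(5)))
        other = random_distance_matrix(5, seed=14)
        with pytest.raises(ValueError, match="undefined correlation"):
            mantel_test(const, other, replicates=9)


class TestGroupPermutation:
    def test_separated_communities_significant(self):
        dm, groups = two_community_matrix(n=10, seed=0)
        res = group_permutation_test(dm, groups, replicates=1000, seed=1)
        assert res.statistic > 0.5
        assert res.p_value <= 0.01

    def test_sampled_p_matches_exhaustive_enumeration_at_n6(self):
        dm, groups = two_community_matrix(n=6, within=0.3, between=0.6,
                                          noise=0.1, seed=2)
        exact = group_exhaustive_p(dm, groups)
        sampled = group_permutation_test(
            dm, groups, replicates=2000, seed=3
        ).p_value
        assert sampled == pytest.approx(
            exact, abs=4 * np.sqrt(exact * (1 - exact) / 2000) + 1e-3
        )

    def test_degenerate_equal_matrix_statistic_zero(self):
        labels = [f"s{k}" for k in range(6)]
        dm = DistanceMatrix(labels, 0.7 * (1 - np.eye(6)))
        groups = {l: ("g1" if k < 3 else "g2") for k, l in enumerate(labels)}
        res = group_permutation_test(dm, groups, replicates=50, seed=4)
        assert res.statistic == pytest.approx(0.0)
        assert np.allclose(res.null_values, 0.0)
        assert res.p_value == pytest.approx(1.0, abs=0.02)

    def test_missing_group_assignment_rejected(self):
        dm, groups = two_community_matrix(n=6, seed=5)
        del groups["s0"]
        with pytest.raises(ValueError, match="no group assignment"):
            group_permutation_test(dm, groups, replicates=9)

    def test_seed_reproducibility(self):
        dm, groups = two_community_matrix(n=8, seed=6)
        p1 = group_permutation_test(dm, groups, replicates=200, seed=7).p_value
        p2 = group_permutation_test(dm, groups, replicates=200, seed=7).p_value
        assert p1 == p2


class TestClassicalMds:
    def test_unit_square_recovered(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        emb = classical_mds(euclidean_matrix(square), k=2)
        _, _, disparity = procrustes(square, emb.coordinates)
        assert disparity < 1e-8
        assert emb.eigenvalues[0] >= emb.eigenvalues[1]

    def test_full_rank_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(6, 3))
        dm = euclidean_matrix(points)
        emb = classical_mds(dm, k=5)
        reproduced = squareform(pdist(emb.coordinates))
        assert np.allclose(reproduced, dm.values, atol=1e-8)

    def test_known_2d_configuration_recovered(self):
        rng = np.random.default_rng(1)
        points = rng.uniform(size=(10, 2))
        emb = classical_mds(euclidean_matrix(points), k=2)
        _, _, disparity = procrustes(points, emb.coordinates)
        assert disparity < 1e-8

    def test_agrees_with_skbio_pcoa(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        points = rng.normal(size=(8, 2))
        dm = euclidean_matrix(points)
        emb = classical_mds(dm, k=2)
        ref = skbio_ord.pcoa(skbio_distance.DistanceMatrix(dm.values, dm.labels),
                             number_of_dimensions=2)
        _, _, disparity = procrustes(ref.samples.to_numpy(), emb.coordinates)
        assert disparity < 1e-8

    def test_all_zero_distances_collapse_to_origin(self):
        labels = ["a", "b", "c"]
        dm = DistanceMatrix(labels, np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="non-positive"):
            emb = classical_mds(dm, k=2)
        assert np.allclose(emb.coordinates, 0.0)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            classical_mds(dm, k=1)


class TestConvergenceFit:
    def test_exact_parameter_recovery(self):
        depths = np.array([100, 500, 1000, 2000, 4000, 8000])
        y = 0.6 + 0.3 * np.exp(-1e-3 * depths)
        fit = fit_convergence_curve(depths, y)
        assert fit.asymptote == pytest.approx(0.6, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.3, abs=1e-6)
        assert fit.rate == pytest.approx(1e-3, abs=1e-6)
        assert fit.sse < 1e-12

    def test_constant_series(self):
        fit = fit_convergence_curve([100, 200, 400, 800], [0.5] * 4)
        assert fit.asymptote + fit.amplitude * np.exp(-fit.rate * 100) == pytest.approx(0.5, abs=1e-6)
        assert fit.sse < 1e-10

    def test_decreasing_series_gives_positive_rate(self):
        depths = [250, 500, 1000, 2000, 4000]
        y = [0.95, 0.90, 0.84, 0.80, 0.78]
        fit = fit_convergence_curve(depths, y)
        assert fit.rate > 0
        assert fit.amplitude > 0

    def test_invalid_depths_rejected(self):
        with pytest.raises(ValueError):
            fit_convergence_curve([100, 100, 200, 300], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            fit_convergence_curve([100, 200, 300], [1, 2, 3])
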