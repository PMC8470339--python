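import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from commphylo.community import CommunityTable
from commphylo.ordination import (
    OrdinationError,
    pcoa,
    site_distance_matrix,
    variance_explained,
)
from commphylo.synth import SynthConfig, generate_communities, generate_tree
from commphylo.tree import DistanceMatrix, cophenetic
from commphylo.metrics import mntd_between, mpd_between

from conftest import random_tree


def euclidean_dm(points, labels=None):
    labels = labels or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(tuple(labels), squareform(pdist(points)))


class TestSiteDistanceMatrix:
    def make_table(self):
        return CommunityTable(
            ("s1", "s2"),
            ("A", "B", "C", "D"),
            np.array([[1, 1, 0, 0], [0, 0, 1, 1]]),
        )

    def test_cross_clade_entry(self, tree4):
        table = self.make_table()
        for metric in ("mpd", "mntd"):
            dm = site_distance_matrix(tree4, table, metric)
            assert dm.get("s1", "s2") == pytest.approx(4.0)

    def test_identical_sites_mntd_zero(self, tree4):
        table = CommunityTable(
            ("s1", "s2"), ("A", "B"), np.array([[1, 1], [1, 1]])
        )
        dm = site_distance_matrix(tree4, table, "mntd")
        assert dm.get("s1", "s2") == 0.0

    def test_matches_pairwise_metrics(self):
        cfg = SynthConfig(n_tips=40, n_sites=6, richness_range=(3, 10), seed=3)
        tree = generate_tree(cfg)
        table = generate_communities(tree, cfg)
        d = cophenetic(tree)
        dm_mpd = site_distance_matrix(tree, table, "mpd")
        dm_mntd = site_distance_matrix(tree, table, "mntd")
        for i, si in enumerate(table.sites):
            for sj in table.sites[i + 1:]:
                a, b = table.site_species(si), table.site_species(sj)
                assert dm_mpd.get(si, sj) == pytest.approx(mpd_between(d, a, b))
                assert dm_mntd.get(si, sj) == pytest.approx(mntd_between(d, a, b))

    def test_unknown_metric(self, tree4):
        with pytest.raises(OrdinationError):
            site_distance_matrix(tree4, self.make_table(), "unifrac")


class TestPCoA:
    def test_collinear_points_one_axis(self):
        dm = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
        )
        result = pcoa(dm)
        assert result.n_axes == 1
        assert variance_explained(result, 1) == pytest.approx(1.0)

    def test_reconstructs_euclidean_distances(self, rng):
        points = rng.normal(size=(15, 4))
        dm = euclidean_dm(points)
        result = pcoa(dm)
        recon = squareform(pdist(result.coordinates.to_numpy()))
        np.testing.assert_allclose(recon, dm.values, atol=1e-9)

    def test_all_zero_matrix(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        result = pcoa(dm)
        assert result.n_axes == 0
        np.testing.assert_allclose(result.eigenvalues, 0.0, atol=1e-12)

    def test_eigenvalues_non_increasing(self, rng):
        points = rng.normal(size=(10, 3))
        result = pcoa(euclidean_dm(points))
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean: violates the four-point condition strongly
        values = np.array([
            [0.0, 1, 1, 2],
            [1, 0, 2, 1],
            [1, 2, 0, 1],
            [2, 1, 1, 0.0],
        ]) * np.array([[1.0]])
        values[0, 3] = values[3, 0] = 4.0
        dm = DistanceMatrix(("a", "b", "c", "d"), values)
        result = pcoa(dm)
        assert result.eigenvalues.min() < 0

    def test_lingoes_removes_negative_eigenvalues(self):
        values = np.array([
            [0.0, 1, 1, 4],
            [1, 0, 2, 1],
            [1, 2, 0, 1],
            [4, 1, 1, 0.0],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), values)
        result = pcoa(dm, correction="lingoes")
        scale = abs(result.eigenvalues[0])
        assert result.eigenvalues.min() >= -1e-8 * scale

    def test_cailliez_removes_negative_eigenvalues(self):
        values = np.array([
            [0.0, 1, 1, 4],
            [1, 0, 2, 1],
            [1, 2, 0, 1],
            [4, 1, 1, 0.0],
        ])
        dm = DistanceMatrix(("a", "b", "c", "d"), values)
        result = pcoa(dm, correction="cailliez")
        scale = abs(result.eigenvalues[0])
        assert result.eigenvalues.min() >= -1e-8 * scale

    def test_matches_skbio(self, rng):
        import skbio

        points = rng.normal(size=(12, 5))
        dm = euclidean_dm(points)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
        )
        th_eig = np.sort(theirs.eigvals.to_numpy())[::-1]
        k = ours.n_axes
        np.testing.assert_allclose(
            ours.eigenvalues[:k], th_eig[:k], rtol=1e-8, atol=1e-10
        )
        np.testing.assert_allclose(
            ours.proportions,
            np.sort(theirs.proportion_explained.to_numpy())[::-1][:k],
            rtol=1e-8, atol=1e-10,
        )

    def test_site_order_invariance_up_to_sign(self, rng):
        points = rng.normal(size=(9, 3))
        labels = [f"p{i}" for i in range(9)]
        dm = euclidean_dm(points, labels)
        perm = rng.permutation(9)
        dm2 = DistanceMatrix(
            tuple(labels[i] for i in perm), dm.values[np.ix_(perm, perm)]
        )
        r1 = pcoa(dm)
        r2 = pcoa(dm2)
        np.testing.assert_allclose(
            r1.eigenvalues, r2.eigenvalues, rtol=1e-8, atol=1e-10
        )
        c1 = r1.coordinates.loc[labels].to_numpy()
        c2 = r2.coordinates.loc[labels].to_numpy()
        for k in range(min(c1.shape[1], c2.shape[1])):
            match = np.allclose(c1[:, k], c2[:, k], atol=1e-8) or \
                np.allclose(c1[:, k], -c2[:, k], atol=1e-8)
            assert match

    def test_axis_sign_convention(self, rng):
        points = rng.normal(size=(8, 3))
        result = pcoa(euclidean_dm(points))
        coords = result.coordinates.to_numpy()
        for k in range(result.n_axes):
            assert coords[np.argmax(np.abs(coords[:, k])), k] >= 0


class TestVarianceExplained:
    def test_monotone_and_bounded(self, rng):
        cfg = SynthConfig(n_tips=60, n_sites=28, richness_range=(5, 20), seed=8)
        tree = generate_tree(cfg)
        table = generate_communities(tree, cfg)
        result = pcoa(site_distance_matrix(tree, table, "mntd"))
        values = [variance_explained(result, k)
                  for k in range(1, result.n_axes + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] <= 1 + 1e-12

    def test_all_positive_axes_sum_to_one(self, rng):
        points = rng.normal(size=(10, 4))
        result = pcoa(euclidean_dm(points))
        assert variance_explained(result, result.n_axes) == pytest.approx(1.0)

    def test_k_validation(self, rng):
        result = pcoa(euclidean_dm(rng.normal(size=(5, 2))))
        with pytest.raises(OrdinationError):
            variance_explained(result, 0)
        with pytest.raises(OrdinationError):
            variance_explained(result, result.n_axes + 1)
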