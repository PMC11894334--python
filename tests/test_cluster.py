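"""Electrode-map rank-sum tests, adjacency and cluster permutation."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from heartscales import (build_adjacency, electrode_wise_test,
                         exact_two_sided_p, form_clusters,
                         permutation_cluster_test, pick_connected_patch)
from heartscales.io import ConfigError
from heartscales.montage import biosemi_montage


class TestAdjacency:
    def test_default_montage_degree_and_symmetry(self):
        labels, pos = biosemi_montage(128)
        adj = build_adjacency(pos, labels)
        assert np.array_equal(adj.matrix, adj.matrix.T)
        assert not np.diag(adj.matrix).any()
        assert 5.0 <= adj.mean_degree <= 9.0

    def test_antipodal_pair_isolated_with_warning(self):
        pos = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        with pytest.warns(UserWarning):
            adj = build_adjacency(pos, ["a", "b"], radius=0.5)
        assert not adj.matrix.any()

    def test_grid_four_connectivity(self):
        """Small lat-long grid: inner nodes have 4 neighbours at a radius
        between the grid step and its diagonal."""
        step = 0.1
        pts, labels = [], []
        for i in range(5):
            for j in range(5):
                # near the equator, where the lat-long grid is uniform
                th, ph = np.pi / 2 + (i - 2) * step, j * step
                pts.append([np.sin(th) * np.cos(ph),
                            np.sin(th) * np.sin(ph), np.cos(th)])
                labels.append(f"g{i}{j}")
        adj = build_adjacency(np.array(pts), labels, radius=1.25 * step)
        inner = labels.index("g22")
        assert adj.matrix[inner].sum() == 4

    def test_connected_patch_is_connected(self):
        labels, pos = biosemi_montage(64)
        adj = build_adjacency(pos, labels)
        patch = pick_connected_patch(adj, labels[5], 8)
        assert len(patch) == 8
        idx = [adj.labels.index(p) for p in patch]
        sub = adj.matrix[np.ix_(idx, idx)]
        # breadth-first reachability within the patch
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = [j for i in frontier for j in np.where(sub[i])[0]
                   if j not in seen]
            seen.update(nxt)
            frontier = nxt
        assert seen == set(range(8))


class TestElectrodeWiseTest:
    def test_exact_p_against_enumeration_oracle(self):
        """A=[1,2,3] vs B=[4,5,6]: enumerate all 20 assignments directly."""
        pooled = np.array([1, 2, 3, 4, 5, 6], float)
        obs = 1 + 2 + 3
        mu = 3 * 7 / 2.0
        null = [pooled[list(c)].sum() for c in combinations(range(6), 3)]
        p_oracle = np.mean([abs(s - mu) >= abs(obs - mu) for s in null])
        assert p_oracle == pytest.approx(0.100)
        assert exact_two_sided_p([1, 2, 3], [4, 5, 6]) == \
            pytest.approx(p_oracle)

    def test_identical_groups_p_is_maximal(self):
        a = np.tile([[1.0], [2.0], [3.0]], (1, 1))
        _, p = electrode_wise_test(a, a.copy(), method="exact")
        assert p[0] == 1.0

    def test_label_swap_flips_sign_keeps_p(self, rng):
        a, b = rng.normal(size=(8, 5)), rng.normal(size=(9, 5))
        z1, p1 = electrode_wise_test(a, b)
        z2, p2 = electrode_wise_test(b, a)
        assert np.allclose(z1, -z2)
        assert np.allclose(p1, p2)

    def test_exact_and_asymptotic_agree_at_n6_plus_6(self, rng):
        dmax = 0.0
        for _ in range(100):
            a, b = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
            _, pe = electrode_wise_test(a, b, method="exact")
            _, pa = electrode_wise_test(a, b, method="asymptotic")
            dmax = max(dmax, np.abs(pe - pa).max())
        assert dmax <= 0.02

    def test_asymptotic_matches_scipy_mannwhitney(self, rng):
        a, b = rng.normal(size=(15, 6)), rng.normal(size=(14, 6))
        _, p = electrode_wise_test(a, b, method="asymptotic")
        p_ref = np.array([
            stats.mannwhitneyu(a[:, j], b[:, j], method="asymptotic").pvalue
            for j in range(6)])
        assert np.allclose(p, p_ref, atol=1e-9)

    def test_mismatched_electrode_sets_rejected(self, rng):
        with pytest.raises(ConfigError):
            electrode_wise_test(rng.normal(size=(5, 4)),
                                rng.normal(size=(5, 3)))


class TestFormClusters:
    def _line_adjacency(self, n=12):
        # electrodes on an arc: neighbours are index +/-1
        th = np.linspace(0.2, 1.4, n)
        pos = np.stack([np.sin(th), np.zeros(n), np.cos(th)], axis=1)
        return build_adjacency(pos, [f"e{i}" for i in range(n)],
                               radius=1.5 * (th[1] - th[0]))

    def test_no_supra_threshold_electrodes_no_clusters(self):
        adj = self._line_adjacency()
        z = np.ones(12)
        p = np.full(12, 0.5)
        assert form_clusters(z, p, adj) == []

    def test_six_connected_electrodes_form_one_cluster(self):
        adj = self._line_adjacency()
        z = np.zeros(12)
        p = np.ones(12)
        z[3:9] = 3.0
        p[3:9] = 0.001
        clusters = form_clusters(z, p, adj, alpha=0.025, min_size=5)
        assert len(clusters) == 1
        members, mass, sign = clusters[0]
        assert len(members) == 6 and sign == 1
        assert mass == pytest.approx(18.0)

    def test_four_connected_electrodes_below_min_size(self):
        adj = self._line_adjacency()
        z = np.zeros(12)
        p = np.ones(12)
        z[3:7] = 3.0
        p[3:7] = 0.001
        assert form_clusters(z, p, adj, alpha=0.025, min_size=5) == []

    def test_opposite_signs_never_merge(self):
        adj = self._line_adjacency()
        z = np.r_[np.full(6, 3.0), np.full(6, -3.0)]
        p = np.full(12, 0.001)
        clusters = form_clusters(z, p, adj, min_size=5)
        signs = sorted(s for _, _, s in clusters)
        assert signs == [-1, 1]
        assert all(len(m) == 6 for m, _, _ in clusters)


class TestPermutationTest:
    def _setup(self, seed=0, effect=False):
        labels, pos = biosemi_montage(32)
        adj = build_adjacency(pos, labels)
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (12, 32))
        b = rng.normal(0, 1, (12, 32))
        patch = None
        if effect:
            patch = pick_connected_patch(adj, labels[0], 6)
            idx = [labels.index(e) for e in patch]
            a[:, idx] += 3.0
        return a, b, adj, patch

    def test_deterministic_given_seed(self):
        a, b, adj, _ = self._setup(effect=True)
        r1 = permutation_cluster_test(a, b, adj, n_perm=300, seed=5)
        r2 = permutation_cluster_test(a, b, adj, n_perm=300, seed=5)
        assert [c.p_perm for c in r1] == [c.p_perm for c in r2]

    def test_strong_effect_reaches_minimum_attainable_p(self):
        a, b, adj, patch = self._setup(effect=True)
        res = permutation_cluster_test(a, b, adj, n_perm=300, seed=5)
        assert res and res[0].p_perm == pytest.approx(1.0 / 301.0)
        assert set(patch) <= set(res[0].members)

    def test_p_bounded_below_by_permutation_count(self):
        a, b, adj, _ = self._setup(effect=True)
        res = permutation_cluster_test(a, b, adj, n_perm=150, seed=2)
        assert all(c.p_perm >= 1.0 / 151.0 for c in res)

    def test_low_n_perm_warns(self):
        a, b, adj, _ = self._setup(effect=True)
        with pytest.warns(UserWarning):
            permutation_cluster_test(a, b, adj, n_perm=50, seed=1)


def test_scalp_map_plots_without_error(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from heartscales.cluster import plot_scalp_map

    labels, pos = biosemi_montage(32)
    rng = np.random.default_rng(0)
    ax = plot_scalp_map(rng.normal(size=32), pos, highlight=[1, 2, 3],
                        title="demo")
    assert ax is not None
    ax.figure.savefig(tmp_path / "map.png")
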