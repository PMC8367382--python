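"""Embedding, clustering, phenotype assignment and Mann-Whitney DE."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from coreshell.cell_typing import (
    assign_phenotypes, cluster_leiden, differential_expression, embed_umap,
    significance_stars, box_summary, ClusterResult,
)
from coreshell.quantification import PACMatrix


def _pac_from_array(x, normalized=True, columns=None):
    cols = columns or [f"g{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=cols)
    return PACMatrix(values=df, cells=pd.DataFrame(index=df.index),
                     normalized=normalized)


def _blobs(k, n_per, dim=6, sep=5.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, (k, dim))
    x = np.concatenate([c + 0.2 * rng.normal(size=(n_per, dim))
                        for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return x, labels


class TestUMAP:
    def test_separated_blobs_stay_separated_in_embedding(self):
        x, labels = _blobs(2, 40, seed=1)
        coords = embed_umap(_pac_from_array(x), seed=3)
        c0, c1 = coords[labels == 0], coords[labels == 1]
        between = np.linalg.norm(c0.mean(0) - c1.mean(0))
        within = np.mean([np.linalg.norm(c - c.mean(0), axis=1).mean()
                          for c in (c0, c1)])
        assert between > 5 * within

    def test_same_seed_reproduces_coordinates(self):
        x, _ = _blobs(2, 25, seed=2)
        a = embed_umap(_pac_from_array(x), seed=11)
        b = embed_umap(_pac_from_array(x), seed=11)
        np.testing.assert_array_equal(a, b)

    def test_too_few_cells_rejected(self):
        x = np.random.default_rng(0).random((15, 4))
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_umap(_pac_from_array(x), n_neighbors=15)


class TestLeiden:
    def test_five_planted_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        x, labels = _blobs(5, 40, seed=4)
        res = cluster_leiden(_pac_from_array(x), target_k=5, seed=0)
        assert res.n_clusters == 5
        assert adjusted_rand_score(labels, res.labels) >= 0.9

    def test_single_blob_takes_warning_path(self):
        x = 0.1 * np.random.default_rng(5).normal(size=(60, 4))
        with pytest.warns(UserWarning, match="no grid resolution"):
            res = cluster_leiden(_pac_from_array(x), target_k=5,
                                 resolution_grid=np.array([0.01]), seed=0)
        assert res.n_clusters < 5 and res.warnings

    def test_same_seed_and_grid_reproduce_labels(self):
        x, _ = _blobs(3, 30, seed=6)
        a = cluster_leiden(_pac_from_array(x), target_k=3, seed=2)
        b = cluster_leiden(_pac_from_array(x), target_k=3, seed=2)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.resolution == b.resolution

    def test_empty_grid_rejected(self):
        x, _ = _blobs(2, 20, seed=7)
        with pytest.raises(ValueError, match="empty"):
            cluster_leiden(_pac_from_array(x), resolution_grid=np.array([]))

    def test_labels_partition_all_cells(self, default_run):
        res = default_run.clusters
        assert len(res.labels) == default_run.pac_norm.n_cells
        assert set(res.labels) == set(range(res.n_clusters))


class TestPhenotypes:
    def _cluster_result(self, labels):
        labels = np.asarray(labels)
        return ClusterResult(labels=labels, resolution=1.0,
                             n_clusters=labels.max() + 1,
                             cell_index=pd.RangeIndex(len(labels)))

    def test_markers_map_to_their_peak_clusters(self, default_run):
        """The cluster holding most planted core cells is labeled core,
        and likewise for shell and deep L6."""
        from conftest import match_planted_phenotypes

        planted = match_planted_phenotypes(default_run)
        res = default_run.clusters
        assigned = res.phenotypes()
        for pheno in ("core", "shell", "deep_L6"):
            mask = planted == pheno
            majority = assigned[mask].mode()[0]
            assert majority == pheno

    def test_tied_marker_breaks_to_lowest_cluster_id(self):
        pac = _pac_from_array(np.ones((8, 4)), normalized=False,
                              columns=["Synpr", "Nnat", "Ctgf", "Pcp4"])
        clusters = self._cluster_result([0, 0, 1, 1, 2, 2, 3, 3])
        with pytest.warns(UserWarning, match="tied"):
            res = assign_phenotypes(clusters, pac)
        assert res.phenotype_map[0] == "core"
        assert res.phenotype_map[1] == "shell"
        assert res.phenotype_map[2] == "deep_L6"

    def test_three_clusters_leave_cortex_unassigned(self):
        x = np.array([[9, 0, 0, 1], [0, 9, 0, 1], [0, 0, 9, 1]] * 3,
                     dtype=float)
        pac = _pac_from_array(x, normalized=False,
                              columns=["Synpr", "Nnat", "Ctgf", "Pcp4"])
        clusters = self._cluster_result([0, 1, 2] * 3)
        res = assign_phenotypes(clusters, pac)
        assert set(res.phenotype_map.values()) == {"core", "shell", "deep_L6"}

    def test_assignment_invariant_to_cluster_relabeling(self):
        x = np.array([[9, 0, 0, 1], [0, 9, 0, 2], [0, 0, 9, 3],
                      [0, 0, 0, 8], [0, 0, 0, 4]] * 4, dtype=float)
        pac = _pac_from_array(x, normalized=False,
                              columns=["Synpr", "Nnat", "Ctgf", "Pcp4"])
        base = np.array([0, 1, 2, 3, 4] * 4)
        perm = np.array([3, 0, 4, 1, 2])
        res_a = assign_phenotypes(self._cluster_result(base), pac)
        res_b = assign_phenotypes(self._cluster_result(perm[base]), pac)
        pheno_a = res_a.phenotypes()
        pheno_b = res_b.phenotypes()
        pd.testing.assert_series_equal(pheno_a, pheno_b)


class TestDifferentialExpression:
    def test_identical_groups_are_never_significant(self):
        x = np.tile([[1.0, 2.0, 3.0]], (6, 1))
        pac = _pac_from_array(x, normalized=False)
        de = differential_expression(pac, pd.Index([0, 1, 2]),
                                     pd.Index([3, 4, 5]))
        assert (de["p_adj"] == 1.0).all()
        assert (de["stars"] == "ns").all()

    def test_disjoint_ranks_match_full_enumeration(self):
        """(1,2,3) vs (4,5,6): U = 0 and exact two-sided p = 2/20."""
        pac = _pac_from_array(np.array([[1.], [2.], [3.], [4.], [5.], [6.]]),
                              normalized=False, columns=["g"])
        de = differential_expression(pac, pd.Index([0, 1, 2]),
                                     pd.Index([3, 4, 5]))
        assert de.loc["g", "U"] == 0.0
        assert de.loc["g", "p"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_small_sample_p_equals_rank_enumeration_oracle(self, seed):
        """Brute force over all C(6,3) group assignments reproduces the
        exact two-sided Mann-Whitney p-value."""
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, 7.0))   # tie-free
        pac = _pac_from_array(vals[:, None], normalized=False, columns=["g"])
        de = differential_expression(pac, pd.Index([0, 1, 2]),
                                     pd.Index([3, 4, 5]))

        def u_stat(a_idx):
            a = vals[list(a_idx)]
            b = vals[[i for i in range(6) if i not in a_idx]]
            return sum((x > y) for x in a for y in b)

        u_obs = u_stat((0, 1, 2))
        us = [u_stat(c) for c in combinations(range(6), 3)]
        # two-sided: as-or-more-extreme deviation from the null mean (4.5)
        p_exact = np.mean([abs(u - 4.5) >= abs(u_obs - 4.5) for u in us])
        assert de.loc["g", "p"] == pytest.approx(p_exact)

    def test_bonferroni_multiplies_by_genes_tested(self):
        rng = np.random.default_rng(3)
        x = rng.random((12, 11))
        x[:6, 0] += 10.0   # one strongly shifted gene among 11
        pac = _pac_from_array(x, normalized=False)
        de = differential_expression(pac, pd.Index(range(6)),
                                     pd.Index(range(6, 12)))
        np.testing.assert_allclose(de["p_adj"],
                                   np.minimum(1.0, de["p"] * 11))

    def test_star_coding_thresholds(self):
        assert significance_stars(0.5) == "ns"
        assert significance_stars(0.05) == "ns"
        assert significance_stars(0.044) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"

    def test_empty_group_rejected(self):
        pac = _pac_from_array(np.ones((3, 2)), normalized=False)
        with pytest.raises(ValueError):
            differential_expression(pac, pd.Index([]), pd.Index([0, 1]))


def test_box_summary_hinges_and_whiskers():
    x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 100.0])   # one far outlier
    s = box_summary(x)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    assert s["q1"] == q1 and s["median"] == med and s["q3"] == q3
    assert s["whisker_hi"] <= q3 + 1.5 * (q3 - q1)
    assert s["whisker_hi"] == 8.0
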