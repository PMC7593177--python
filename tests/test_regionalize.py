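"""Codebook clustering, k selection, and spatial cleaning of the zone map."""

import logging

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from florizone.grid import GridSpec
from florizone.regionalize import (
    PROV_IMPUTED,
    PROV_ISLAND,
    PROV_OBSERVED,
    PROV_UNASSIGNED,
    UNASSIGNED,
    KSelection,
    ZoneMap,
    apply_island_rule,
    cells_to_zones,
    codebook_distances,
    complete_linkage,
    cut_tree,
    impute_empty_cells,
    relabel_by_area,
    select_k,
    silhouette_mean,
    zone_map_from_csv,
    zone_map_to_csv,
)
from florizone.som import SOMFit, SOMModel
from florizone.synthetic import adjusted_rand_index


def make_zm(labels, grid, provenance=None):
    labels = np.asarray(labels, dtype=int)
    if provenance is None:
        provenance = np.where(labels != UNASSIGNED, PROV_OBSERVED, PROV_UNASSIGNED)
    return ZoneMap(labels=labels, provenance=np.asarray(provenance, dtype=object), grid=grid)


class TestCodebookDistances:
    def test_identical_codebook_all_zero(self):
        m = SOMModel(2, 2, np.ones((4, 3)))
        assert np.array_equal(codebook_distances(m), np.zeros(6))

    def test_two_nodes_single_distance(self):
        m = SOMModel(1, 2, np.array([[0.0, 0.0], [3.0, 4.0]]))
        np.testing.assert_allclose(codebook_distances(m), [5.0])

    def test_nine_nodes_match_double_loop(self):
        rng = np.random.default_rng(0)
        m = SOMModel(3, 3, rng.random((9, 5)))
        d = codebook_distances(m)
        k = 0
        for i in range(9):
            for j in range(i + 1, 9):
                assert d[k] == pytest.approx(
                    np.linalg.norm(m.codebook[i] - m.codebook[j]), abs=1e-12
                )
                k += 1


class TestCompleteLinkage:
    def test_hand_run_three_item_example(self):
        # d(A,B)=1, d(A,C)=5, d(B,C)=4
        dist = np.array([1.0, 5.0, 4.0])
        tree = complete_linkage(dist)
        assert tree.merges[0] == (0, 1, 1.0, 2)
        assert tree.merges[1][2] == 5.0 and tree.merges[1][3] == 3

    def test_equal_distances_give_equal_heights(self):
        dist = np.ones(10)  # 5 items
        tree = complete_linkage(dist)
        assert all(h == 1.0 for _, _, h, _ in tree.merges)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            dist = pdist(rng.random((12, 4)))
            tree = complete_linkage(dist)
            hs = [h for _, _, h, _ in tree.merges]
            assert all(a <= b + 1e-12 for a, b in zip(hs, hs[1:]))

    def test_matches_scipy_heights_and_partitions(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = rng.random((12, 3))
            dist = pdist(pts)
            tree = complete_linkage(dist)
            Z = hierarchy.linkage(dist, method="complete")
            np.testing.assert_allclose(
                [h for _, _, h, _ in tree.merges], Z[:, 2], atol=1e-12
            )
            for k in range(1, 13):
                ours = cut_tree(tree, k)
                theirs = hierarchy.fcluster(Z, t=k, criterion="maxclust")
                assert adjusted_rand_index(ours, theirs) == pytest.approx(1.0)

    def test_fewer_than_two_items_error(self):
        with pytest.raises(ValueError):
            complete_linkage(np.array([]))


class TestCutTree:
    def test_extremes(self):
        tree = complete_linkage(np.array([1.0, 5.0, 4.0]))
        assert cut_tree(tree, 3).tolist() == [1, 2, 3]
        assert cut_tree(tree, 1).tolist() == [1, 1, 1]

    def test_k2_on_hand_example(self):
        tree = complete_linkage(np.array([1.0, 5.0, 4.0]))
        assert cut_tree(tree, 2).tolist() == [1, 1, 2]

    def test_out_of_range(self):
        tree = complete_linkage(np.array([1.0, 5.0, 4.0]))
        for k in (0, 4):
            with pytest.raises(ValueError):
                cut_tree(tree, k)

    def test_labels_numbered_by_first_appearance(self):
        rng = np.random.default_rng(3)
        tree = complete_linkage(pdist(rng.random((10, 2))))
        for k in range(1, 11):
            labels = cut_tree(tree, k)
            seen = []
            for l in labels:
                if l not in seen:
                    seen.append(l)
            assert seen == list(range(1, k + 1))


class TestSilhouette:
    def test_two_separated_identical_clusters_is_one(self):
        pts = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert silhouette_mean(pdist(pts), [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_all_singletons_is_zero(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        assert silhouette_mean(pdist(pts), [1, 2, 3]) == 0.0

    def test_single_cluster_error(self):
        with pytest.raises(ValueError):
            silhouette_mean(pdist(np.random.rand(4, 2)), [1, 1, 1, 1])

    def test_matches_textbook_formula_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            pts = rng.random((30, 3))
            labels = rng.integers(1, 5, size=30)
            if np.unique(labels).size < 2:
                continue
            sq = squareform(pdist(pts))
            expected = []
            for i in range(30):
                own = np.flatnonzero(labels == labels[i])
                if own.size == 1:
                    expected.append(0.0)
                    continue
                a = sq[i, own].sum() / (own.size - 1)
                b = min(
                    sq[i, labels == u].mean() for u in np.unique(labels) if u != labels[i]
                )
                expected.append((b - a) / max(a, b))
            got = silhouette_mean(pdist(pts), labels)
            assert got == pytest.approx(np.mean(expected), abs=1e-12)
            assert -1.0 <= got <= 1.0


class TestSelectK:
    def test_two_blob_codebooks_select_two(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.05, (8, 3)), rng.normal(5, 0.05, (8, 3))])
        dist = pdist(pts)
        sel = select_k(complete_linkage(dist), dist, 2, 8)
        assert sel.k_star == 2

    def test_four_blob_codebooks_select_four(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], dtype=float)
        pts = np.vstack([c + rng.normal(0, 0.1, (6, 2)) for c in centers])
        dist = pdist(pts)
        sel = select_k(complete_linkage(dist), dist, 2, 15)
        assert sel.k_star == 4

    def test_tie_resolves_to_smaller_k(self):
        # symmetric configuration with an exact tie is contrived; assert the
        # rule directly on the selection logic via a duplicated profile
        sel = KSelection(ks=[2, 3, 4], silhouettes=[0.5, 0.7, 0.7], k_star=3)
        assert sel.ks[int(np.argmax(sel.silhouettes))] == 3

    def test_invalid_range(self):
        dist = pdist(np.random.rand(5, 2))
        tree = complete_linkage(dist)
        with pytest.raises(ValueError):
            select_k(tree, dist, 2, 9)


class TestCellsToZones:
    def grid(self, n):
        return GridSpec(x_min=0, y_min=0, cell_w=1, cell_h=1, n_cols=n, n_rows=1)

    def make_fit(self, cell_to_node, n_nodes=4, n_feat=3):
        model = SOMModel(2, n_nodes // 2, np.zeros((n_nodes, n_feat)))
        return SOMFit(model=model, cell_to_node=np.asarray(cell_to_node), qe_history=[])

    def test_single_cluster_all_label_one(self, tiny_pa):
        n_cells = tiny_pa.grid.n_cells
        c2n = np.full(n_cells, -1)
        c2n[tiny_pa.surveyed] = 0
        fit = self.make_fit(c2n, n_nodes=4, n_feat=tiny_pa.n_taxa)
        zm = cells_to_zones(fit, [1, 1, 1, 1], tiny_pa)
        assert (zm.labels[tiny_pa.surveyed] == 1).all()
        assert (zm.labels[~tiny_pa.surveyed] == UNASSIGNED).all()
        assert set(zm.provenance[tiny_pa.surveyed]) == {PROV_OBSERVED}

    def test_cell_inherits_its_bmu_label(self, tiny_pa):
        n_cells = tiny_pa.grid.n_cells
        c2n = np.full(n_cells, -1)
        surveyed_cells = np.flatnonzero(tiny_pa.surveyed)
        c2n[surveyed_cells] = [0, 2, 3]
        node_labels = [1, 1, 2, 3]
        fit = self.make_fit(c2n, n_nodes=4, n_feat=tiny_pa.n_taxa)
        zm = cells_to_zones(fit, node_labels, tiny_pa)
        for cell, node in zip(surveyed_cells, [0, 2, 3]):
            assert zm.labels[cell] == node_labels[node]

    def test_label_count_mismatch_error(self, tiny_pa):
        fit = self.make_fit(np.zeros(tiny_pa.grid.n_cells, int), n_nodes=4,
                            n_feat=tiny_pa.n_taxa)
        with pytest.raises(ValueError):
            cells_to_zones(fit, [1, 2], tiny_pa)


class TestImpute:
    def grid(self, rows, cols):
        return GridSpec(x_min=0, y_min=0, cell_w=1, cell_h=1, n_cols=cols, n_rows=rows)

    def test_majority_neighbor_label(self):
        g = self.grid(3, 3)
        labels = [3, 3, 0, 3, 0, 0, 1, 0, 0]
        zm = impute_empty_cells(make_zm(labels, g))
        assert zm.labels[4] == 3  # neighbors {3,3,3,1}
        assert zm.provenance[4] == PROV_IMPUTED

    def test_tie_goes_to_smallest_label(self):
        g = self.grid(1, 5)
        labels = [1, 1, 0, 3, 3]
        zm = impute_empty_cells(make_zm(labels, g))
        assert zm.labels[2] == 1

    def test_iterated_passes_reach_every_connected_cell(self):
        # a rectangular grid is Moore-connected, so repeated passes sweep
        # labels out from a single assigned seed to every cell
        g = self.grid(1, 5)
        zm = impute_empty_cells(make_zm([1, 0, 0, 0, 0], g))
        assert (zm.labels == 1).all()

    def test_synchronous_passes_use_pass_start_state(self):
        # 1 x 4 strip: [2, 0, 0, 1]; synchronous first pass fills cell 1
        # from {2} and cell 2 from {1} simultaneously
        g = self.grid(1, 4)
        zm = impute_empty_cells(make_zm([2, 0, 0, 1], g))
        assert zm.labels.tolist() == [2, 2, 1, 1]

    def test_observed_cells_never_change_and_growth_monotone(self):
        rng = np.random.default_rng(7)
        g = self.grid(6, 6)
        labels = rng.integers(0, 3, size=36)
        if not (labels > 0).any():
            labels[0] = 1
        zm0 = make_zm(labels, g)
        zm = impute_empty_cells(zm0)
        observed = zm0.labels != UNASSIGNED
        assert np.array_equal(zm.labels[observed], zm0.labels[observed])
        assert (zm.provenance[observed] == PROV_OBSERVED).all()
        assert zm.assigned.sum() >= zm0.assigned.sum()

    def test_no_assigned_cells_error(self):
        g = self.grid(2, 2)
        with pytest.raises(ValueError):
            impute_empty_cells(make_zm([0, 0, 0, 0], g))


class TestIslandRule:
    def grid(self):
        return GridSpec(x_min=0, y_min=0, cell_w=1, cell_h=1, n_cols=6, n_rows=1)

    def test_modal_observed_label_wins(self):
        zm0 = make_zm([4, 4, 3, 1, 1, 1], self.grid())
        zm = apply_island_rule(zm0, {"isl": [0, 1, 2]})
        assert zm.labels[:3].tolist() == [4, 4, 4]
        assert set(zm.provenance[:3]) == {PROV_ISLAND}

    def test_tie_goes_to_smallest(self):
        zm0 = make_zm([4, 3, 4, 3, 1, 1], self.grid())
        zm = apply_island_rule(zm0, {"isl": [0, 1, 2, 3]})
        assert set(zm.labels[:4]) == {3}

    def test_island_without_surveyed_cells_untouched(self, caplog):
        zm0 = make_zm([0, 0, 1, 1, 1, 1], self.grid())
        with caplog.at_level(logging.WARNING, logger="florizone.regionalize"):
            zm = apply_island_rule(zm0, {"isl": [0, 1]})
        assert zm.labels[:2].tolist() == [0, 0]
        assert "no surveyed" in caplog.text

    def test_mainland_never_altered(self):
        zm0 = make_zm([4, 4, 3, 1, 2, 1], self.grid())
        zm = apply_island_rule(zm0, {"isl": [0, 1, 2]})
        assert np.array_equal(zm.labels[3:], zm0.labels[3:])
        assert np.array_equal(zm.provenance[3:], zm0.provenance[3:])

    def test_overlapping_groups_error(self):
        zm0 = make_zm([1, 1, 1, 1, 1, 1], self.grid())
        with pytest.raises(ValueError):
            apply_island_rule(zm0, {"a": [0, 1], "b": [1, 2]})


def test_relabel_by_area_orders_descending():
    g = GridSpec(x_min=0, y_min=0, cell_w=1, cell_h=1, n_cols=6, n_rows=1)
    zm = relabel_by_area(make_zm([7, 7, 7, 2, 2, 9], g))
    assert zm.labels.tolist() == [1, 1, 1, 2, 2, 3]


def test_zone_map_csv_round_trip(tmp_path):
    g = GridSpec(x_min=0, y_min=0, cell_w=1, cell_h=1, n_cols=3, n_rows=2)
    zm = make_zm([1, 2, 0, 1, 0, 2], g)
    zm.provenance[2] = PROV_UNASSIGNED
    zone_map_to_csv(zm, tmp_path / "zm.csv")
    back = zone_map_from_csv(tmp_path / "zm.csv", g)
    assert np.array_equal(back.labels, zm.labels)
    assert np.array_equal(back.provenance, zm.provenance)
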