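"""Neighbor graphs, patch-method permutation scores, distances, neighborhoods."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

import stromascope as st
from stromascope.core import SegmentationMask


def _mask_from_points(points, shape=(100, 100), um=1.0):
    """Mask with 1-pixel cells at given (row, col) positions."""
    labels = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(points, start=1):
        labels[r, c] = i
    return SegmentationMask("R", labels, um)


def brute_force_edges(mask, radius_um):
    """Oracle: all-pairs minimum pixel distance, no shortcuts."""
    ids = mask.cell_ids()
    coords = {i: np.argwhere(mask.labels == i).astype(float) for i in ids}
    edges = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            d = cdist(coords[ids[a]], coords[ids[b]]).min() * mask.um_per_px
            if d <= radius_um:
                edges.add((ids[a], ids[b]))
    return edges


def graph_edges(graph):
    df = graph.edge_list()
    return {tuple(sorted(p)) for p in zip(df.cell_a, df.cell_b)}


class TestNeighborGraph:
    def test_single_pixel_cells_at_known_distance(self):
        near = _mask_from_points([(10, 10), (10, 35)])   # 25 µm apart
        far = _mask_from_points([(10, 10), (10, 45)])    # 35 µm apart
        assert graph_edges(st.build_neighbor_graph(near, 30)) == {(1, 2)}
        assert graph_edges(st.build_neighbor_graph(far, 30)) == set()

    def test_single_cell_has_no_edges(self):
        g = st.build_neighbor_graph(_mask_from_points([(5, 5)]), 30)
        assert g.n_edges == 0

    def test_border_distance_uses_pixel_scale(self):
        m = _mask_from_points([(10, 10), (10, 25)], um=2.5)  # 37.5 µm
        assert st.build_neighbor_graph(m, 30).n_edges == 0
        assert st.build_neighbor_graph(m, 40).n_edges == 1

    def test_matches_brute_force_on_simulated_mask(self):
        cfg = st.SyntheticCohortConfig(seed=6, n_patients=2, rois_per_patient=1,
                                       cells_per_roi=25, roi_size_px=(200, 200))
        mask = st.simulate_roi(cfg, 0).mask
        g = st.build_neighbor_graph(mask, 30)
        assert graph_edges(g) == brute_force_edges(mask, 30)

    def test_empty_mask_gives_empty_graph(self):
        g = st.build_neighbor_graph(
            SegmentationMask("R", np.zeros((20, 20), np.int32), 1.0), 30)
        assert g.n_cells == 0 and g.n_edges == 0


class TestPatchFraction:
    def _toy(self):
        # cells 1..5 on a line, 10 µm spacing; radius 15 connects neighbors
        g = st.graph_from_centroids([0, 10, 20, 30, 40], [0] * 5, radius_um=15)
        return g

    def test_hand_enumerated_fraction(self):
        g = self._toy()
        labels = np.array(["ref", "tgt", "ref", "ref", "x"], dtype=object)
        # ref cells: 1 (neighbor 2=tgt), 3 (neighbors 2,4), 4 (neighbors 3,5)
        assert st.patch_fraction(g, labels, "ref", "tgt") == pytest.approx(2 / 3)

    def test_no_target_cells_gives_zero(self):
        g = self._toy()
        labels = np.array(["ref"] * 5, dtype=object)
        assert st.patch_fraction(g, labels, "ref", "missing") == 0.0

    def test_self_target_on_clique_is_one(self):
        g = st.graph_from_centroids([0, 5, 10], [0, 0, 0], radius_um=30)
        labels = np.array(["a", "a", "a"], dtype=object)
        assert st.patch_fraction(g, labels, "a", "a") == 1.0

    def test_absent_reference_is_nan(self):
        g = self._toy()
        labels = np.array(["x"] * 5, dtype=object)
        assert np.isnan(st.patch_fraction(g, labels, "ref", "x"))


class TestInteractionTest:
    def test_small_subpopulation_excluded(self):
        rng = np.random.default_rng(0)
        g = st.graph_from_centroids(rng.uniform(0, 300, 100), rng.uniform(0, 300, 100), 30)
        labels = np.array(["a"] * 91 + ["b"] * 9, dtype=object)
        res = st.interaction_test(g, labels, "a", "b", n_perm=200, seed=1)
        assert not res["included"]
        assert res["n_target"] == 9

    def test_planted_attraction_scores_positive(self):
        cfg = st.SyntheticCohortConfig(
            seed=8, n_patients=2, rois_per_patient=1, cells_per_roi=120,
            roi_size_px=(400, 400),
            profiles=(st.SubtypeProfile("A", {"DNA1": 5}), st.SubtypeProfile("B", {"DNA1": 5})),
            rules=(st.SpatialRule("attraction", "A", "B", range_um=10, strength=1.0),))
        cells = st.simulate_roi(cfg, 0, render_images=False).cells
        g = st.graph_from_centroids(cells.centroid_x_um, cells.centroid_y_um, 30)
        res = st.interaction_test(g, cells.subtype.to_numpy(), "B", "A",
                                  n_perm=500, seed=2)
        assert res["score"] == 1

    def test_null_labels_rarely_flagged(self):
        rng = np.random.default_rng(5)
        flags = []
        scores = []
        for rep in range(10):
            g = st.graph_from_centroids(rng.uniform(0, 500, 200),
                                        rng.uniform(0, 500, 200), 30)
            labels = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
            rng.shuffle(labels)
            res = st.interaction_test_all(g, labels, n_perm=300, alpha=0.01,
                                          seed=rep)
            flags.append((res["score"] != 0).sum())
            scores.append(res["score"].mean())
        assert np.mean(flags) <= 1.0        # 4 pairs/ROI at 2% expected each
        assert abs(np.mean(scores)) <= 0.1


class TestScoreMatrix:
    def _rows(self, scores, included=True):
        return pd.DataFrame({
            "roi_id": [f"R{i}" for i in range(len(scores))],
            "ref": "a", "target": "b", "n_ref": 20, "n_target": 20,
            "patch_fraction": 0.5, "p_high": 0.5, "p_low": 0.5,
            "score": scores, "included": included})

    def test_mean_of_scores(self):
        mat = st.score_matrix(self._rows([1, 1, 0]))
        assert mat.loc["a", "b"] == pytest.approx(2 / 3)

    def test_all_zero_scores_average_to_zero(self):
        assert st.score_matrix(self._rows([0, 0, 0])).loc["a", "b"] == 0.0

    def test_pair_excluded_everywhere_is_missing(self):
        mat = st.score_matrix(self._rows([1, 1], included=False))
        assert np.isnan(mat.loc["a", "b"])


class TestDistances:
    def _table(self, sources, targets):
        rows = []
        for i, (x, y) in enumerate(sources):
            rows.append(("R1", i, x, y, "CAF", "caf_s"))
        for j, (x, y) in enumerate(targets, start=len(sources)):
            rows.append(("R1", j, x, y, "tumor", "tumor"))
        return pd.DataFrame(rows, columns=["roi_id", "cell_id", "centroid_x_um",
                                           "centroid_y_um", "population", "subtype"])

    def test_hand_computed_minimum(self):
        tab = self._table([(0, 0)], [(3, 4), (6, 8)])
        d = st.min_distance_to(tab, ["caf_s"], "tumor")
        assert d.iloc[0] == pytest.approx(5.0)

    def test_coincident_cell_has_zero_distance(self):
        tab = self._table([(3, 4)], [(3, 4)])
        assert st.min_distance_to(tab, ["caf_s"], "tumor").iloc[0] == 0.0

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 100, (50, 2))
        tgt = rng.uniform(0, 100, (50, 2))
        tab = self._table(src, tgt)
        d = st.min_distance_to(tab, ["caf_s"], "tumor")
        oracle = cdist(src, tgt).min(axis=1)
        assert np.allclose(d.iloc[:50], oracle)

    def test_missing_target_population_is_nan(self):
        tab = self._table([(0, 0)], [])
        assert st.min_distance_to(tab, ["caf_s"], "tumor").isna().all()


class TestKsCompare:
    def test_identical_samples_have_zero_d(self):
        d, p = st.ks_compare([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports_have_d_one(self):
        d, _ = st.ks_compare([1, 2], [10, 20])
        assert d == 1.0

    def test_known_small_sample_against_ecdf_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        # oracle: evaluate both ECDFs at every observed point
        pts = sorted(set(a) | set(b))
        d_oracle = max(abs(sum(x <= t for x in a) / 3 - sum(x <= t for x in b) / 3)
                       for t in pts)
        d, _ = st.ks_compare(a, b)
        assert d == pytest.approx(d_oracle) == pytest.approx(1 / 3)

    def test_small_sample_p_matches_exhaustive_permutation(self):
        from itertools import combinations

        def ecdf_d(x, y):
            x, y = np.sort(x), np.sort(y)
            allv = np.concatenate([x, y])
            return np.abs(np.searchsorted(x, allv, side="right") / len(x)
                          - np.searchsorted(y, allv, side="right") / len(y)).max()

        rng = np.random.default_rng(3)
        for na, nb in [(3, 3), (4, 5), (6, 4)]:
            a, b = rng.normal(0, 1, na), rng.normal(0.8, 1, nb)
            d_obs, p = st.ks_compare(a, b)
            assert d_obs == pytest.approx(ecdf_d(a, b), abs=1e-15)
            pooled = np.concatenate([a, b])
            hits = total = 0
            for ia in combinations(range(na + nb), na):
                m = np.zeros(na + nb, bool)
                m[list(ia)] = True
                total += 1
                hits += ecdf_d(pooled[m], pooled[~m]) >= d_obs - 1e-12
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            st.ks_compare([], [1.0])


class TestNeighborhoods:
    def test_hand_counted_composition(self):
        # star: center 1 with neighbors 2..5 labeled 2×tumor, 2×CAF-1
        pts_x = [0, 10, -10, 0, 0]
        pts_y = [0, 0, 0, 10, -10]
        g = st.graph_from_centroids(pts_x, pts_y, radius_um=12)
        labels = np.array(["EC", "tumor", "tumor", "CAF 1", "CAF 1"], dtype=object)
        comp = st.neighborhood_compositions(g, labels, ["tumor", "CAF 1", "EC"])
        center = comp.iloc[0]
        assert center["tumor"] == 0.5 and center["CAF 1"] == 0.5 and center["EC"] == 0.0

    def test_isolated_cell_gets_zero_vector_and_rows_sum_to_one(self):
        g = st.graph_from_centroids([0, 10, 500], [0, 0, 0], radius_um=15)
        labels = np.array(["a", "b", "a"], dtype=object)
        comp = st.neighborhood_compositions(g, labels, ["a", "b"])
        sums = comp.sum(axis=1).to_numpy()
        assert sums[2] == 0.0
        assert np.allclose(sums[:2], 1.0)

    def test_unmappable_label_is_an_error(self):
        g = st.graph_from_centroids([0, 10], [0, 0], radius_um=15)
        with pytest.raises(ValueError, match="not mappable"):
            st.neighborhood_compositions(g, np.array(["a", "zzz"], dtype=object), ["a"])

    def test_planted_domains_recovered_with_k2(self):
        cfg = st.SyntheticCohortConfig(
            seed=12, n_patients=2, rois_per_patient=1, cells_per_roi=300,
            roi_size_px=(400, 400),
            profiles=(st.SubtypeProfile("A", {"DNA1": 5}), st.SubtypeProfile("B", {"DNA1": 5})),
            rules=(st.SpatialRule("domain", "A", "A", strength=1.0),
                   st.SpatialRule("domain", "B", "B", strength=1.0)))
        cells = st.simulate_roi(cfg, 0, render_images=False).cells
        g = st.graph_from_centroids(cells.centroid_x_um, cells.centroid_y_um, 30)
        comp = st.neighborhood_compositions(g, cells.subtype.to_numpy(), ["A", "B"])
        model = st.cluster_neighborhoods(comp, k=2, seed=0)
        assert adjusted_rand_score(cells.domain_id, model.assignments) >= 0.8

    def test_identical_vectors_collapse_to_one_effective_cluster(self):
        vecs = pd.DataFrame(np.tile([0.5, 0.5], (20, 1)), columns=["a", "b"])
        model = st.cluster_neighborhoods(vecs, k=3, seed=0)
        assert model.n_effective == 1

    def test_seed_reproducible(self):
        rng = np.random.default_rng(0)
        vecs = pd.DataFrame(rng.dirichlet([1, 1, 1], 100), columns=list("abc"))
        m1 = st.cluster_neighborhoods(vecs, k=4, seed=3)
        m2 = st.cluster_neighborhoods(vecs, k=4, seed=3)
        assert np.array_equal(m1.assignments, m2.assignments)
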