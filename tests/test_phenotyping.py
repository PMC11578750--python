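"""Transforms, graph clustering, population annotation and the refine loop."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import stromascope as st
from stromascope.core import ASINH_PREFIX, NORM_PREFIX, RAW_PREFIX
from stromascope.phenotyping import assign_clusters, marker_thresholds


def _raw_table(values, marker="m1"):
    return pd.DataFrame({"cell_id": np.arange(len(values)), "roi_id": "R",
                         RAW_PREFIX + marker: values})


class TestTransformNormalize:
    def test_asinh_of_zero_is_zero_and_maps_to_scale_bottom(self):
        tab = _raw_table(np.concatenate([[0.0], np.linspace(1, 100, 99)]))
        out = st.transform_normalize(tab, ["m1"])
        assert out.loc[0, ASINH_PREFIX + "m1"] == 0.0
        assert out.loc[0, NORM_PREFIX + "m1"] == 0.0

    def test_output_in_unit_interval_and_rank_preserving(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2, 10, 1000)
        out = st.transform_normalize(_raw_table(vals), ["m1"])
        norm = out[NORM_PREFIX + "m1"].to_numpy()
        assert norm.min() >= 0 and norm.max() <= 1
        order = np.argsort(vals, kind="stable")
        assert np.all(np.diff(norm[order]) >= -1e-15)  # weakly monotone

    def test_endpoints_match_sort_based_percentile_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(1, 1, 1000)
        out = st.transform_normalize(_raw_table(vals), ["m1"])
        a = np.sort(np.arcsinh(vals))

        def interp_pct(q):
            pos = (len(a) - 1) * q / 100
            lo = int(np.floor(pos))
            return a[lo] + (a[min(lo + 1, len(a) - 1)] - a[lo]) * (pos % 1)

        lo, hi = interp_pct(1), interp_pct(99)
        norm = out[NORM_PREFIX + "m1"].to_numpy()
        expected = (np.clip(np.arcsinh(vals), lo, hi) - lo) / (hi - lo)
        assert np.max(np.abs(norm - expected)) < 1e-12
        clipped = np.mean((np.arcsinh(vals) < lo) | (np.arcsinh(vals) > hi))
        assert 0.01 <= clipped <= 0.03

    def test_degenerate_marker_set_to_zero_with_warning(self):
        tab = _raw_table(np.full(10, 7.0))
        with pytest.warns(UserWarning, match="degenerate"):
            out = st.transform_normalize(tab, ["m1"])
        assert (out[NORM_PREFIX + "m1"] == 0).all()


class TestClusterCells:
    def _two_blob_table(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        truth = np.repeat([0, 1], n)
        x1 = np.where(truth, 0.9, 0.1) + rng.normal(0, 0.03, 2 * n)
        x2 = np.where(truth, 0.1, 0.9) + rng.normal(0, 0.03, 2 * n)
        tab = pd.DataFrame({NORM_PREFIX + "a": x1, NORM_PREFIX + "b": x2})
        return tab, truth

    def test_two_separated_profiles_give_two_communities(self):
        # with k on the order of the group size each blob is a near-clique
        # and modularity recovers exactly the two profiles
        tab, truth = self._two_blob_table(n=80)
        res = st.cluster_cells(tab, ["a", "b"], k=40, seed=0)
        assert res.n_clusters == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_cells_collapse_to_one_cluster(self):
        tab = pd.DataFrame({NORM_PREFIX + "a": np.full(100, 0.5)})
        res = st.cluster_cells(tab, ["a"], k=10, seed=0)
        assert res.n_clusters == 1

    def test_row_permutation_does_not_change_partition(self):
        tab, truth = self._two_blob_table(n=60, seed=1)
        res = st.cluster_cells(tab, ["a", "b"], k=30, seed=0)
        perm = np.random.default_rng(0).permutation(len(tab))
        res_p = st.cluster_cells(tab.iloc[perm].reset_index(drop=True),
                                 ["a", "b"], k=30, seed=0)
        assert adjusted_rand_score(res.labels[perm], res_p.labels) == 1.0

    def test_seed_reproducible(self):
        tab, _ = self._two_blob_table(n=150, seed=2)
        a = st.cluster_cells(tab, ["a", "b"], k=15, seed=7)
        b = st.cluster_cells(tab, ["a", "b"], k=15, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_fewer_cells_than_k_is_an_error(self):
        tab = pd.DataFrame({NORM_PREFIX + "a": np.arange(10.0)})
        with pytest.raises(ValueError, match="smaller k"):
            st.cluster_cells(tab, ["a"], k=30)


class TestAnnotation:
    def _profiles(self):
        # cluster-mean profiles: rows are clusters
        return pd.DataFrame(
            {"Pan-Ck": [0.9, 0.05, 0.1, 0.05], "CD45": [0.05, 0.9, 0.05, 0.05],
             "CD31": [0.02, 0.05, 0.9, 0.05], "peptide-C": [0.0, 0.0, 0.0, 0.9],
             "vimentin": [0.1, 0.2, 0.3, 0.1]},
            index=pd.Index([0, 1, 2, 3], name="cluster"))

    def test_rule_based_population_calls(self):
        mapping = assign_clusters(self._profiles(), st.phenotyping.default_population_rules())
        assert mapping[0] == "tumor"
        assert mapping[1] == "immune"
        assert mapping[2] == "EC"
        assert mapping[3] == "islet"

    def test_cluster_matching_no_rule_is_other(self):
        prof = self._profiles()
        prof.loc[4] = [0.05, 0.05, 0.05, 0.0, 0.05]
        rules = [r for r in st.phenotyping.default_population_rules()
                 if r.name != "CAF"]
        assert assign_clusters(prof, rules)[4] == "other"

    def test_uninformative_marker_blocks_positivity(self):
        prof = pd.DataFrame({"m": [0.50, 0.52, 0.51]})
        thr = marker_thresholds(prof)
        assert np.isinf(thr["m"])


class TestRefineAndEmbed:
    def test_full_loop_recovers_planted_populations_and_subtypes(self, phenotyped_table, panel):
        tab, truth = phenotyped_table
        markers = panel.clustering_markers
        res = st.cluster_cells(tab, markers, k=60, seed=0)
        ann = st.annotate_populations(tab, res)
        ref = st.refine_populations(ann, markers, seed=0)
        assert adjusted_rand_score(truth["population"], ref["population"]) >= 0.9
        caf = truth["population"] == "CAF"
        assert adjusted_rand_score(truth.loc[caf, "subtype"], ref.loc[caf, "subtype"]) >= 0.9

    def test_planted_misannotation_is_repaired(self, phenotyped_table, panel):
        tab, truth = phenotyped_table
        markers = panel.clustering_markers
        res = st.cluster_cells(tab, markers, k=60, seed=0)
        ann = st.annotate_populations(tab, res)
        # corrupt: push a slab of immune cells into the CAF subset
        immune = ann.index[ann["population"] == "immune"][:150]
        ann.loc[immune, "population"] = "CAF"
        ref = st.refine_populations(ann, markers, seed=0)
        assert (ref.loc[immune, "population"] == "immune").mean() > 0.9

    def test_refinement_is_a_fixed_point_on_clean_annotations(self, phenotyped_table, panel):
        tab, truth = phenotyped_table
        markers = panel.clustering_markers
        res = st.cluster_cells(tab, markers, k=60, seed=0)
        ann = st.annotate_populations(tab, res)
        ref = st.refine_populations(ann, markers, seed=0)
        again = st.refine_populations(ref, markers, seed=0)
        assert (ref["population"] == again["population"]).all()

    def test_embedding_is_deterministic_and_separates_groups(self):
        rng = np.random.default_rng(0)
        truth = np.repeat([0, 1], 100)
        tab = pd.DataFrame({
            NORM_PREFIX + "a": np.where(truth, 0.9, 0.1) + rng.normal(0, 0.02, 200),
            NORM_PREFIX + "b": np.where(truth, 0.1, 0.9) + rng.normal(0, 0.02, 200)})
        e1 = st.embed_2d(tab, ["a", "b"], seed=1)
        e2 = st.embed_2d(tab, ["a", "b"], seed=1)
        assert np.array_equal(e1, e2)
        c0, c1 = e1[truth == 0].mean(0), e1[truth == 1].mean(0)
        between = np.linalg.norm(c0 - c1)
        within = max(np.linalg.norm(e1[truth == 0] - c0, axis=1).mean(),
                     np.linalg.norm(e1[truth == 1] - c1, axis=1).mean())
        assert between > within

    def test_empty_table_embeds_to_empty(self):
        assert st.embed_2d(pd.DataFrame(), ["a"]).shape == (0, 2)
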