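"""Two-channel graph construction, filtering, rescaling and layering."""

import numpy as np
import pytest

from lesiongraph.imaging import BrainTemplate
from lesiongraph.lesion_graph import (
    CohortGraph,
    accumulate_graph,
    filter_nodes,
    lesion_adjacency,
    randomize_layers,
    read_graph,
    rescale_weights,
    to_layered,
    write_graph,
)
from lesiongraph.synthetic_cohort import LesionCohort, Patient


def _tiny_template(shape=(6, 6, 6)):
    mask = np.ones(shape, bool)
    return BrainTemplate(
        shape=shape, voxel_size_mm=4.0, brain_mask=mask,
        labels=np.zeros(shape, np.int16), affine=np.diag([4.0, 4.0, 4.0, 1.0]),
    )


def _cohort(masks, scores, shape=(6, 6, 6), test="stroop"):
    template = _tiny_template(shape)
    patients = [
        Patient(id=f"p{i}", mask=m.astype(bool), scores={test: s})
        for i, (m, s) in enumerate(zip(masks, scores))
    ]
    return LesionCohort(template=template, patients=patients)


class TestLesionAdjacency:
    def test_face_adjacent_pair_one_edge(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        assert len(lesion_adjacency(m)) == 1

    def test_single_voxel_no_edges(self):
        m = np.zeros((4, 4, 4), bool)
        m[2, 2, 2] = True
        assert len(lesion_adjacency(m)) == 0

    def test_full_cube_26_connectivity(self):
        """All C(8,2)=28 pairs of a 2x2x2 cube are Chebyshev-adjacent."""
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert len(lesion_adjacency(m, connectivity=26)) == 28

    def test_six_connectivity_is_sparser(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert len(lesion_adjacency(m, connectivity=6)) == 12

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            edges = lesion_adjacency(np.zeros((3, 3, 3), bool))
        assert len(edges) == 0

    def test_clique_variant_joins_all_pairs(self):
        m = np.zeros((5, 5, 5), bool)
        m[0, 0, 0] = m[4, 4, 4] = m[2, 2, 2] = True
        assert len(lesion_adjacency(m, clique=True)) == 3


class TestAccumulate:
    def test_shared_edge_inverse_score_sum(self):
        m = np.zeros((6, 6, 6), bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        g = accumulate_graph(_cohort([m, m], [2.0, 4.0]), "stroop")
        assert g.n_edges == 1
        assert g.lesion_w[0] == 2
        assert g.task_w[0] == pytest.approx(0.75)  # 1/2 + 1/4

    def test_zero_score_excluded_from_task_sum(self):
        m = np.zeros((6, 6, 6), bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        g = accumulate_graph(_cohort([m, m], [0.0, 5.0]), "stroop")
        assert g.lesion_w[0] == 2  # lesion count still includes both patients
        assert g.task_w[0] == pytest.approx(0.2)

    def test_disjoint_lesions_unit_weights(self):
        m1 = np.zeros((6, 6, 6), bool)
        m1[0, 0, 0] = m1[0, 0, 1] = True
        m2 = np.zeros((6, 6, 6), bool)
        m2[5, 5, 5] = m2[5, 5, 4] = True
        g = accumulate_graph(_cohort([m1, m2], [2.0, 4.0]), "stroop")
        assert (g.lesion_w == 1).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        """A^lesion and A^task equal a double loop over patients and pairs."""
        rng = np.random.default_rng(seed)
        shape = (5, 5, 5)
        masks = [rng.random(shape) < 0.25 for _ in range(5)]
        masks = [m for m in masks if m.any()] or [np.ones(shape, bool)]
        scores = rng.uniform(1.0, 10.0, len(masks))
        g = accumulate_graph(_cohort(masks, scores, shape), "stroop")

        expect = {}
        offs = [
            (dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ]
        for mask, score in zip(masks, scores):
            for a in map(tuple, np.argwhere(mask)):
                for off in offs:
                    b = tuple(np.add(a, off))
                    if any(c < 0 or c >= 5 for c in b) or not mask[b]:
                        continue
                    fa = np.ravel_multi_index(a, shape)
                    fb = np.ravel_multi_index(b, shape)
                    if fa < fb:
                        lw, tw = expect.get((fa, fb), (0, 0.0))
                        expect[(fa, fb)] = (lw + 1, tw + 1.0 / score)
        got = {
            (g.nodes[i], g.nodes[j]): (lw, tw)
            for (i, j), lw, tw in zip(g.edges, g.lesion_w, g.task_w)
        }
        assert set(got) == set(expect)
        for key in expect:
            assert got[key][0] == expect[key][0]
            assert got[key][1] == pytest.approx(expect[key][1])

    def test_all_zero_scores_rejected(self):
        m = np.zeros((6, 6, 6), bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        with pytest.raises(ValueError, match="zero"):
            accumulate_graph(_cohort([m], [0.0]), "stroop")


def _graph(edges, n=None, lesion=None, task=None):
    edges = np.array(edges)
    n = n or int(edges.max()) + 1
    e = len(edges)
    return CohortGraph(
        nodes=np.arange(n),
        edges=edges,
        lesion_w=np.ones(e, np.int64) if lesion is None else np.asarray(lesion),
        task_w=np.full(e, 0.5) if task is None else np.asarray(task, float),
        shape=(n, 1, 1),
    )


class TestFilterNodes:
    def test_star_collapses(self):
        """Star: all leaves fall below the min-degree floor; only the centre
        survives and no edges remain."""
        g = _graph([(0, i) for i in range(1, 11)])
        out = filter_nodes(g)
        assert out.n_nodes == 1 and out.nodes[0] == 0
        assert out.n_edges == 0

    def test_all_degree_two_empties(self):
        g = _graph([(0, 1), (1, 2), (2, 3), (3, 0)])  # 4-cycle, all degree 2
        with pytest.raises(ValueError, match="empty"):
            filter_nodes(g)

    def test_regular_graph_unchanged(self):
        # K4: all degrees 3, all at the median, none below the floor
        g = _graph([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        out = filter_nodes(g)
        assert out.n_nodes == 4 and out.n_edges == 6

    def test_idempotent_at_fixed_point(self):
        g = _graph([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        once = filter_nodes(g)
        twice = filter_nodes(once)
        np.testing.assert_array_equal(once.nodes, twice.nodes)
        np.testing.assert_array_equal(once.edges, twice.edges)


class TestRescale:
    def test_minmax_example(self):
        g = _graph([(0, 1), (1, 2), (2, 3)], task=[2.0, 4.0, 6.0], lesion=[1, 2, 3])
        out = rescale_weights(g)
        np.testing.assert_allclose(out.task_w_scaled, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out.lesion_w_scaled, [0.0, 0.5, 1.0])

    def test_constant_channel_maps_to_zero(self):
        g = _graph([(0, 1), (1, 2)], task=[5.0, 5.0], lesion=[2, 2])
        out = rescale_weights(g)
        np.testing.assert_array_equal(out.task_w_scaled, [0.0, 0.0])

    def test_idempotent_on_unit_range(self):
        g = _graph([(0, 1), (1, 2), (2, 3)], task=[0.0, 0.25, 1.0])
        out = rescale_weights(g)
        np.testing.assert_allclose(out.task_w_scaled, [0.0, 0.25, 1.0])

    def test_raw_counts_preserved(self):
        g = _graph([(0, 1), (1, 2)], lesion=[3, 7])
        out = rescale_weights(g)
        np.testing.assert_array_equal(out.lesion_w, [3, 7])


class TestLayering:
    def test_two_entries_per_dual_channel_edge(self):
        g = rescale_weights(_graph([(0, 1), (1, 2)], task=[1.0, 2.0]))
        lay = to_layered(g)
        assert lay.n_entries == 4

    def test_zero_task_edge_in_lesion_layer_only(self):
        g = rescale_weights(_graph([(0, 1), (1, 2)], task=[0.0, 2.0]))
        lay = to_layered(g)
        assert lay.n_entries == 3
        lesion_edges = set(lay.entry_edge[lay.entry_layer == 0])
        task_edges = set(lay.entry_edge[lay.entry_layer == 1])
        assert lesion_edges == {0, 1} and task_edges == {1}

    def test_weight_model_tags(self):
        g = rescale_weights(_graph([(0, 1)]))
        assert to_layered(g).weight_models == ("poisson", "gaussian")

    def test_requires_rescaled_graph(self):
        with pytest.raises(ValueError, match="rescale"):
            to_layered(_graph([(0, 1)]))


class TestRandomizeLayers:
    def _layered(self, e=1000, seed=0):
        rng = np.random.default_rng(seed)
        edges = np.column_stack([np.arange(e), np.arange(e) + 1])
        g = rescale_weights(
            _graph(edges, n=e + 1, lesion=rng.integers(1, 9, e), task=rng.random(e) + 0.1)
        )
        return to_layered(g)

    def test_conserves_weight_multiset_and_layer_counts(self):
        lay = self._layered()
        null = randomize_layers(lay, seed=1)
        np.testing.assert_array_equal(np.sort(null.entry_value), np.sort(lay.entry_value))
        assert (null.entry_layer == 0).sum() == (lay.entry_layer == 0).sum()
        assert (null.entry_layer == 1).sum() == (lay.entry_layer == 1).sum()

    def test_different_seeds_differ(self):
        lay = self._layered()
        n1 = randomize_layers(lay, seed=1)
        n2 = randomize_layers(lay, seed=2)
        assert (n1.entry_layer != n2.entry_layer).any()

    def test_seeded_reproducible(self):
        lay = self._layered()
        np.testing.assert_array_equal(
            randomize_layers(lay, seed=5).entry_layer,
            randomize_layers(lay, seed=5).entry_layer,
        )

    def test_single_layer_rejected(self):
        g = rescale_weights(_graph([(0, 1), (1, 2)], task=[0.0, 0.0]))
        lay = to_layered(g)
        with pytest.raises(ValueError, match="two layers"):
            randomize_layers(lay, seed=0)


def test_degree_bounded_by_neighbourhood(small_cohort):
    g = accumulate_graph(small_cohort, "stroop")
    assert g.degrees().max() <= 26


def test_graph_round_trip(tmp_path, small_cohort):
    g = rescale_weights(filter_nodes(accumulate_graph(small_cohort, "stroop")))
    write_graph(g, tmp_path)
    back = read_graph(tmp_path)
    np.testing.assert_array_equal(back.nodes, g.nodes)
    np.testing.assert_array_equal(back.edges, g.edges)
    np.testing.assert_array_equal(back.lesion_w, g.lesion_w)
    np.testing.assert_allclose(back.task_w, g.task_w)
    np.testing.assert_allclose(back.task_w_scaled, g.task_w_scaled)
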