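"""Description length, SBM fitting, block tests and back-projection."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import planted_layered_graph, random_layered_graph
from lesiongraph.imaging import dice
from lesiongraph.lesion_graph import randomize_layers
from lesiongraph.sbm import (
    BlockFit,
    SBMConfig,
    back_project,
    block_weight_test,
    compare_to_null,
    description_length,
    exhaustive_mdl,
    fit_sbm,
    log_posterior_odds,
    permutation_retention,
    polish_partition,
)
from lesiongraph.synthetic_cohort import default_template

FAST = SBMConfig(seed=0, wait=40, max_sweeps=200, anneal_sweeps=25, p_uniform=0.4)


class TestDescriptionLength:
    def test_planted_partition_beats_single_block(self):
        lay, truth = planted_layered_graph(seed=1)
        s_true = description_length(lay, truth)
        s_one = description_length(lay, np.zeros(lay.n_nodes, int))
        assert s_true < s_one

    def test_splitting_homogeneous_graph_costs(self):
        """Duplicating a block into halves on an unstructured graph adds cost."""
        rng = np.random.default_rng(2)
        lay = random_layered_graph(20, rng, p_edge=0.3)
        one = np.zeros(20, int)
        split = np.array([0] * 10 + [1] * 10)
        assert description_length(lay, split) > description_length(lay, one)

    def test_positive_for_any_graph(self):
        rng = np.random.default_rng(3)
        for n in (2, 5, 9):
            lay = random_layered_graph(n, rng)
            assert description_length(lay, np.zeros(n, int)) > 0

    def test_kernel_and_vectorised_paths_agree(self):
        rng = np.random.default_rng(4)
        lay = random_layered_graph(8, rng)
        fit = fit_sbm(lay, FAST)
        assert fit.S == pytest.approx(description_length(lay, fit.b), abs=1e-8)

    def test_partition_length_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        lay = random_layered_graph(6, rng)
        with pytest.raises(ValueError, match="partition"):
            description_length(lay, np.zeros(5, int))


class TestFit:
    def test_same_seed_identical(self):
        rng = np.random.default_rng(6)
        lay = random_layered_graph(12, rng)
        f1 = fit_sbm(lay, FAST)
        f2 = fit_sbm(lay, FAST)
        np.testing.assert_array_equal(f1.b, f2.b)
        assert f1.S == f2.S

    def test_record_sequence_strictly_decreasing(self):
        lay, _ = planted_layered_graph(seed=2)
        fit = fit_sbm(lay, SBMConfig(seed=1, wait=40, max_sweeps=150))
        assert (np.diff(fit.records) < 0).all()

    def test_empty_graph_rejected(self):
        rng = np.random.default_rng(7)
        lay = random_layered_graph(2, rng)
        single = lay.__class__(
            nodes=lay.nodes[:1], edges=np.empty((0, 2), int),
            entry_edge=np.empty(0, int), entry_layer=np.empty(0, np.int8),
            entry_value=np.empty(0), entry_count=np.empty(0, int), shape=lay.shape,
        )
        with pytest.raises(ValueError, match="too small"):
            fit_sbm(single, FAST)

    def test_planted_partition_recovered(self):
        lay, truth = planted_layered_graph(seed=3)
        fit = fit_sbm(lay, SBMConfig(seed=3, wait=60, max_sweeps=200, anneal_sweeps=30))
        assert adjusted_rand_score(truth, fit.b) >= 0.9

    def test_hierarchy_levels_coarsen(self):
        lay, _ = planted_layered_graph(n_blocks=4, block_size=15, seed=4)
        fit = fit_sbm(lay, SBMConfig(seed=4, wait=40, max_sweeps=150, max_levels=3))
        for fine, coarse in zip(fit.levels, fit.levels[1:]):
            # each fine block maps into exactly one coarse block
            for blk in range(int(fine.max()) + 1):
                assert len(np.unique(coarse[fine == blk])) == 1

    def test_polish_never_worsens(self):
        rng = np.random.default_rng(8)
        lay = random_layered_graph(15, rng)
        start = rng.integers(0, 4, 15)
        polished = polish_partition(lay, start)
        assert polished.S <= description_length(lay, start) + 1e-9


class TestExhaustive:
    def test_two_node_graph(self):
        rng = np.random.default_rng(9)
        lay = random_layered_graph(2, rng, p_edge=1.0)
        fit = exhaustive_mdl(lay)
        both = [description_length(lay, np.array(p)) for p in ([0, 0], [0, 1])]
        assert fit.S == pytest.approx(min(both))

    def test_self_consistency(self):
        rng = np.random.default_rng(10)
        lay = random_layered_graph(6, rng)
        fit = exhaustive_mdl(lay)
        assert fit.S == pytest.approx(description_length(lay, fit.b))

    def test_too_large_rejected(self):
        rng = np.random.default_rng(11)
        lay = random_layered_graph(9, rng)
        with pytest.raises(ValueError, match="enumeration"):
            exhaustive_mdl(lay)


class TestPosteriorOdds:
    def test_printed_fluency_arithmetic(self):
        assert log_posterior_odds(646761.165, 432339.440) == pytest.approx(214421.725)
        assert round(log_posterior_odds(646761.165, 432339.440)) == 214422

    def test_printed_stroop_arithmetic(self):
        assert log_posterior_odds(671673.462, 440889.980) == pytest.approx(230783.482)
        assert round(log_posterior_odds(671673.462, 440889.980)) == 230783

    def test_equal_entropies_indifferent(self):
        assert log_posterior_odds(5.0, 5.0) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            log_posterior_odds(np.inf, 1.0)


class TestBlockTest:
    def _fit_and_graph(self, seed=0):
        lay, truth = planted_layered_graph(seed=seed)
        return BlockFit(
            levels=[truth], S=0.0, node_voxels=np.arange(lay.n_nodes), shape=lay.shape
        ), lay

    def test_identical_channels_not_retained(self):
        fit, lay = self._fit_and_graph()
        # make task values equal lesion values edge-for-edge
        e = lay.edges.shape[0]
        lay2 = lay.__class__(
            nodes=lay.nodes, edges=lay.edges, entry_edge=lay.entry_edge,
            entry_layer=lay.entry_layer,
            entry_value=np.concatenate([lay.entry_value[:e], lay.entry_value[:e]]),
            entry_count=lay.entry_count, shape=lay.shape,
        )
        sig = block_weight_test(fit, lay2)
        assert not sig.table["retained"].any()

    def test_separated_channels_task_dominant(self):
        rng = np.random.default_rng(12)
        n, e = 20, 120
        edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])[:e]
        ee = np.arange(e)
        from lesiongraph.lesion_graph import LayeredGraph

        lay = LayeredGraph(
            nodes=np.arange(n), edges=edges,
            entry_edge=np.concatenate([ee, ee]),
            entry_layer=np.concatenate([np.zeros(e, np.int8), np.ones(e, np.int8)]),
            entry_value=np.concatenate([
                rng.normal(0.05, 0.01, e).clip(0, 1),   # lesion ~ 0
                rng.normal(0.95, 0.01, e).clip(0, 1),   # task ~ 1
            ]),
            entry_count=np.zeros(2 * e, np.int64), shape=(n, 1, 1),
        )
        fit = BlockFit(levels=[np.zeros(n, int)], S=0.0,
                       node_voxels=np.arange(n), shape=lay.shape)
        sig = block_weight_test(fit, lay, unit="edge")
        row = sig.table.iloc[0]
        assert row["retained"] and row["dominance"] == "task"

    def test_interval_matches_textbook_t(self):
        rng = np.random.default_rng(13)
        fit, lay = self._fit_and_graph(seed=5)
        sig = block_weight_test(fit, lay, unit="edge")
        # recompute one block's lesion interval independently
        from lesiongraph.sbm import _entry_arrays

        ent_u, ent_v, ent_l, ent_w = _entry_arrays(lay)
        b = fit.b
        incident = ((b[ent_u] == 0) | (b[ent_v] == 0)) & (ent_l == 0)
        x = ent_w[incident]
        lo, hi = stats.t.interval(0.95, len(x) - 1, loc=x.mean(),
                                  scale=stats.sem(x, ddof=1))
        row = sig.table.iloc[0]
        assert row["lesion_lo"] == pytest.approx(lo, rel=1e-9)
        assert row["lesion_hi"] == pytest.approx(hi, rel=1e-9)

    def test_tiny_blocks_flagged_untestable(self):
        rng = np.random.default_rng(14)
        lay = random_layered_graph(4, rng, p_edge=1.0)
        b = np.array([0, 0, 0, 1])
        fit = BlockFit(levels=[b], S=0.0, node_voxels=np.arange(4), shape=lay.shape)
        sig = block_weight_test(fit, lay, unit="node")
        assert set(sig.table.columns) >= {"testable", "retained", "dominance"}


class TestBackProjection:
    def test_retained_block_painted_with_mean_weight(self):
        template = default_template((8, 8, 8))
        lay, truth = planted_layered_graph(n_blocks=2, block_size=10, seed=6)
        fit = BlockFit(levels=[truth], S=0.0,
                       node_voxels=np.arange(20), shape=template.shape)
        sig = block_weight_test(fit, lay)
        tab = sig.table.copy()
        tab["retained"] = [True, False]
        tab["dominance"] = ["task", "neither"]
        vol = back_project(fit, sig.__class__(tab), template)
        painted = vol.data.ravel()[:10]
        assert np.allclose(painted, tab.loc[0, "mean_task"])
        assert vol.data.ravel()[10:].sum() == 0

    def test_nothing_retained_all_zero(self):
        template = default_template((8, 8, 8))
        lay, truth = planted_layered_graph(n_blocks=2, block_size=10, seed=7)
        fit = BlockFit(levels=[truth], S=0.0,
                       node_voxels=np.arange(20), shape=template.shape)
        sig = block_weight_test(fit, lay)
        tab = sig.table.copy()
        tab["retained"] = False
        vol = back_project(fit, sig.__class__(tab), template)
        assert (vol.data == 0).all()

    def test_dice_against_hand_computed_overlap(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, :3] = True
        b[0, 0, 1:4] = True
        assert dice(a, b) == pytest.approx(2 * 2 / 6)


class TestNullComparison:
    def test_matched_comparison_on_planted_graph(self):
        """With real layer structure the layered model codes shorter."""
        rng = np.random.default_rng(15)
        lay, truth = planted_layered_graph(seed=8, mu_in=0.8, mu_out=0.2)
        # give the two layers genuinely different weight levels
        task = lay.entry_layer == 1
        values = lay.entry_value.copy()
        values[task] = np.clip(values[task] + 0.15, 0, 1)
        lay2 = lay.__class__(
            nodes=lay.nodes, edges=lay.edges, entry_edge=lay.entry_edge,
            entry_layer=lay.entry_layer, entry_value=values,
            entry_count=lay.entry_count, shape=lay.shape,
        )
        null = randomize_layers(lay2, seed=9)
        fit_l, fit_n, odds = compare_to_null(lay2, null, SBMConfig(seed=10, wait=40, max_sweeps=150))
        assert odds > 0
        assert odds == pytest.approx(fit_n.S - fit_l.S)

    def test_permutation_retention_controls_null(self):
        """On a graph with no layer structure nothing should be retained."""
        lay, truth = planted_layered_graph(seed=11)
        null = randomize_layers(lay, seed=12)
        fit = fit_sbm(null, SBMConfig(seed=13, wait=40, max_sweeps=150))
        sig = permutation_retention(fit, null, n_permutations=20, seed=14)
        assert not sig.table["retained"].any()
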