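"""Nei distance, AGD and the panel cost function."""

import numpy as np
import pytest

from msatpanel import (
    GenotypeMatrix,
    MarkerPanel,
    PanelEvaluator,
    accuracy_loss,
    agd,
    distance_matrix,
    nei_distance,
    simulate_genotypes,
    SimConfig,
)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        fa = {"mk1": {1: 0.3, 2: 0.7}, "mk2": {5: 1.0}}
        assert nei_distance(fa, fa) == 0.0

    def test_one_locus_hand_value(self):
        d = nei_distance({"mk": {1: 1.0}}, {"mk": {1: 0.5, 2: 0.5}})
        assert d == pytest.approx(0.34657359, abs=1e-7)

    def test_disjoint_alleles_infinite(self):
        d = nei_distance({"mk": {1: 1.0}}, {"mk": {2: 1.0}})
        assert np.isinf(d)

    def test_panel_restricts_sums(self):
        fa = {"mk1": {1: 1.0}, "mk2": {1: 0.5, 2: 0.5}}
        fb = {"mk1": {1: 1.0}, "mk2": {1: 1.0}}
        panel = MarkerPanel.from_names(["mk1"], ["mk1", "mk2"])
        assert nei_distance(fa, fb, panel) == 0.0

    def test_no_shared_locus_errors(self):
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError, match="no locus"):
                nei_distance({"mk1": {1: 1.0}}, {"mk2": {1: 1.0}})


class TestDistanceMatrix:
    def test_identical_populations_zero_matrix(self):
        calls = np.tile(np.array([[1, 2], [1, 1], [2, 2]]), (3, 1)).reshape(9, 1, 2)
        G = GenotypeMatrix(
            [f"i{j}" for j in range(9)],
            ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
            ["mk"],
            calls,
        )
        dm = distance_matrix(G)
        assert np.allclose(dm.values.to_numpy(), 0.0)

    def test_symmetry_and_zero_diagonal(self, sim_default):
        dm = distance_matrix(sim_default)
        v = dm.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert (v[np.isfinite(v)] >= 0).all()

    def test_group_permutation_consistency(self, sim_default):
        dm = distance_matrix(sim_default)
        order = dm.groups[::-1]
        assert np.allclose(
            dm.values.loc[order, order].to_numpy(), dm.values.to_numpy()[::-1, ::-1]
        )

    def test_single_population_requires_individual_grouping(self):
        G = GenotypeMatrix(
            ["a", "b"], ["P", "P"], ["mk"], np.array([[[1, 2]], [[1, 1]]])
        )
        with pytest.raises(ValueError, match="individual"):
            distance_matrix(G, grouping="population")
        dm = distance_matrix(G, grouping="auto")  # falls back to individuals
        assert dm.groups == ["a", "b"]


class TestAGDAndLoss:
    def test_two_groups_agd_is_the_pair_distance(self, tiny_matrix):
        dm = distance_matrix(tiny_matrix)
        expected = dm.values.iloc[0, 1]
        assert agd(tiny_matrix) == pytest.approx(expected)

    def test_agd_is_mean_of_pairwise(self, sim_default):
        dm = distance_matrix(sim_default)
        v = dm.values.to_numpy()
        iu = np.triu_indices_from(v, k=1)
        upper = v[iu]
        assert agd(sim_default) == pytest.approx(upper[np.isfinite(upper)].mean())

    def test_full_panel_loss_zero(self, sim_default):
        panel = MarkerPanel.full(list(sim_default.loci))
        assert accuracy_loss(sim_default, panel) == 0.0

    def test_loss_invariant_to_panel_order(self, sim_default):
        loci = list(sim_default.loci)
        p1 = MarkerPanel.from_names(loci[2:6], loci)
        p2 = MarkerPanel.from_names(loci[5:1:-1], loci)
        assert accuracy_loss(sim_default, p1) == accuracy_loss(sim_default, p2)

    def test_loss_hand_derived_two_groups(self):
        # two pops, two fixed loci: loss = 100*|D(panel)-D(full)|/D(full)
        calls = np.array(
            [
                [[1, 1], [1, 1]],
                [[1, 1], [1, 1]],
                [[1, 2], [1, 1]],
                [[2, 2], [1, 2]],
            ]
        )
        G = GenotypeMatrix(
            ["a", "b", "c", "d"], ["P1", "P1", "P2", "P2"], ["mk1", "mk2"], calls
        )
        # P1 freqs: mk1 (1:1.0), mk2 (1:1.0); P2: mk1 (1:.25,2:.75), mk2 (1:.75,2:.25)
        num_full = 1 * 0.25 + 1 * 0.75
        d_full = -np.log(num_full / np.sqrt(2 * ((0.25**2 + 0.75**2) * 2)))
        num_p = 0.25
        d_p = -np.log(num_p / np.sqrt(1 * (0.25**2 + 0.75**2)))
        expected = 100 * abs(d_p - d_full) / d_full
        panel = MarkerPanel.from_names(["mk1"], ["mk1", "mk2"])
        ev = PanelEvaluator(G)
        assert ev.loss(panel.mask) == pytest.approx(expected)

    def test_small_panels_rejected_by_cost(self, sim_default):
        panel = MarkerPanel.from_names([sim_default.loci[0]], list(sim_default.loci))
        with pytest.raises(ValueError, match=">= 2"):
            accuracy_loss(sim_default, panel)


class TestEvaluatorProperties:
    def test_distance_depends_only_on_included_loci(self, sim_default):
        G = sim_default
        mask = np.zeros(G.n_loci, dtype=bool)
        mask[:4] = True
        d1 = PanelEvaluator(G).pair_distances(mask)
        # scramble the data of every excluded locus
        calls = G.calls.copy()
        rng = np.random.default_rng(3)
        calls[:, ~mask, :] = rng.integers(1, 30, size=calls[:, ~mask, :].shape)
        G2 = GenotypeMatrix(G.individuals, G.populations, G.loci, calls)
        d2 = PanelEvaluator(G2).pair_distances(mask)
        assert np.allclose(d1, d2, equal_nan=True)

    def test_allele_relabeling_invariance(self, sim_default):
        G = sim_default
        relabeled = GenotypeMatrix(
            G.individuals, G.populations, G.loci,
            np.where(G.calls > 0, G.calls + 1000, 0),
        )
        full = np.ones(G.n_loci, dtype=bool)
        assert np.allclose(
            PanelEvaluator(G).pair_distances(full),
            PanelEvaluator(relabeled).pair_distances(full),
            equal_nan=True,
        )

    def test_adding_identical_frequency_locus_shrinks_distance(self):
        # a locus with equal frequencies in both groups moves the ratio
        # toward 1, so D can only decrease or stay
        rng = np.random.default_rng(9)
        for _ in range(10):
            p2 = rng.dirichlet(np.ones(4))
            calls = np.zeros((40, 2, 2), dtype=np.int64)
            calls[:20, 0, :] = rng.choice([1, 2], p=[0.9, 0.1], size=(20, 2))
            calls[20:, 0, :] = rng.choice([1, 2], p=[0.2, 0.8], size=(20, 2))
            shared = rng.choice(np.arange(1, 5), p=p2, size=(40, 2))
            calls[:, 1, :] = np.concatenate([shared[:20], shared[:20]])
            G = GenotypeMatrix(
                [f"i{j}" for j in range(40)],
                ["A"] * 20 + ["B"] * 20,
                ["mk1", "mk2"],
                calls,
            )
            ev = PanelEvaluator(G)
            d_one = ev.pair_distances(np.array([True, False]))[0]
            d_both = ev.pair_distances(np.array([True, True]))[0]
            assert d_both <= d_one + 1e-12

    def test_batch_loss_matches_scalar_loss(self, sim_default):
        ev = PanelEvaluator(sim_default)
        rng = np.random.default_rng(4)
        masks = rng.random((8, sim_default.n_loci)) < 0.5
        masks[:, :2] = True
        batch = ev.batch_loss(masks)
        singles = [ev.loss(m) for m in masks]
        assert np.allclose(batch, singles)
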