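"""Ant colony engine: pheromones, construction, updates, search, oracle."""

import numpy as np
import pytest

from msatpanel import (
    ACOConfig,
    PanelEvaluator,
    aco_select_fixed_n,
    aco_select_margin,
    construct_solution,
    exhaustive_optimum,
    init_pheromones,
    update_pheromones,
)
from msatpanel.aco import PHEROMONE_EPS, PheromoneState, _batch_construct


class TestInitPheromones:
    def test_pic_mode_equal_pic_is_symmetric(self):
        ph = init_pheromones(5, "pic", np.full(5, 0.6))
        assert np.allclose(ph.tau_include, ph.tau_include[0])
        assert np.allclose(ph.tau_exclude, ph.tau_exclude[0])

    def test_pic_mode_monotone(self):
        ph = init_pheromones(2, "pic", np.array([0.95, 0.12]))
        assert ph.tau_include[0] > ph.tau_include[1]
        assert ph.tau_exclude[0] < ph.tau_exclude[1]
        assert ph.tau_include[0] == pytest.approx(PHEROMONE_EPS + 0.95)

    def test_random_mode_reproducible_and_bounded(self):
        a = init_pheromones(10, "random", rng=np.random.default_rng(3))
        b = init_pheromones(10, "random", rng=np.random.default_rng(3))
        assert np.array_equal(a.tau_include, b.tau_include)
        assert (a.tau_include >= PHEROMONE_EPS).all() and (a.tau_include <= 1).all()

    def test_pic_mode_requires_values(self):
        with pytest.raises(ValueError, match="PIC value per locus"):
            init_pheromones(3, "pic")


class TestConstruction:
    # enough loci that the >= 2-locus resampling floor is negligible and
    # does not condition the per-locus inclusion frequencies
    def test_free_mode_half_probability_when_balanced(self):
        ph = PheromoneState(np.full(16, 0.4), np.full(16, 0.4))
        rng = np.random.default_rng(0)
        masks = _batch_construct(ph, 0.7, 10_000, None, rng)
        freq = masks.mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(freq - 0.5) < 3.5 * se + 1e-9)

    def test_free_mode_matches_tau_alpha_formula(self):
        tau_i = np.tile([0.9, 0.2, 0.5, 0.75], 4)
        tau_e = np.tile([0.1, 0.8, 0.5, 0.25], 4)
        alpha = 0.7
        ph = PheromoneState(tau_i, tau_e)
        expected = tau_i**alpha / (tau_i**alpha + tau_e**alpha)
        masks = _batch_construct(ph, alpha, 20_000, None, np.random.default_rng(1))
        freq = masks.mean(axis=0)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert np.all(np.abs(freq - expected) < 3.5 * se + 1e-9)

    def test_fixed_n_full_is_forced(self):
        ph = init_pheromones(5, "random", rng=np.random.default_rng(2))
        panel = construct_solution(ph, N=5, rng=np.random.default_rng(0))
        assert panel.size == 5

    def test_fixed_n_exact_size(self):
        ph = init_pheromones(9, "random", rng=np.random.default_rng(2))
        masks = _batch_construct(ph, 0.7, 500, 3, np.random.default_rng(0))
        assert (masks.sum(axis=1) == 3).all()

    def test_minimum_two_loci_enforced(self):
        # exclude trail overwhelming: free mode would draw empty panels
        ph = PheromoneState(np.full(4, 1e-3 + PHEROMONE_EPS), np.full(4, 1.0))
        masks = _batch_construct(ph, 3.0, 200, None, np.random.default_rng(0))
        assert (masks.sum(axis=1) >= 2).all()


class TestUpdate:
    def test_pure_evaporation_scales_by_decay(self):
        ph = PheromoneState(np.full(4, 0.5), np.full(4, 0.5))
        cfg = ACOConfig(ant_n=10, elite_fraction=0.1)
        sol = [(np.zeros(4, dtype=bool) | np.array([1, 1, 0, 0], bool), 100.0)]
        out = update_pheromones(ph, sol, cfg)  # deposit is 0 at loss 100
        assert np.allclose(out.tau_include, 0.45)

    def test_zero_loss_deposits_full_quantum(self):
        # a zero-loss panel has quality 1; a single-member elite deposits
        # the full EMA quantum (1 - decay) on its own edges
        ph = PheromoneState(np.full(4, 0.5), np.full(4, 0.5))
        cfg = ACOConfig(ant_n=5, elite_fraction=0.2)  # elite of exactly 1
        mask = np.array([True, False, True, False])
        out = update_pheromones(ph, [(mask, 0.0), (~mask, 50.0)], cfg)
        assert np.allclose(out.tau_include[mask], 0.45 + 0.1)
        assert np.allclose(out.tau_include[~mask], 0.45)
        assert np.allclose(out.tau_exclude[~mask], 0.45 + 0.1)

    def test_duplicate_panels_deposit_once(self):
        ph = PheromoneState(np.full(4, 0.5), np.full(4, 0.5))
        cfg = ACOConfig(ant_n=4, elite_fraction=0.5)  # elite of 2
        mask = np.array([True, True, False, False])
        other = np.array([False, False, True, True])
        dup = update_pheromones(ph, [(mask, 0.0), (mask, 0.0)], cfg)
        # the duplicate is dropped: one distinct panel, full quantum once
        assert np.allclose(dup.tau_include[mask], 0.45 + 0.1)
        mixed = update_pheromones(ph, [(mask, 0.0), (other, 0.0)], cfg)
        # two distinct panels split the quantum
        assert np.allclose(mixed.tau_include[mask], 0.45 + 0.05)

    def test_better_elite_leaves_more_pheromone(self):
        ph = PheromoneState(np.full(3, 0.5), np.full(3, 0.5))
        cfg = ACOConfig(ant_n=5, elite_fraction=0.2)
        mask = np.array([True, True, False])
        good = update_pheromones(ph, [(mask, 5.0), (mask, 60.0)], cfg)
        bad = update_pheromones(ph, [(mask, 60.0), (mask, 60.0)], cfg)
        assert (good.tau_include[mask] > bad.tau_include[mask]).all()

    def test_pheromones_stay_positive_forever(self):
        ph = init_pheromones(6, "random", rng=np.random.default_rng(1))
        cfg = ACOConfig(ant_n=4, elite_fraction=0.25)
        mask = np.zeros(6, dtype=bool)
        mask[:2] = True
        for _ in range(300):
            ph = update_pheromones(ph, [(mask, 100.0)], cfg)  # zero deposit
            assert (ph.tau_include > 0).all() and (ph.tau_exclude > 0).all()
        assert np.allclose(ph.tau_include, PHEROMONE_EPS)


class TestSearch:
    def test_full_size_gives_zero_loss(self, sim_default):
        cfg = ACOConfig(ant_n=5, epochs=2)
        res = aco_select_fixed_n(sim_default, sim_default.n_loci, cfg, seed=0)
        assert res.loss == 0.0 and res.panel.size == sim_default.n_loci

    def test_seed_reproducibility(self, sim_default):
        cfg = ACOConfig(ant_n=10, epochs=10)
        a = aco_select_fixed_n(sim_default, 5, cfg, seed=42)
        b = aco_select_fixed_n(sim_default, 5, cfg, seed=42)
        assert a.panel == b.panel
        assert np.array_equal(a.trace, b.trace)

    def test_trace_monotone_non_increasing(self, sim_default):
        cfg = ACOConfig(ant_n=10, epochs=30)
        res = aco_select_fixed_n(sim_default, 4, cfg, seed=1)
        assert (np.diff(res.trace) <= 1e-15).all()
        assert res.trace[-1] == pytest.approx(res.loss)

    def test_matches_exhaustive_on_small_instance(self, sim_default):
        ev = PanelEvaluator(sim_default)
        opt = exhaustive_optimum(ev, N=5)
        res = aco_select_fixed_n(sim_default, 5, ACOConfig(), seed=3)
        assert res.loss == pytest.approx(ev.loss(opt.mask), abs=1e-9)

    def test_margin_larger_than_any_loss_gives_floor_panel(self, sim_default):
        cfg = ACOConfig(ant_n=20, epochs=15)
        res = aco_select_margin(sim_default, margin=1e6, config=cfg, seed=0)
        assert res.panel.size == 2

    def test_margin_zero_returns_full_with_warning(self, sim_default):
        with pytest.warns(UserWarning, match="degenerate"):
            res = aco_select_margin(sim_default, margin=0.0, seed=0)
        assert res.panel.size == sim_default.n_loci and res.loss == 0.0


class TestExhaustive:
    def test_enumerates_three_panels(self):
        import itertools

        from msatpanel import GenotypeMatrix

        rng = np.random.default_rng(0)
        calls = rng.integers(1, 5, size=(30, 3, 2))
        G = GenotypeMatrix(
            [f"i{j}" for j in range(30)],
            ["A"] * 15 + ["B"] * 15,
            ["x", "y", "z"],
            calls,
        )
        ev = PanelEvaluator(G)
        opt = exhaustive_optimum(ev, N=2)
        losses = {}
        for pair in itertools.combinations(range(3), 2):
            m = np.zeros(3, dtype=bool)
            m[list(pair)] = True
            losses[pair] = ev.loss(m)
        best = min(losses, key=losses.get)
        assert set(np.flatnonzero(opt.mask)) == set(best)

    def test_locus_permutation_equivariance(self, sim_default):
        G = sim_default
        opt = exhaustive_optimum(G, N=4)
        perm = list(np.random.default_rng(7).permutation(G.n_loci))
        G2 = G.subset_loci([G.loci[i] for i in perm])
        opt2 = exhaustive_optimum(G2, N=4)
        assert set(opt.included) == set(opt2.included)

    def test_refuses_large_k(self):
        from msatpanel import SimConfig, simulate_genotypes

        G = simulate_genotypes(SimConfig(n_pops=2, n_per_pop=4, n_loci=21, seed=0))
        with pytest.raises(ValueError, match="refused"):
            exhaustive_optimum(G, N=2)

    def test_requires_exactly_one_mode(self, sim_default):
        with pytest.raises(ValueError, match="exactly one"):
            exhaustive_optimum(sim_default, N=3, margin=5.0)
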