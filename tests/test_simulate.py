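"""Ground-truth properties of the synthetic-data generators."""

import math

import numpy as np
import pytest

import lepimacro as lm
from lepimacro.dec import DECModel, build_state_space
from lepimacro.simmap import er_rate_matrix
from lepimacro.simulate import (
    SimulationConfig,
    simulate_bd_tree,
    simulate_dec_history,
    simulate_host_matrix,
    simulate_mk_traits,
    simulate_plant_tree,
)


class TestBirthDeathTree:
    def test_two_tips_is_cherry(self):
        t = simulate_bd_tree(2, 1.0, 0.0, lm.make_rng(0))
        assert t.n_tips == 2 and t.n_nodes == 3
        assert t.is_ultrametric()

    def test_yule_mean_root_age(self):
        # E[crown age] = sum_{k=2..n} 1/(lambda k) for the pure-birth process
        n, lam, reps = 10, 1.0, 2000
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        rng = lm.make_rng(7)
        ages = [simulate_bd_tree(n, lam, 0.0, rng).root_age for _ in range(reps)]
        # crown age is a sum of exponentials; SE from the sampled ages
        se = np.std(ages) / math.sqrt(reps)
        assert abs(np.mean(ages) - expected) < 3 * se

    def test_seeded_reproducibility(self):
        s1 = simulate_bd_tree(20, 0.5, 0.1, lm.make_rng(9)).to_newick()
        s2 = simulate_bd_tree(20, 0.5, 0.1, lm.make_rng(9)).to_newick()
        assert s1 == s2

    def test_death_exceeding_birth_rejected(self):
        with pytest.raises(ValueError):
            simulate_bd_tree(5, 0.1, 0.2, lm.make_rng(0))

    def test_survival_conditioning_with_extinction(self):
        t = simulate_bd_tree(30, 0.5, 0.25, lm.make_rng(3))
        assert t.n_tips == 30
        assert t.is_ultrametric()


class TestMkTraits:
    def test_zero_rate_keeps_root_state(self, three_tip_tree):
        tips, nodes = simulate_mk_traits(
            three_tip_tree, np.zeros((2, 2)), root_state=1, rng=lm.make_rng(0)
        )
        assert set(tips.values()) == {"s1"}
        assert set(nodes.tolist()) == {1}

    def test_two_state_change_probability(self):
        # P(tip differs from root) over a branch of length t is (1-e^{-2rt})/2
        r, t, reps = 0.4, 1.5, 10_000
        expected = (1 - math.exp(-2 * r * t)) / 2
        tree = lm.read_newick(f"(A:{t},B:{t});")
        rng = lm.make_rng(11)
        q = er_rate_matrix(2, r)
        changed = 0
        for _ in range(reps):
            tips, _ = simulate_mk_traits(tree, q, root_state=0, rng=rng)
            changed += tips["A"] != "s0"
        se = math.sqrt(expected * (1 - expected) / reps)
        assert abs(changed / reps - expected) < 3 * se

    def test_invalid_rate_matrix(self, three_tip_tree):
        with pytest.raises(ValueError):
            simulate_mk_traits(three_tip_tree, np.ones((2, 2)), rng=lm.make_rng(0))

    def test_seeded_reproducibility(self, three_tip_tree):
        q = er_rate_matrix(3, 0.7)
        a = simulate_mk_traits(three_tip_tree, q, rng=lm.make_rng(5))
        b = simulate_mk_traits(three_tip_tree, q, rng=lm.make_rng(5))
        assert a[0] == b[0] and np.array_equal(a[1], b[1])


class TestHostMatrix:
    def test_forced_k_two_generalists(self, rng):
        cfg = SimulationConfig(n_tips=40, p_generalist=1.0, generalist_k=2)
        tree = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
        m, _, cls = simulate_host_matrix(tree, cfg, rng)
        counts = (m.weights > 0).sum(axis=1)
        assert np.all(counts == 2)
        assert set(cls.values()) == {"generalist"}

    def test_every_species_has_a_host(self, rng):
        cfg = SimulationConfig(n_tips=60)
        tree = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
        m, _, _ = simulate_host_matrix(tree, cfg, rng)
        assert np.all(m.weights.sum(axis=1) > 0)
        assert np.all(m.weights[m.weights > 0] >= 1)

    def test_specialist_fraction_calibrated(self):
        # realized generalist share matches p_generalist within a binomial CI
        cfg = SimulationConfig(n_tips=150, p_generalist=0.3)
        total, gen = 0, 0
        for seed in range(10):
            rng = lm.make_rng(300 + seed)
            tree = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
            _, _, cls = simulate_host_matrix(tree, cfg, rng)
            gen += sum(1 for c in cls.values() if c == "generalist")
            total += len(cls)
        se = math.sqrt(0.3 * 0.7 / total)
        assert abs(gen / total - 0.3) < 3 * se

    def test_noise_free_matrix_is_block_diagonal(self, rng):
        cfg = SimulationConfig(
            n_tips=30, n_modules=3, n_hosts_per_module=2,
            p_generalist=0.0, noise_edge_prob=0.0,
        )
        tree = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
        m, true_mod, _ = simulate_host_matrix(tree, cfg, rng)
        for i, sp in enumerate(m.row_labels):
            cols = {m.col_labels[j].split("_")[0] for j in np.flatnonzero(m.weights[i])}
            assert cols == {f"H{true_mod[sp] + 1}"}

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig(n_tips=50)
        out = []
        for _ in range(2):
            rng = lm.make_rng(77)
            tree = simulate_bd_tree(cfg.n_tips, cfg.birth_rate, cfg.death_rate, rng)
            m, mods, cls = simulate_host_matrix(tree, cfg, rng)
            out.append((m.to_long().to_csv(index=False), mods, cls))
        assert out[0] == out[1]


class TestPlantTree:
    def test_modules_form_clades(self, rng):
        cfg = SimulationConfig(n_modules=5, n_hosts_per_module=3)
        pt = simulate_plant_tree(cfg, rng, crown_age=100.0, module_crown_age=10.0)
        assert pt.n_tips == 15
        assert pt.is_ultrametric()
        D, labels = pt.patristic_matrix()
        idx = {l: i for i, l in enumerate(labels)}
        for a in labels:
            for b in labels:
                if a == b:
                    continue
                d = D[idx[a], idx[b]]
                if a.split("_")[0] == b.split("_")[0]:
                    assert d <= 2 * 10.0 + 1e-6  # within-module: young clade
                else:
                    assert d > 2 * 10.0  # across modules: deep split


class TestDECHistory:
    def test_zero_rates_copy_root_range(self, three_tip_tree):
        space = build_state_space(["A", "B"])
        tips, truth = simulate_dec_history(
            three_tip_tree, DECModel(0.0, 0.0, space), lm.make_rng(0), root_range="A"
        )
        assert all(r == frozenset({"A"}) for r in tips.values())
        assert truth["events"] == []

    def test_expansion_waiting_time(self):
        # single branch, 1 of 2 adjacent areas occupied, e=0:
        # P(expanded by t) = 1 - exp(-d t)
        d, t, reps = 0.3, 2.0, 10_000
        space = build_state_space(["A", "B"])
        tree = lm.read_newick(f"(A:{t},B:{t});")
        model = DECModel(d, 0.0, space)
        rng = lm.make_rng(13)
        expanded = 0
        for _ in range(reps):
            tips, _ = simulate_dec_history(tree, model, rng, root_range="A")
            # the two branches are independent; use tip A's branch only
            expanded += tips["A"] == frozenset({"A", "B"})
        expect = 1 - math.exp(-d * t)
        se = math.sqrt(expect * (1 - expect) / reps)
        assert abs(expanded / reps - expect) < 3 * se

    def test_null_range_absorbing_and_flagged(self):
        space = build_state_space(["A", "B"])
        tree = lm.read_newick("(A:200,B:200);")
        tips, truth = simulate_dec_history(
            tree, DECModel(0.0, 0.05, space), lm.make_rng(2), root_range="A"
        )
        # with e >> 0 over 200 Ma both lineages die; tips flagged None
        assert tips["A"] is None and tips["B"] is None

    def test_seeded_reproducibility(self, three_tip_tree):
        space = build_state_space(["A", "B", "C"])
        model = DECModel(0.2, 0.05, space)
        a = simulate_dec_history(three_tip_tree, model, lm.make_rng(4))
        b = simulate_dec_history(three_tip_tree, model, lm.make_rng(4))
        assert a[0] == b[0] and a[1]["events"] == b[1]["events"]
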