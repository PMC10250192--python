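"""DEC range evolution: state spaces, likelihoods, mapping and rate summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

import lepimacro as lm
from lepimacro.dec import (
    DECModel,
    ancestral_ranges,
    biogeo_stochastic_map,
    build_state_space,
    cladogenesis_events,
    dec_loglik,
    dec_rate_matrix,
    fit_dec,
    lineage_area_counts,
    timesliced_rates,
)
from lepimacro.simulate import simulate_bd_tree, simulate_dec_history


def brute_force_dec_loglik(tree, tip_ranges, model):
    """Oracle: enumerate every internal-node range and cladogenetic event,
    with dense matrix exponentials for the branch transitions."""
    sp = model.space
    n = sp.n_states
    Q = dec_rate_matrix(sp, model.d, model.e)
    P = {v: expm(Q * tree.blen[v]) for v in range(1, tree.n_nodes)}
    events = {
        i: [(sp.index[l], sp.index[r], w)
            for l, r, w in cladogenesis_events(sp.ranges[i], sp, model.mode)]
        for i in range(n)
    }
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    tip_state = {v: sp.encode(tip_ranges[tree.labels[v]]) for v in tree.tip_indices}

    def subtree_lik(v, state):
        if not tree.children[v]:
            return 1.0 if tip_state[v] == state else 0.0
        x, y = tree.children[v]
        total = 0.0
        for l, r, w in events[state]:
            lx = sum(P[x][l, s] * subtree_lik(x, s) for s in range(n))
            ly = sum(P[y][r, s] * subtree_lik(y, s) for s in range(n))
            total += w * lx * ly
        return total

    lik = sum(subtree_lik(0, s) / n for s in range(n))
    return math.log(lik)


class TestStateSpace:
    def test_two_areas_full(self):
        sp = build_state_space(["A", "B"])
        assert [sp.range_label(i) for i in range(sp.n_states)] == ["A", "B", "A+B"]

    def test_path_adjacency_connectivity(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        sp = build_state_space(["A", "B", "C"], adjacency=adj, require_connected=True)
        labels = {sp.range_label(i) for i in range(sp.n_states)}
        assert labels == {"A", "B", "C", "A+B", "B+C", "A+B+C"}

    def test_seven_areas_unconstrained(self):
        sp = build_state_space(list("ABCDEFG"))
        assert sp.n_states == 127

    def test_max_size_caps_state_count(self):
        sp = build_state_space(list("ABCDE"), max_size=2)
        assert sp.n_states == 5 + 10

    def test_encode_rejects_disallowed(self):
        sp = build_state_space(["A", "B", "C"], max_size=1)
        with pytest.raises(KeyError):
            sp.encode("A;B")


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self):
        sp = build_state_space(["A", "B"])
        assert np.all(dec_rate_matrix(sp, 0.0, 0.0) == 0.0)

    def test_two_area_entries(self):
        sp = build_state_space(["A", "B"])
        d, e = 0.3, 0.07
        Q = dec_rate_matrix(sp, d, e)
        iA, iB, iAB = sp.encode("A"), sp.encode("B"), sp.encode("A;B")
        null = sp.n_states
        assert Q[iA, iAB] == pytest.approx(d)
        assert Q[iAB, iA] == pytest.approx(e)
        assert Q[iAB, iB] == pytest.approx(e)
        assert Q[iA, null] == pytest.approx(e)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(Q[null] == 0.0)

    def test_time_rate_rescaling_invariance(self):
        sp = build_state_space(["A", "B", "C"])
        Q1 = dec_rate_matrix(sp, 0.2, 0.05)
        Q2 = dec_rate_matrix(sp, 0.4, 0.10)
        np.testing.assert_allclose(expm(Q1 * 3.0), expm(Q2 * 1.5), atol=1e-12)


class TestCladogenesis:
    def test_single_area_identity(self):
        sp = build_state_space(["A", "B"])
        assert cladogenesis_events(frozenset({0}), sp) == [
            (frozenset({0}), frozenset({0}), 1.0)]

    def test_two_area_dec_event_set(self):
        sp = build_state_space(["A", "B"])
        evs = cladogenesis_events(frozenset({0, 1}), sp, "DEC")
        assert len(evs) == 6
        assert all(w == pytest.approx(1 / 6) for _, _, w in evs)
        pairs = {(tuple(sorted(l)), tuple(sorted(r))) for l, r, _ in evs}
        assert ((0,), (1,)) in pairs and ((0,), (0, 1)) in pairs

    def test_divalike_allows_wide_vicariance_only(self):
        sp = build_state_space(list("ABCD"))
        evs = cladogenesis_events(frozenset({0, 1, 2, 3}), sp, "DIVALIKE")
        sizes = {(len(l), len(r)) for l, r, _ in evs}
        assert (2, 2) in sizes  # both daughters multi-area
        assert all(len(l) + len(r) == 4 and not (l & r) for l, r, _ in evs)

    @pytest.mark.parametrize("mode", ["DEC", "DIVALIKE"])
    def test_weights_normalize(self, mode):
        sp = build_state_space(list("ABCD"))
        for i in range(sp.n_states):
            evs = cladogenesis_events(sp.ranges[i], sp, mode)
            assert sum(w for _, _, w in evs) == pytest.approx(1.0)


class TestLoglik:
    def test_no_event_case_is_flat_root_prior(self):
        sp = build_state_space(["A", "B"])
        tree = lm.read_newick("(A:1,B:1);")
        ll = dec_loglik(tree, {"A": "A", "B": "A"}, DECModel(0.0, 0.0, sp))
        assert ll == pytest.approx(math.log(1 / 3))

    @pytest.mark.parametrize("d,e,mode", [
        (0.1, 0.05, "DEC"), (0.3, 0.0, "DEC"), (0.05, 0.2, "DEC"),
        (0.1, 0.05, "DIVALIKE"),
    ])
    def test_matches_brute_force(self, three_tip_tree, d, e, mode):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "B", "C": "A;B"}
        model = DECModel(d, e, sp, mode)
        assert dec_loglik(three_tip_tree, tips, model) == pytest.approx(
            brute_force_dec_loglik(three_tip_tree, tips, model), abs=1e-8)

    def test_area_relabeling_invariance(self, three_tip_tree):
        sp = build_state_space(["A", "B", "C"])
        sp2 = build_state_space(["C", "A", "B"])
        tips = {"A": "A", "B": "A;B", "C": "C"}
        m1 = DECModel(0.1, 0.02, sp)
        m2 = DECModel(0.1, 0.02, sp2)
        assert dec_loglik(three_tip_tree, tips, m1) == pytest.approx(
            dec_loglik(three_tip_tree, tips, m2))

    def test_disallowed_tip_range_reported(self, three_tip_tree):
        sp = build_state_space(["A", "B"], max_size=1)
        with pytest.raises(KeyError):
            dec_loglik(three_tip_tree, {"A": "A", "B": "A;B", "C": "B"},
                       DECModel(0.1, 0.0, sp))

    def test_time_slices_reduce_to_unsliced_when_identical(self, three_tip_tree):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "B", "C": "A;B"}
        plain = DECModel(0.2, 0.05, sp)
        sliced = DECModel(0.2, 0.05, sp, "DEC", (1.2,),
                          (sp.adjacency, sp.adjacency))
        assert dec_loglik(three_tip_tree, tips, sliced) == pytest.approx(
            dec_loglik(three_tip_tree, tips, plain))


class TestFit:
    def test_identical_single_area_tips_pin_d_at_bound(self, rng):
        sp = build_state_space(["A", "B"])
        tree = simulate_bd_tree(20, 0.5, 0.0, rng)
        tips = {l: "A" for l in tree.tip_labels}
        model, ll, _ = fit_dec(tree, tips, sp)
        assert model.d <= 1e-6

    def test_recovery_single_replicate(self):
        sp = build_state_space(list("ABCD"))
        rng = lm.make_rng(42)
        tree = simulate_bd_tree(250, 0.1, 0.0, rng)
        tips, _ = simulate_dec_history(tree, DECModel(0.05, 0.01, sp), rng)
        model, _, _ = fit_dec(tree, tips, sp)
        assert 0.02 < model.d < 0.12
        assert 0.002 < model.e < 0.05


class TestAncestralRanges:
    def test_degenerate_model_certain_root(self):
        sp = build_state_space(["A", "B"])
        tree = lm.read_newick("(A:1,B:1);")
        marg, modal = ancestral_ranges(tree, {"A": "A", "B": "A"},
                                       DECModel(0.0, 0.0, sp))
        assert marg[0, sp.encode("A")] == pytest.approx(1.0)
        assert modal[0] == "A"

    def test_matches_enumeration_at_root(self, three_tip_tree):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "B", "C": "A;B"}
        model = DECModel(0.1, 0.05, sp)
        marg, _ = ancestral_ranges(three_tip_tree, tips, model)
        np.testing.assert_allclose(marg.sum(axis=1), 1.0)
        # root posterior by brute force: condition each root state
        n = sp.n_states
        post = np.zeros(n)
        for s in range(n):
            Q = dec_rate_matrix(sp, model.d, model.e)
            # likelihood of data given root state s, flat-prior weight 1/n
            model_fixed = model

            def subtree(v, state, tree=three_tip_tree):
                if not tree.children[v]:
                    return 1.0 if sp.encode(tips[tree.labels[v]]) == state else 0.0
                x, y = tree.children[v]
                tot = 0.0
                for l, r, w in cladogenesis_events(sp.ranges[state], sp):
                    li, ri = sp.index[l], sp.index[r]
                    lx = sum(expm(Q * tree.blen[x])[li, ss] * subtree(x, ss)
                             for ss in range(n))
                    ly = sum(expm(Q * tree.blen[y])[ri, ss] * subtree(y, ss)
                             for ss in range(n))
                    tot += w * lx * ly
                return tot

            post[s] = subtree(0, s) / n
        post /= post.sum()
        np.testing.assert_allclose(marg[0, :n], post, atol=1e-8)


class TestStochasticMapping:
    def test_zero_dispersal_zero_events(self, three_tip_tree):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "A", "C": "A"}
        model = DECModel(0.0, 0.0, sp)
        _, summary = biogeo_stochastic_map(three_tip_tree, tips, model, 50,
                                           lm.make_rng(0))
        assert summary.counts.sum() == 0.0

    def test_node_frequencies_match_marginals(self, three_tip_tree):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "B", "C": "A;B"}
        model = DECModel(0.1, 0.05, sp)
        marg, _ = ancestral_ranges(three_tip_tree, tips, model)
        _, summary = biogeo_stochastic_map(three_tip_tree, tips, model, 4000,
                                           lm.make_rng(1))
        se = np.sqrt(np.clip(marg * (1 - marg), 1e-12, None) / 4000)
        assert np.all(np.abs(summary.node_state_freq - marg) <= 3 * se + 1e-9)

    def test_event_conservation_across_bins(self, three_tip_tree):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "B", "C": "A;B"}
        model = DECModel(0.4, 0.1, sp)
        _, summary = biogeo_stochastic_map(three_tip_tree, tips, model, 500,
                                           lm.make_rng(2))
        sliced = timesliced_rates(summary, bin_width=0.5)
        np.testing.assert_allclose(
            sliced["bins"].sum(axis=0), summary.relative_mean_rates(), atol=1e-9)

    def test_mean_expansion_count_matches_forward_rejection(self):
        # single branch with range {A} at both ends: the uniformization
        # sampler against forward simulation + rejection on the endpoint
        from lepimacro.ctmc import CTMCPropagator
        sp = build_state_space(["A", "B"])
        d, e, t = 0.4, 0.2, 2.0
        prop = CTMCPropagator(dec_rate_matrix(sp, d, e))
        iA0, n0 = sp.encode("A"), sp.n_states
        rng_c = lm.make_rng(3)
        cond = []
        for _ in range(3000):
            segs = prop.sample_path(iA0, iA0, t, rng_c)
            nexp = sum(
                1 for (s1, _), (s2, _) in zip(segs, segs[1:])
                if s2 < n0 and s1 < n0 and len(sp.ranges[s2]) > len(sp.ranges[s1])
            )
            cond.append(nexp)
        cond_mean = np.mean(cond)
        # forward-rejection oracle on one branch
        rng = lm.make_rng(4)
        Q = dec_rate_matrix(sp, d, e)
        iA, n = sp.encode("A"), sp.n_states
        kept = []
        while len(kept) < 3000:
            s, left, nexp = iA, t, 0
            while True:
                rate = -Q[s, s]
                if rate <= 0:
                    break
                dt = rng.exponential(1 / rate)
                if dt >= left:
                    break
                left -= dt
                probs = np.clip(Q[s], 0, None)
                probs[s] = 0
                new = int(rng.choice(n + 1, p=probs / probs.sum()))
                if new < n and len(sp.ranges[new]) > len(sp.ranges[s]):
                    nexp += 1
                s = new
                if s == n:
                    break
            if s == iA:
                kept.append(nexp)
        se = np.std(kept) / math.sqrt(len(kept))
        se_c = np.std(cond) / math.sqrt(len(cond))
        assert abs(cond_mean - np.mean(kept)) < 3 * math.hypot(se, se_c)

    def test_div100_display_scaling(self, three_tip_tree):
        sp = build_state_space(["A", "B"])
        tips = {"A": "A", "B": "B", "C": "A;B"}
        _, summary = biogeo_stochastic_map(
            three_tip_tree, tips, DECModel(0.3, 0.05, sp), 200, lm.make_rng(5))
        np.testing.assert_allclose(
            summary.relative_mean_rates(div100=True) * 100.0,
            summary.relative_mean_rates())


class TestTimeslicedRates:
    def _summary(self, times):
        from lepimacro.dec import DispersalSummary
        k = len(times)
        return DispersalSummary(
            areas=("A", "B"),
            counts=np.zeros((1, 2, 2)),
            event_sim=np.zeros(k, int),
            event_time=np.asarray(times, float),
            event_src=np.zeros(k, int),
            event_dst=np.ones(k, int),
            event_weight=np.ones(k),
        )

    def test_all_recent_events_in_first_bin(self):
        out = timesliced_rates(self._summary([2.0, 2.0, 1.0]), bin_width=5.0)
        assert out["bins"].shape[0] == 1
        assert out["bins"][0, 0, 1] == pytest.approx(3.0)

    def test_boundary_event_goes_to_older_bin(self):
        out = timesliced_rates(self._summary([5.0]), bin_width=5.0)
        assert out["bins"][1, 0, 1] == pytest.approx(1.0)

    def test_period_average_of_identical_bins(self):
        out = timesliced_rates(
            self._summary([1.0, 6.0]), bin_width=5.0,
            periods={"P": (0.0, 10.0)})
        np.testing.assert_allclose(out["periods"]["P"],
                                   (out["bins"][0] + out["bins"][1]) / 2)


def test_lineage_area_counts_trivial(three_tip_tree):
    sp = build_state_space(["A", "B"])
    model = DECModel(0.0, 0.0, sp)
    marg, _ = ancestral_ranges(three_tip_tree, {"A": "A", "B": "A", "C": "A"}, model)
    counts = lineage_area_counts(three_tip_tree, marg, model, [0.5, 1.5])
    np.testing.assert_allclose(counts[:, 0], [3.0, 2.0])
    np.testing.assert_allclose(counts[:, 1], 0.0)
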