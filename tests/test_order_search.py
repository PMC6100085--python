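"""Order distance, clustering, BSO operators and the three searchers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from k2bso import (
    BSOConfig,
    Order,
    Population,
    ScoreCache,
    StepSize,
    bso_search,
    cluster_orders,
    forward_sample,
    ga_search,
    merge_orders,
    order_distance,
    perturb_order,
    random_search,
    score_order,
    step_size,
)


def kendall_disagreements(r1: Order, r2: Order) -> int:
    """Brute-force oracle: count unordered pairs on whose relative order
    the two permutations disagree."""
    pos1, pos2 = r1.position(), r2.position()
    names = list(r1.sequence)
    count = 0
    for u, v in itertools.combinations(names, 2):
        if (pos1[u] < pos1[v]) != (pos2[u] < pos2[v]):
            count += 1
    return count


class TestOrderDistance:
    def test_identical_orders(self):
        r = Order(tuple("ABCDE"))
        assert order_distance(r, r) == 0

    def test_reversal_is_maximal(self):
        assert order_distance(Order(("A", "B", "C")), Order(("C", "B", "A"))) == 3

    def test_adjacent_swap(self):
        assert order_distance(Order(("A", "B", "C")), Order(("A", "C", "B"))) == 1

    def test_mismatched_name_sets_raise(self):
        with pytest.raises(ValueError):
            order_distance(Order(("A", "B")), Order(("A", "C")))

    def test_equals_pair_disagreement_oracle_exhaustively(self):
        """Prefix-overlap distance equals the Kendall-tau disagreement
        count on every permutation pair for n <= 4."""
        for n in (2, 3, 4):
            names = tuple("ABCD"[:n])
            for p1 in itertools.permutations(names):
                for p2 in itertools.permutations(names):
                    r1, r2 = Order(p1), Order(p2)
                    assert order_distance(r1, r2) == kendall_disagreements(r1, r2)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(2, 15), st.integers(0, 2**31 - 1))
    def test_metric_axioms_random_pairs(self, n, seed):
        rng = np.random.default_rng(seed)
        names = [f"v{i}" for i in range(n)]
        r1 = Order(tuple(np.array(names)[rng.permutation(n)]))
        r2 = Order(tuple(np.array(names)[rng.permutation(n)]))
        d = order_distance(r1, r2)
        assert 0 <= d <= n * (n - 1) // 2
        assert d == order_distance(r2, r1)
        assert (d == 0) == (r1.sequence == r2.sequence)
        assert d == kendall_disagreements(r1, r2)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        names = [f"v{i}" for i in range(8)]
        for _ in range(100):
            a, b, c = (
                Order(tuple(np.array(names)[rng.permutation(8)])) for _ in range(3)
            )
            assert order_distance(a, c) <= order_distance(a, b) + order_distance(b, c)


class TestClustering:
    def _pop(self, orders, scores):
        return Population(members=orders, scores=scores)

    def test_singleton_clusters(self):
        rng = np.random.default_rng(0)
        names = list("ABCDE")
        orders = [Order(tuple(np.array(names)[rng.permutation(5)])) for _ in range(4)]
        pop = cluster_orders(self._pop(orders, [1.0, 2.0, 3.0, 4.0]), 4, seed=0)
        assert sorted(pop.cluster_of) == [0, 1, 2, 3]
        assert sorted(pop.centers) == [0, 1, 2, 3]

    def test_planted_bundles_separate(self):
        """Two bundles of small perturbations around distant seed orders
        land in distinct clusters in at least 9/10 seeds."""
        names = [f"v{i}" for i in range(10)]
        seed_a = Order(tuple(names))
        seed_b = Order(tuple(reversed(names)))
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            members = []
            for base in (seed_a, seed_b):
                members.append(base)
                for _ in range(4):
                    members.append(perturb_order(base, StepSize(1e-9), rng))
            pop = cluster_orders(
                self._pop(members, [0.0] * 10), 2, seed=seed
            )
            labels = pop.cluster_of
            ok = len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
            ok = ok and labels[0] != labels[5]
            hits += ok
        assert hits >= 9

    def test_center_is_best_scoring_member(self):
        rng = np.random.default_rng(1)
        names = list("ABCDEF")
        orders = [Order(tuple(np.array(names)[rng.permutation(6)])) for _ in range(12)]
        scores = list(rng.normal(size=12))
        pop = cluster_orders(self._pop(orders, scores), 3, seed=5)
        for c in range(3):
            members = pop.cluster_members(c)
            assert pop.centers[c] in members
            assert scores[pop.centers[c]] == max(scores[i] for i in members)

    def test_invariant_to_member_shuffling(self):
        """The partition (as sets of orders) survives shuffling the
        member list, up to cluster relabeling."""
        rng = np.random.default_rng(2)
        names = [f"v{i}" for i in range(8)]
        seed_a, seed_b = Order(tuple(names)), Order(tuple(reversed(names)))
        members, scores = [], []
        for base in (seed_a, seed_b):
            for _ in range(5):
                members.append(perturb_order(base, StepSize(1e-9), rng))
                scores.append(float(rng.normal()))
        pop1 = cluster_orders(self._pop(members, scores), 2, seed=3)
        shuffle = rng.permutation(10)
        pop2 = cluster_orders(
            self._pop([members[i] for i in shuffle], [scores[i] for i in shuffle]),
            2,
            seed=3,
        )
        parts1 = {
            frozenset(members[i].sequence for i in pop1.cluster_members(c)) for c in range(2)
        }
        parts2 = {
            frozenset(pop2.members[i].sequence for i in pop2.cluster_members(c))
            for c in range(2)
        }
        assert parts1 == parts2

    def test_too_many_clusters_raise(self):
        pop = self._pop([Order(("A", "B"))], [0.0])
        with pytest.raises(ValueError):
            cluster_orders(pop, 2, seed=0)
        with pytest.raises(ValueError):
            cluster_orders(pop, 0, seed=0)


class TestStepSize:
    def test_midpoint_halves_the_draw(self):
        cfg = BSOConfig(max_iteration=100, slope_k=10.0)
        rng = np.random.default_rng(0)
        draws = [step_size(cfg, 50, rng).xi for _ in range(1000)]
        assert max(draws) <= 0.5  # logsig(0) = 1/2 caps the weight
        assert np.mean(draws) == pytest.approx(0.25, abs=0.02)

    def test_late_iterations_shrink(self):
        cfg = BSOConfig(max_iteration=100, slope_k=1.0)
        rng = np.random.default_rng(1)
        late = [step_size(cfg, 100, rng).xi for _ in range(200)]
        assert max(late) < 1e-9  # sigmoid tail at -50

    def test_monte_carlo_expectation_matches_closed_form(self):
        """At iteration 0 with max_iteration=100, k=10 the expectation is
        logsig(5)/2 ~= 0.4967."""
        cfg = BSOConfig(max_iteration=100, slope_k=10.0)
        rng = np.random.default_rng(2)
        draws = [step_size(cfg, 0, rng).xi for _ in range(100_000)]
        expected = 0.5 / (1.0 + np.exp(-5.0))
        assert np.mean(draws) == pytest.approx(expected, abs=0.01)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            BSOConfig(slope_k=0.0)


class TestPerturb:
    def test_minimum_one_move(self):
        base = Order(tuple(f"v{i}" for i in range(10)))
        rng = np.random.default_rng(0)
        for _ in range(50):
            out = perturb_order(base, StepSize(1e-12), rng)
            # a single insertion move changes at most n-1 pair precedences
            assert order_distance(base, out) <= 9

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(2, 12), st.floats(1e-9, 1 - 1e-9), st.integers(0, 2**31 - 1))
    def test_output_is_permutation(self, n, xi, seed):
        base = Order(tuple(f"v{i}" for i in range(n)))
        out = perturb_order(base, StepSize(xi), np.random.default_rng(seed))
        assert sorted(out.sequence) == sorted(base.sequence)

    def test_expected_distance_monotone_in_step(self):
        """Mean displacement grows with xi (Spearman rho > 0.9 on a grid)."""
        base = Order(tuple(f"v{i}" for i in range(20)))
        rng = np.random.default_rng(4)
        grid = [0.05, 0.15, 0.3, 0.5, 0.7, 0.9]
        means = []
        for xi in grid:
            dists = [
                order_distance(base, perturb_order(base, StepSize(xi), rng))
                for _ in range(200)
            ]
            means.append(np.mean(dists))
        rho, _ = spearmanr(grid, means)
        assert rho > 0.9


class TestMerge:
    def test_idempotent(self):
        r = Order(tuple("ABCDE"))
        assert merge_orders(r, r, np.random.default_rng(0)).sequence == r.sequence

    def test_reversed_pair_keys_all_tie(self):
        """Merging (A,B,C) with (C,B,A): every key ties at 1.0, so the
        jitter makes each of the 3! outputs possible; B's key is exactly
        1 and A, C are symmetric."""
        r1, r2 = Order(("A", "B", "C")), Order(("C", "B", "A"))
        seen = set()
        for seed in range(200):
            out = merge_orders(r1, r2, np.random.default_rng(seed))
            seen.add(out.sequence)
        assert seen <= set(itertools.permutations(("A", "B", "C")))
        assert len(seen) == 6  # all orderings occur under the tie-break jitter

    def test_merged_order_lies_between_parents(self):
        """distance(merge, parent) <= distance(parent, parent) in >= 95%
        of 100 random n=10 pairs."""
        rng = np.random.default_rng(5)
        names = [f"v{i}" for i in range(10)]
        ok = 0
        for _ in range(100):
            r1 = Order(tuple(np.array(names)[rng.permutation(10)]))
            r2 = Order(tuple(np.array(names)[rng.permutation(10)]))
            m = merge_orders(r1, r2, rng)
            d12 = order_distance(r1, r2)
            if order_distance(m, r1) <= d12 and order_distance(m, r2) <= d12:
                ok += 1
        assert ok >= 95


class TestSearchers:
    def test_bso_trace_non_decreasing_and_deterministic(self, chain5_data):
        cfg = BSOConfig(pop_size=10, n_clusters=3, max_iteration=15, seed=3)
        o1, s1, t1 = bso_search(chain5_data, cfg, 3)
        o2, s2, t2 = bso_search(chain5_data, cfg, 3)
        assert o1.sequence == o2.sequence and s1 == s2
        best = [row["best_score"] for row in t1]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_bso_score_matches_recomputation(self, chain5_data):
        cfg = BSOConfig(pop_size=10, n_clusters=3, max_iteration=10, seed=1)
        order, score, _ = bso_search(chain5_data, cfg, 3)
        assert score == pytest.approx(score_order(chain5_data, order, 3), abs=1e-9)

    def test_bso_finds_exhaustive_optimum_on_chain(self, chain5_data):
        """On the 5-variable chain the returned score equals the
        exhaustive best over all 120 orders in >= 8/10 seeds."""
        cache = ScoreCache()
        exhaustive = max(
            score_order(chain5_data, Order(p), 3, cache)
            for p in itertools.permutations(chain5_data.columns)
        )
        hits = 0
        for seed in range(10):
            cfg = BSOConfig(pop_size=20, n_clusters=4, max_iteration=50, seed=seed)
            _, score, _ = bso_search(chain5_data, cfg, 3)
            hits += abs(score - exhaustive) < 1e-9
        assert hits >= 8

    def test_random_search_single_variable_terminates(self):
        from k2bso import DiscreteDataset

        data = DiscreteDataset(["A"], np.array([[0], [1], [0]]), [2])
        order, score = random_search(data, batch=2, seed=0)
        assert order.sequence == ("A",)
        assert score == pytest.approx(score_order(data, order))

    def test_random_search_deterministic(self, chain5_data):
        a = random_search(chain5_data, batch=10, max_parents=3, seed=4, max_evaluations=200)
        b = random_search(chain5_data, batch=10, max_parents=3, seed=4, max_evaluations=200)
        assert a[0].sequence == b[0].sequence and a[1] == b[1]

    def test_random_search_covers_small_space(self):
        """With an ever-growing batch over 3! orders, the unique optimum
        is found (geometric coverage)."""
        from k2bso import DiscreteDataset, Network

        net = Network(
            ["A", "B"],
            [2, 2],
            {"A": [], "B": ["A"]},
            {"A": np.array([[0.5, 0.5]]), "B": np.array([[0.95, 0.05], [0.05, 0.95]])},
        )
        data = forward_sample(net, 1000, seed=0)
        cache = ScoreCache()
        best = max(
            score_order(data, Order(p), 1, cache)
            for p in itertools.permutations(data.columns)
        )
        _, score = random_search(data, batch=30, max_parents=1, seed=1)
        assert score == pytest.approx(best, abs=1e-9)

    def test_ga_zero_generations_is_initial_best(self, chain5_data):
        order, score = ga_search(chain5_data, pop_size=8, generations=0, max_parents=3, seed=7)
        # recompute the initial population the same way the searcher does
        names = list(chain5_data.columns)
        rng = np.random.default_rng(7)
        members = [Order.random(names, rng) for _ in range(8)]
        scores = [score_order(chain5_data, o, 3) for o in members]
        assert score == pytest.approx(max(scores), abs=1e-9)

    def test_ga_score_matches_recomputation(self, chain5_data):
        order, score = ga_search(chain5_data, pop_size=10, generations=8, max_parents=3, seed=2)
        assert score == pytest.approx(score_order(chain5_data, order, 3), abs=1e-9)

    def test_ga_not_worse_than_random_at_matched_budget(self, chain5_data):
        """Paired comparison on the chain task: GA at pop 20 for 50
        generations vs random restarts at the same evaluation budget."""
        budget = 20 * 50
        ga_scores, rnd_scores = [], []
        for seed in range(10):
            _, g = ga_search(
                chain5_data, pop_size=20, generations=50, max_parents=3,
                seed=seed, max_evaluations=budget,
            )
            _, r = random_search(
                chain5_data, batch=20, max_parents=3, seed=seed, max_evaluations=budget
            )
            ga_scores.append(g)
            rnd_scores.append(r)
        assert np.mean(ga_scores) >= np.mean(rnd_scores) - 1e-9
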