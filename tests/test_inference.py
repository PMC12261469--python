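import numpy as np
import pytest

from recombmix import (
    MISSING,
    PenaltyParams,
    QuerySet,
    build_compact_graph,
    enumerate_paths_oracle,
    infer_path,
    infer_queryset,
    site_population_mismatch,
)
from recombmix.graph import CompactPopulationGraph

from conftest import (
    make_panel,
    make_sites,
    random_graph,
    random_penalties,
    uniform_penalties,
)


def graph_from_node_sets(node_sets, p):
    n = len(node_sets)
    presence = np.zeros((n, 2, p), dtype=bool)
    for j, pairs in enumerate(node_sets):
        for a, l in pairs:
            presence[j, a, l] = True
    return CompactPopulationGraph(
        presence=presence,
        sites=make_sites(n),
        population_names=[f"P{i}" for i in range(p)],
    )


class TestSitePopulationMismatch:
    def test_definition_instance(self):
        g = graph_from_node_sets([{(0, 0), (1, 0), (0, 1)}], p=2)
        np.testing.assert_array_equal(
            site_population_mismatch(g, np.array([1])), [[0.0, 1.0]]
        )

    def test_shared_allele_gives_zero_row(self):
        g = graph_from_node_sets([{(0, 0), (0, 1), (1, 1)}], p=2)
        np.testing.assert_array_equal(
            site_population_mismatch(g, np.array([0])), [[0.0, 0.0]]
        )

    def test_missing_query_allele_is_uninformative(self):
        g = graph_from_node_sets([{(0, 0), (1, 1)}], p=2)
        np.testing.assert_array_equal(
            site_population_mismatch(g, np.array([MISSING])), [[0.0, 0.0]]
        )

    def test_population_with_no_node_costs_missing_population_cost(self):
        g = graph_from_node_sets([{(0, 0)}], p=2)
        np.testing.assert_array_equal(
            site_population_mismatch(g, np.array([0])), [[0.0, 1.0]]
        )
        params = PenaltyParams(missing_population_cost=0.25)
        np.testing.assert_array_equal(
            site_population_mismatch(g, np.array([0]), params), [[0.0, 0.25]]
        )

    def test_length_mismatch_errors(self):
        g = graph_from_node_sets([{(0, 0), (0, 1)}], p=2)
        with pytest.raises(ValueError, match="length"):
            site_population_mismatch(g, np.array([0, 0]))


class TestInferPath:
    def test_perfect_copy(self, two_pop_panel):
        g = build_compact_graph(two_pop_panel)
        painting = infer_path(g, uniform_penalties(8), np.zeros(8, dtype=np.int8))
        np.testing.assert_array_equal(painting.labels, np.zeros(8))
        assert painting.total_cost == 0.0

    def test_single_switch_costs_w_times_penalty(self, two_pop_panel):
        g = build_compact_graph(two_pop_panel)
        query = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
        painting = infer_path(g, uniform_penalties(8, 2.0), query, PenaltyParams(w=1.5))
        np.testing.assert_array_equal(painting.labels, [0] * 4 + [1] * 4)
        assert painting.total_cost == pytest.approx(3.0)
        assert painting.mismatch_cost_sum == 0.0
        assert painting.switch_cost_sum == pytest.approx(2.0)

    def test_oracle_tie_example(self):
        # two sites disagree on the best population; switching costs 3
        g = graph_from_node_sets([{(0, 0), (1, 1)}, {(1, 0), (0, 1)}], p=2)
        pen = uniform_penalties(2, 2.0)
        params = PenaltyParams(w=1.5)
        cost, labels = enumerate_paths_oracle(g, pen, np.array([0, 0]), params)
        assert cost == 1.0
        np.testing.assert_array_equal(labels, [0, 0])
        painting = infer_path(g, pen, np.array([0, 0]), params)
        assert painting.total_cost == 1.0
        np.testing.assert_array_equal(painting.labels, [0, 0])

    def test_oracle_equivalence_randomized(self, rng):
        for trial in range(200):
            g = random_graph(rng, n=int(rng.integers(2, 11)), p=int(rng.integers(2, 4)))
            pen = random_penalties(rng, g.n_sites)
            query = rng.integers(0, 2, g.n_sites)
            params = PenaltyParams(w=float(rng.choice([0.5, 1.5, 3.0])))
            cost_o, labels_o = enumerate_paths_oracle(g, pen, query, params)
            painting = infer_path(g, pen, query, params)
            assert painting.total_cost == pytest.approx(cost_o, abs=1e-9)
            np.testing.assert_array_equal(painting.labels, labels_o)

    def test_cost_decomposition(self, rng):
        for _ in range(30):
            g = random_graph(rng, n=20)
            pen = random_penalties(rng, 20)
            params = PenaltyParams(w=float(rng.uniform(0.1, 3.0)))
            painting = infer_path(g, pen, rng.integers(0, 2, 20), params)
            recomputed = (
                painting.mismatch_cost_sum + params.w * painting.switch_cost_sum
            )
            assert painting.total_cost == pytest.approx(recomputed, abs=1e-9)

    def test_switch_count_monotone_in_w(self, rng):
        for _ in range(10):
            g = random_graph(rng, n=30, p=3)
            pen = random_penalties(rng, 30)
            query = rng.integers(0, 2, 30)
            switches = []
            for w in (0.1, 0.5, 1.5, 5.0, 50.0):
                painting = infer_path(g, pen, query, PenaltyParams(w=w))
                switches.append(int((np.diff(painting.labels) != 0).sum()))
            assert switches == sorted(switches, reverse=True)

    def test_large_w_limit_is_best_single_population(self, rng):
        for _ in range(20):
            g = random_graph(rng, n=15, p=3)
            pen = random_penalties(rng, 15)
            query = rng.integers(0, 2, 15)
            m = site_population_mismatch(g, query)
            painting = infer_path(g, pen, query, PenaltyParams(w=1e6))
            assert len(set(painting.labels.tolist())) == 1
            assert painting.labels[0] == int(np.argmin(m.sum(axis=0)))

    def test_w_zero_is_per_site_argmin(self, rng):
        g = random_graph(rng, n=12, p=3)
        pen = random_penalties(rng, 12)
        query = rng.integers(0, 2, 12)
        m = site_population_mismatch(g, query)
        painting = infer_path(g, pen, query, PenaltyParams(w=0.0))
        np.testing.assert_array_equal(
            m[np.arange(12), painting.labels], m.min(axis=1)
        )

    def test_label_permutation_equivariance(self, rng):
        for _ in range(6):
            g = random_graph(rng, n=10, p=3)
            pen = random_penalties(rng, 10)
            query = rng.integers(0, 2, 10)
            perm = rng.permutation(3)
            g2 = CompactPopulationGraph(
                presence=g.presence[:, :, perm],
                sites=g.sites,
                population_names=[g.population_names[i] for i in perm],
            )
            params = PenaltyParams()
            p1 = infer_path(g, pen, query, params)
            p2 = infer_path(g2, pen, query, params)
            # permuting population indices permutes the painting identically
            # up to tie degeneracy: the permuted path is always an equal-cost
            # optimum, and equal labels are required when the optimum is unique
            inv = np.argsort(perm)
            assert p1.total_cost == pytest.approx(p2.total_cost, abs=1e-9)
            m2 = site_population_mismatch(g2, query, params)
            permuted = inv[p1.labels]
            cost = float(m2[np.arange(10), permuted].sum()) + params.w * float(
                pen.values[np.diff(permuted) != 0].sum()
            )
            assert cost == pytest.approx(p2.total_cost, abs=1e-9)
            import itertools

            n_opt = 0
            for path in itertools.product(range(3), repeat=10):
                path = np.array(path)
                c = float(m2[np.arange(10), path].sum()) + params.w * float(
                    pen.values[np.diff(path) != 0].sum()
                )
                n_opt += c <= p2.total_cost + 1e-9
            if n_opt == 1:
                np.testing.assert_array_equal(permuted, p2.labels)

    def test_within_population_penalty_ablation(self, two_pop_panel):
        g = build_compact_graph(two_pop_panel)
        query = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
        pen = uniform_penalties(8, 2.0)
        base = infer_path(g, pen, query, PenaltyParams(w=1.5))
        ablated = infer_path(
            g, pen, query, PenaltyParams(w=1.5, within_population_switch_cost=1.0)
        )
        # uniform within-population charge adds w * 1.0 * R' on the 6 stay moves
        assert ablated.total_cost == pytest.approx(base.total_cost + 1.5 * 2.0 * 6)

    def test_single_site(self):
        g = graph_from_node_sets([{(0, 0), (1, 1)}], p=2)
        painting = infer_path(g, uniform_penalties(1), np.array([1]))
        np.testing.assert_array_equal(painting.labels, [1])
        assert painting.total_cost == 0.0


class TestEnumerateOracle:
    def test_single_site(self):
        g = graph_from_node_sets([{(0, 0), (1, 1)}], p=2)
        cost, labels = enumerate_paths_oracle(g, uniform_penalties(1), np.array([1]))
        assert cost == 0.0 and list(labels) == [1]

    def test_guard(self, rng):
        g = random_graph(rng, n=30, p=3)
        with pytest.raises(ValueError, match="guard"):
            enumerate_paths_oracle(g, random_penalties(rng, 30), np.zeros(30))


class TestInferQueryset:
    def _queryset(self, haps):
        haps = np.asarray(haps, dtype=np.int8)
        q = haps.shape[0]
        return QuerySet(
            haplotypes=haps,
            sites=make_sites(haps.shape[1]),
            sample_ids=[f"s{i // 2}" for i in range(q)],
            hap_indices=np.tile([0, 1], (q + 1) // 2)[:q],
        )

    def test_batch_equals_single_calls(self, rng):
        g = random_graph(rng, n=25, p=3)
        pen = random_penalties(rng, 25)
        haps = rng.integers(0, 2, (6, 25))
        qs = self._queryset(haps)
        batch = infer_queryset(g, pen, qs)
        for i, painting in enumerate(batch):
            single = infer_path(g, pen, haps[i])
            np.testing.assert_array_equal(painting.labels, single.labels)
            assert painting.total_cost == pytest.approx(single.total_cost)

    def test_duplicated_query_is_deterministic(self, rng):
        g = random_graph(rng, n=15, p=2)
        pen = random_penalties(rng, 15)
        hap = rng.integers(0, 2, 15)
        qs = self._queryset(np.stack([hap, hap]))
        a, b = infer_queryset(g, pen, qs)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.total_cost == b.total_cost

    def test_misaligned_queries_error(self, rng):
        g = random_graph(rng, n=10, p=2)
        qs = self._queryset(np.zeros((2, 9)))
        with pytest.raises(ValueError, match="aligned"):
            infer_queryset(g, random_penalties(rng, 10), qs)

    def test_marker_mask_suppresses_masked_evidence(self, rng):
        g = random_graph(rng, n=20, p=2)
        pen = random_penalties(rng, 20)
        haps = rng.integers(0, 2, (2, 20))
        qs = self._queryset(haps)
        mask = np.zeros(20, dtype=bool)  # nothing informative
        paintings = infer_queryset(g, pen, qs, marker_mask=mask)
        for p in paintings:
            assert p.total_cost == 0.0
            assert len(set(p.labels.tolist())) == 1


class TestCollapsingInvariance:
    def test_phase_swap_and_duplication_leave_painting_unchanged(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 4))
            m = 2 * int(rng.integers(1, 4))
            n = int(rng.integers(4, 12))
            alleles = rng.integers(0, 2, (p * m, n)).astype(np.int8)
            pops = np.repeat(np.arange(p), m)
            panel = make_panel(alleles, pops)
            pen = random_penalties(rng, n)
            query = rng.integers(0, 2, n)
            base = infer_path(build_compact_graph(panel), pen, query)

            # swap alleles between an individual's two haplotypes at one site
            swapped = alleles.copy()
            ind = int(rng.integers(p * m // 2))
            j = int(rng.integers(n))
            swapped[[2 * ind, 2 * ind + 1], j] = swapped[[2 * ind + 1, 2 * ind], j]
            alt = infer_path(
                build_compact_graph(make_panel(swapped, pops)), pen, query
            )
            np.testing.assert_array_equal(base.labels, alt.labels)

            # duplicate a haplotype
            dup_idx = int(rng.integers(p * m))
            dup = make_panel(
                np.vstack([alleles, alleles[dup_idx]]),
                np.concatenate([pops, [pops[dup_idx]]]),
            )
            alt2 = infer_path(build_compact_graph(dup), pen, query)
            np.testing.assert_array_equal(base.labels, alt2.labels)
            assert base.total_cost == pytest.approx(alt2.total_cost)
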