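"""Parallel evolution, co-occurrence and ordering statistics against
independent closed-form / enumeration oracles."""

import itertools
from collections import Counter
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from clonevo.model import Clone, CloneTree
from clonevo.stats import (
    benjamini_hochberg,
    clone_event_matrix,
    combine_cooccurrence_modes,
    cooccurrence_test,
    core_event_label,
    enumerate_trajectories,
    ordering_test,
    parallel_evolution_test,
    simulate_parallel_null,
)


def hypergeom_tail_oracle(N, n_a, n_b, j, upper):
    """Exact hypergeometric tail with integer arithmetic."""
    total = comb(N, n_b)
    rng = range(j, min(n_a, n_b) + 1) if upper else range(0, j + 1)
    acc = sum(comb(n_a, i) * comb(N - n_a, n_b - i) for i in rng)
    return Fraction(acc, total)


def binom_two_sided_oracle(a, b):
    n = a + b
    m = min(a, b)
    tail = Fraction(sum(comb(n, i) for i in range(0, m + 1)), 2**n)
    return min(Fraction(1), 2 * tail)


def matrix_for(N, n_a, n_b, j):
    rows = np.zeros((N, 2), dtype=int)
    rows[:n_a, 0] = 1
    rows[:j, 1] = 1
    rows[n_a: n_a + (n_b - j), 1] = 1
    return pd.DataFrame(rows, columns=["A", "B"])


class TestCooccurrence:
    def test_closed_form_example(self):
        # N=10, both events in 5 rows, full overlap: p_gt = 1/252
        res = cooccurrence_test(matrix_for(10, 5, 5, 5))
        assert res["p_gt"].iloc[0] == pytest.approx(1 / 252, abs=1e-15)

    def test_observed_equal_expected_zero_enrichment(self):
        res = cooccurrence_test(matrix_for(8, 4, 4, 2))
        assert res["expected"].iloc[0] == 2
        assert res["enrichment"].iloc[0] == 0.0

    @pytest.mark.parametrize("N", [3, 5, 8, 12])
    def test_exhaustive_oracle_small_matrices(self, N):
        for n_a in range(1, N + 1):
            for n_b in range(1, n_a + 1):
                for j in range(max(0, n_a + n_b - N), min(n_a, n_b) + 1):
                    res = cooccurrence_test(matrix_for(N, n_a, n_b, j))
                    assert res["p_gt"].iloc[0] == pytest.approx(
                        float(hypergeom_tail_oracle(N, n_a, n_b, j, True)), abs=1e-12
                    )
                    assert res["p_lt"].iloc[0] == pytest.approx(
                        float(hypergeom_tail_oracle(N, n_a, n_b, j, False)), abs=1e-12
                    )

    def test_agrees_with_label_permutation(self, rng):
        # brute-force null: shuffle one event's labels, compare tails
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(20, 2)), columns=["A", "B"]
        )
        if mat["A"].sum() == 0 or mat["B"].sum() == 0:
            pytest.skip("degenerate draw")
        res = cooccurrence_test(mat)
        obs = int((mat["A"] & mat["B"]).sum())
        B = 20_000
        a = mat["A"].to_numpy()
        perms = np.array([rng.permutation(mat["B"].to_numpy()) for _ in range(B)])
        j_null = (perms & a).sum(axis=1)
        p_gt_mc = (j_null >= obs).mean()
        se = np.sqrt(p_gt_mc * (1 - p_gt_mc) / B) + 1e-9
        assert abs(res["p_gt"].iloc[0] - p_gt_mc) < 5 * se + 1e-3

    def test_both_mode_significance_rule(self):
        strong = cooccurrence_test(matrix_for(30, 15, 15, 15))
        weak = cooccurrence_test(matrix_for(30, 15, 15, 8))
        merged = combine_cooccurrence_modes(strong, weak)
        assert not merged["significant"].iloc[0]
        merged2 = combine_cooccurrence_modes(strong, strong)
        assert merged2["significant"].iloc[0]
        assert merged2["direction"].iloc[0] == "cooccurrence"


class TestOrdering:
    def test_eleven_to_zero(self):
        p = ordering_test(Counter({("PBRM1", "SETD2"): 11}))
        assert p["p"].iloc[0] == pytest.approx(2 * 0.5**11, abs=1e-12)

    def test_symmetric_counts_p_one(self):
        res = ordering_test(Counter({("A", "B"): 5, ("B", "A"): 5}))
        assert res["p"].iloc[0] == 1.0

    def test_below_ten_cases_excluded(self):
        assert ordering_test(Counter({("A", "B"): 4, ("B", "A"): 5})).empty

    @pytest.mark.parametrize("n", range(10, 31, 5))
    def test_exact_binomial_oracle(self, n):
        for a in range(n + 1):
            res = ordering_test(Counter({("A", "B"): a, ("B", "A"): n - a}))
            expected = float(binom_two_sided_oracle(a, n - a))
            assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-12)


def path_tree(tumor_id, clone_events):
    """Chain tree with the given per-clone event-id lists."""
    clones, parent = {}, {}
    prev = None
    for i, events in enumerate(clone_events, start=1):
        cid = f"C{i}"
        clones[cid] = Clone(cid, list(events), frozenset({"R1"}))
        parent[cid] = prev
        prev = cid
    return CloneTree(tumor_id, clones, parent)


class TestTrajectories:
    def test_chain_yields_all_ordered_pairs(self):
        tree = path_tree("T1", [["e1"], ["e2"], ["e3"]])
        labels = {"T1": {"e1": "VHL", "e2": "PBRM1", "e3": "SETD2"}}
        per_case, counts = enumerate_trajectories({"T1": tree}, labels)
        assert per_case["T1"] == {
            ("VHL", "PBRM1"), ("VHL", "SETD2"), ("PBRM1", "SETD2")
        }

    def test_pairs_deduplicated_per_case(self):
        # one PBRM1 ancestor over many SETD2 descendants counts once
        clones = {"C1": Clone("C1", ["p"], frozenset({"R1"}))}
        parent = {"C1": None}
        for i in range(10):
            cid = f"S{i}"
            clones[cid] = Clone(cid, [f"s{i}"], frozenset({"R1"}))
            parent[cid] = "C1"
        tree = CloneTree("T1", clones, parent)
        labels = {"T1": {"p": "PBRM1", **{f"s{i}": "SETD2" for i in range(10)}}}
        _, counts = enumerate_trajectories({"T1": tree}, labels)
        assert counts[("PBRM1", "SETD2")] == 1

    def test_same_clone_events_unordered(self):
        tree = path_tree("T1", [["e1", "e2"]])
        labels = {"T1": {"e1": "VHL", "e2": "PBRM1"}}
        per_case, _ = enumerate_trajectories({"T1": tree}, labels)
        assert per_case["T1"] == set()

    def test_pi3k_scna_pairs_excluded(self):
        tree = path_tree("T1", [["e1"], ["e2"]])
        labels = {"T1": {"e1": "PI3K", "e2": "loss_9p"}}
        per_case, _ = enumerate_trajectories({"T1": tree}, labels)
        assert per_case["T1"] == set()

    def test_core_label_mapping(self):
        assert core_event_label("mutation", "MTOR", "MTOR") == "PI3K"
        assert core_event_label("mutation", "VHL", "VHL") == "VHL"
        assert core_event_label("mutation", "TP53", "TP53") is None
        assert core_event_label("scna", None, "loss_9p") == "loss_9p"
        assert core_event_label("scna", None, "gain_9p") is None


class TestParallelEvolution:
    def test_gene_below_threshold_excluded(self):
        counts = pd.DataFrame({"G": [1] * 9}, index=[f"K{i}" for i in range(9)])
        nr = pd.Series(7, index=counts.index)
        res = parallel_evolution_test(counts, nr, np.random.default_rng(0))
        assert res.empty
        assert res.attrs["skipped_genes"] == ["G"]

    def test_zero_parallel_count_p_near_one(self):
        counts = pd.DataFrame({"G": [1] * 10}, index=[f"K{i}" for i in range(10)])
        nr = pd.Series(7, index=counts.index)
        res = parallel_evolution_test(counts, nr, np.random.default_rng(0))
        assert res["observed_parallel"].iloc[0] == 0
        assert res["p"].iloc[0] > 0.5

    def test_case_order_invariance(self):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        counts = pd.DataFrame(
            {"G": [2, 0, 1, 3, 0, 2, 1, 2]}, index=[f"K{i}" for i in range(8)]
        )
        nr = pd.Series(7, index=counts.index)
        res1 = parallel_evolution_test(counts, nr, rng1)
        shuffled = counts.sample(frac=1, random_state=1)
        res2 = parallel_evolution_test(shuffled, nr.loc[shuffled.index], rng2)
        assert res1["p"].iloc[0] == res2["p"].iloc[0]

    def test_null_matches_convolution_oracle(self):
        # exact distribution of sum(max(0, Binom(n_i, p) - 1)) over <= 5
        # cases by direct convolution, compared with the sampler
        from scipy import stats as sps

        n_regions = np.array([3, 5, 7, 4, 6])
        p = 0.15
        dists = []
        for n in n_regions:
            pmf = sps.binom.pmf(np.arange(n + 1), n, p)
            collapsed = np.zeros(n)  # support of max(0, k-1): 0..n-1
            collapsed[0] = pmf[0] + pmf[1]
            collapsed[1:] = pmf[2:]
            dists.append(collapsed)
        exact = dists[0]
        for d in dists[1:]:
            exact = np.convolve(exact, d)
        draws = simulate_parallel_null(
            n_regions, p, 200_000, np.random.default_rng(11)
        )
        emp = np.bincount(draws, minlength=len(exact)) / len(draws)
        assert np.abs(emp[: len(exact)] - exact).max() < 0.004

    def test_statistic_switch(self):
        counts = pd.DataFrame({"G": [3] * 5}, index=[f"K{i}" for i in range(5)])
        nr = pd.Series(7, index=counts.index)
        res_e = parallel_evolution_test(
            counts, nr, np.random.default_rng(0), statistic="parallel_events"
        )
        res_c = parallel_evolution_test(
            counts, nr, np.random.default_rng(0), statistic="parallel_cases"
        )
        assert res_e["observed_parallel"].iloc[0] == 10  # sum of (3-1)
        assert res_c["observed_parallel"].iloc[0] == 5   # cases with k>=2


def test_benjamini_hochberg_monotone():
    p = np.array([0.01, 0.4, 0.03, 0.9])
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-15).all()
    assert q.max() <= 1.0


def test_clone_event_matrix_modes():
    clones = {
        "C1": Clone("C1", ["e1"], frozenset({"R1", "R2"})),
        "C2": Clone("C2", ["e2"], frozenset({"R1"})),
        "C3": Clone("C3", ["e3"], frozenset({"R2"})),
    }
    tree = CloneTree("T1", clones, {"C1": None, "C2": "C1", "C3": "C1"})
    labels = {"T1": {"e1": "VHL", "e2": "BAP1", "e3": "SETD2"}}
    events = ("VHL", "BAP1", "SETD2")
    mrca = clone_event_matrix({"T1": tree}, labels, events, "mrca_only")
    assert len(mrca) == 1 and mrca.iloc[0].tolist() == [1, 0, 0]
    both = clone_event_matrix({"T1": tree}, labels, events, "mrca_plus_terminal")
    assert len(both) == 3
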