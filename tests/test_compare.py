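"""Rank tests against enumeration oracles; tournament ordering semantics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import burstline as bl
from burstline.compare import (
    kruskal_wallis,
    pairwise_tests,
    pairwise_wilcoxon,
    tournament_ordering,
)


def rank_with_ties(values):
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = np.asarray(values)[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kruskal_oracle(groups):
    """H from first principles: midranks, tie correction, chi-squared df."""
    pooled = np.concatenate(groups)
    ranks = rank_with_ties(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    pooled = np.concatenate([a, b])
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    nm = na * len(b)
    dist = []
    for combo in itertools.combinations(range(len(pooled)), na):
        sel = pooled[list(combo)]
        rest = np.delete(pooled, list(combo))
        dist.append(sum(1 for x in sel for y in rest if x > y))
    dist = np.array(dist)
    total = len(dist)
    p_low = (dist <= u_obs).sum() / total
    p_high = (dist >= u_obs).sum() / total
    return min(1.0, 2 * min(p_low, p_high))


class TestKruskalWallis:
    def test_identical_groups_no_separation(self):
        h, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert h == 0.0 and p == 1.0

    def test_matches_hand_ranked_oracle(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_oracle(groups), rel=1e-12)

    def test_monotone_transform_invariance(self):
        groups = [np.array([1.0, 4.0, 2.0]), np.array([3.0, 8.0])]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_random_small_inputs_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            sizes = rng.integers(1, 4, size=int(rng.integers(2, 4)))
            groups = [rng.integers(0, 5, size=s).astype(float) for s in sizes]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_oracle(groups), rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestPairwiseWilcoxon:
    def test_identical_multisets_p_one(self):
        _, p = pairwise_wilcoxon([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_exact_small_sample_enumeration(self):
        u, p = pairwise_wilcoxon([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_matches_enumeration_on_small_tie_free_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            na, nb = rng.integers(2, 5), rng.integers(2, 5)
            pooled = rng.permutation(np.arange(na + nb, dtype=float) + 1)
            a, b = pooled[:na], pooled[na:]
            _, p = pairwise_wilcoxon(a, b)
            assert p == pytest.approx(mannwhitney_exact_oracle(a, b), rel=1e-9)

    def test_scale_invariance(self):
        a = np.array([1.0, 5.0, 2.5])
        b = np.array([2.0, 7.0, 0.5, 4.0])
        assert pairwise_wilcoxon(a, b) == pairwise_wilcoxon(10 * a, 10 * b)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon([], [1.0])


def _estimates_from_values(values_by_sample, excluded=None):
    rows = []
    for sample, values in values_by_sample.items():
        for i, v in enumerate(values):
            gene = f"g{i}"
            rows.append(
                {"gene": gene, "sample": sample, "mu": v, "kon": v, "cv2": v,
                 "nu": v, "burst_size": v,
                 "excluded": bool(excluded and (gene, sample) in excluded),
                 "fit": True}
            )
    return pd.DataFrame(rows)


class TestTournament:
    def test_pair_counting(self):
        df = _estimates_from_values({"A": [1, 5, 3], "B": [2, 4, 6]})
        res = tournament_ordering(df, "mu")
        row = res.pair_counts.iloc[0]
        assert (row["wins_a"], row["wins_b"]) == (1, 2)
        assert row["winner"] == "B"
        assert res.ranking[0] == "B"

    def test_total_dominance_ranking(self):
        df = _estimates_from_values({"A": [1, 1], "B": [2, 2], "C": [3, 3]})
        res = tournament_ordering(df, "mu")
        assert res.ranking == ["C", "B", "A"]
        assert res.wins.loc[["C", "B", "A"]].tolist() == [2.0, 1.0, 0.0]

    def test_two_samples_reduce_to_sign_count(self):
        df = _estimates_from_values({"A": [3, 1, 2], "B": [1, 2, 3]})
        res = tournament_ordering(df, "mu")
        row = res.pair_counts.iloc[0]
        assert row["wins_a"] == 1 and row["wins_b"] == 2

    def test_identical_samples_tie_split(self):
        df = _estimates_from_values({"A": [1, 2], "B": [1, 2]})
        res = tournament_ordering(df, "mu")
        assert res.pair_counts.iloc[0]["winner"] == "tie"
        assert res.wins["A"] == res.wins["B"] == 0.5

    def test_per_gene_ties_discarded(self):
        df = _estimates_from_values({"A": [1, 7, 7], "B": [2, 7, 7]})
        res = tournament_ordering(df, "mu")
        row = res.pair_counts.iloc[0]
        assert row["ties"] == 2 and row["wins_a"] + row["wins_b"] == 1

    def test_excluded_genes_skipped_per_pair(self):
        df = _estimates_from_values(
            {"A": [1, 9], "B": [2, 1]}, excluded={("g1", "B")}
        )
        res = tournament_ordering(df, "mu")
        row = res.pair_counts.iloc[0]
        assert row["wins_a"] + row["wins_b"] + row["ties"] == 1  # only g0 shared

    def test_no_shared_genes_pair_skipped(self):
        df = _estimates_from_values({"A": [1], "B": [2]}, excluded={("g0", "B")})
        with pytest.raises(ValueError):
            tournament_ordering(df[df["sample"] == "A"], "mu")
        res = tournament_ordering(df, "mu")
        assert res.skipped_pairs == [("A", "B")]

    def test_monotone_transform_invariance(self):
        df = _estimates_from_values({"A": [1, 5, 3], "B": [2, 4, 6], "C": [9, 0, 1]})
        res1 = tournament_ordering(df, "mu")
        df2 = df.copy()
        df2["mu"] = np.exp(df2["mu"])
        res2 = tournament_ordering(df2, "mu")
        assert res1.ranking == res2.ranking


def test_pairwise_tests_table_shape():
    df = _estimates_from_values({"A": [1, 2, 3], "B": [4, 5, 6], "C": [7, 8, 9]})
    out = pairwise_tests(df)
    # 3 pairs x 5 parameters
    assert len(out) == 15
    assert ((out["p_value"] > 0) & (out["p_value"] <= 1)).all()
    assert "multiplicity" in out.attrs["caveat"]
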