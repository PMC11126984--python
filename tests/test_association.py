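"""Tag selection, correlation + BH, differential expression, Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import burstline as bl
from burstline.association import (
    P_FLOOR,
    differential_expression,
    llps_enrichment,
    select_tag_positive_cells,
    tag_correlation,
)
from burstline.io_qc import NormalizedMatrix, normalize


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up q values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration over the a-cell."""
    (a, b), (c, d) = table
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    lo, hi = max(0, m1 - n2), min(m1, n1)
    probs = {k: hypergeom.pmf(k, n, m1, n1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def make_normalized(values, gene_ids=None, samples=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    barcodes = [f"c{j}" for j in range(values.shape[1])]
    samples = samples or ["s"] * values.shape[1]
    import scipy.sparse as sp

    return NormalizedMatrix(
        sp.csr_matrix(values), np.array(gene_ids, dtype=object),
        np.array(barcodes, dtype=object), np.array(samples, dtype=object),
    )


class TestSelectTagPositive:
    def test_selection_rule(self):
        counts = np.array([[0, 1, 0], [0, 0, 2], [5, 5, 5]])
        m = bl.CountMatrix(counts, ["Dendra2", "HaloTag", "g"], ["a", "b", "c"],
                           ["s"] * 3, tag_genes=("Dendra2", "HaloTag"))
        sel = select_tag_positive_cells(m, ["Dendra2", "HaloTag"])
        assert sel.tolist() == [False, True, True]

    def test_missing_tag_named(self):
        m = bl.CountMatrix(np.ones((1, 1)), ["g"], ["c"], ["s"])
        with pytest.raises(KeyError, match="Dendra2"):
            select_tag_positive_cells(m, ["Dendra2"])

    def test_selected_fraction_matches_generator(self, small_study):
        cfg, matrix, _ = small_study
        sel = select_tag_positive_cells(matrix, list(cfg.tag_names))
        n = matrix.n_cells
        se = np.sqrt(cfg.tag_detection_rate * (1 - cfg.tag_detection_rate) / n)
        assert abs(sel.mean() - cfg.tag_detection_rate) < 4 * se


class TestTagCorrelation:
    def test_identical_vector_r_one(self):
        tag = np.array([0.0, 1.0, 2.0, 3.0, 1.5])
        norm = make_normalized(np.vstack([tag, tag, tag[::-1]]),
                               ["Dendra2", "twin", "rev"])
        out = tag_correlation(norm, "Dendra2").set_index("gene")
        assert out.loc["twin", "r"] == pytest.approx(1.0)
        assert out.loc["rev", "r"] < 0
        assert "Dendra2" not in out.index  # tag not tested against itself

    def test_bh_adjustment_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for m in (3, 10, 100):
            p = rng.uniform(size=m)
            from statsmodels.stats.multitest import multipletests

            q = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh_oracle(p), atol=1e-12)
        # the worked example: (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)
        assert np.allclose(bh_oracle([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_zero_variance_gene_dropped_with_reason(self):
        tag = np.array([0.0, 1.0, 2.0, 3.0])
        flat = np.full(4, 2.0)
        norm = make_normalized(np.vstack([tag, flat]), ["Dendra2", "flat"])
        out = tag_correlation(norm, "Dendra2").set_index("gene")
        assert out.loc["flat", "dropped_reason"] == "zero variance"
        assert np.isnan(out.loc["flat", "r"])

    def test_all_zero_genes_removed_first(self):
        tag = np.array([0.0, 1.0, 2.0])
        norm = make_normalized(np.vstack([tag, np.zeros(3)]), ["Dendra2", "silent"])
        out = tag_correlation(norm, "Dendra2")
        assert "silent" not in set(out["gene"])
        assert out.attrs["removed_all_zero"] == ["silent"]

    def test_degenerate_tag_errors(self):
        norm = make_normalized(np.vstack([np.zeros(3), [1.0, 2.0, 3.0]]),
                               ["Dendra2", "g"])
        with pytest.raises(ValueError, match="zero variance"):
            tag_correlation(norm, "Dendra2")


class TestDifferentialExpression:
    def _two_group_matrix(self, rng, n_null=20, n_cells=80, shift_gene=True):
        counts = rng.poisson(5.0, size=(n_null + 1, 2 * n_cells))
        if shift_gene:
            counts[0, :n_cells] *= 4  # strong planted shift
        m = bl.CountMatrix(
            counts, [f"g{i:02d}" for i in range(n_null + 1)],
            [f"c{j}" for j in range(2 * n_cells)], ["s"] * (2 * n_cells),
        )
        norm = normalize(m)
        ga = np.arange(2 * n_cells) < n_cells
        return norm, ga, ~ga

    def test_planted_shift_detected(self):
        norm, ga, gb = self._two_group_matrix(np.random.default_rng(4))
        out = differential_expression(norm, ga, gb).set_index("gene")
        assert bool(out.loc["g00", "significant"])
        assert out.loc["g00", "direction"] == "up"

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, size=(10, 40))
        m = bl.CountMatrix(counts, [f"g{i}" for i in range(10)],
                           [f"c{j}" for j in range(40)], ["s"] * 40)
        norm = normalize(m)
        idx = np.arange(40)
        out = differential_expression(norm, idx[::2], idx[1::2])
        assert not out["significant"].any()

    def test_fold_change_arithmetic(self):
        # de-logged group means 2 vs 1 -> log2fc ~ 1
        xa = np.log1p(np.full((1, 50), 2.0))
        xb = np.log1p(np.full((1, 50), 1.0))
        norm = make_normalized(np.hstack([xa, xb]), ["g"])
        out = differential_expression(
            norm, np.arange(50), np.arange(50, 100)
        )
        assert out.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-6)

    def test_p_floor_applied(self):
        rng = np.random.default_rng(6)
        n = 3000  # large groups push the normal-approximation p to underflow
        xa = np.log1p(rng.poisson(20.0, size=(1, n)).astype(float))
        xb = np.log1p(rng.poisson(0.05, size=(1, n)).astype(float))
        norm = make_normalized(np.hstack([xa, xb]), ["g"])
        out = differential_expression(norm, np.arange(n), np.arange(n, 2 * n))
        assert out.loc[0, "p"] >= P_FLOOR
        assert P_FLOOR == 2.225074e-308

    def test_group_validation(self):
        norm = make_normalized(np.ones((1, 4)), ["g"])
        with pytest.raises(ValueError, match="disjoint"):
            differential_expression(norm, np.array([0, 1]), np.array([1, 2]))
        with pytest.raises(ValueError, match="nonempty"):
            differential_expression(norm, np.array([], dtype=int), np.array([1]))


class TestLLPSEnrichment:
    def test_enumeration_example(self):
        res = llps_enrichment(["a", "b"], ["a", "b"], ["a", "b", "c", "d"])
        # table [[2,0],[0,2]]: P(a=0)=P(2)=1/6, P(1)=2/3 -> two-sided p = 1/3
        assert res.p_value == pytest.approx(1 / 3, rel=1e-9)
        assert np.array_equal(res.table, [[2, 0], [0, 2]])

    def test_matches_hypergeometric_enumeration_small_margins(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 7, size=4)
            if a + b == 0 or a + c == 0:
                continue
            universe = [f"g{i}" for i in range(a + b + c + d)]
            sig = universe[: a + b]
            llps = universe[:a] + universe[a + b : a + b + c]
            res = llps_enrichment(sig, llps, universe)
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle([[a, b], [c, d]]), rel=1e-7
            )

    def test_llps_equals_universe_no_discrimination(self):
        universe = ["a", "b", "c", "d"]
        res = llps_enrichment(["a"], universe, universe)
        assert res.p_value == 1.0

    def test_empty_significant_set(self):
        res = llps_enrichment([], ["a"], ["a", "b"])
        assert res.p_value == 1.0 and np.isnan(res.odds_ratio)

    def test_bonferroni_and_haldane(self):
        res = llps_enrichment(["a", "b"], ["a", "b"], ["a", "b", "c", "d"],
                              n_contrasts=4)
        assert res.p_adjusted == pytest.approx(min(1.0, 4 * res.p_value))
        assert np.isfinite(res.odds_ratio)  # zero cells -> Haldane correction

    def test_validation(self):
        with pytest.raises(ValueError, match="universe"):
            llps_enrichment(["x"], ["x"], [])
        with pytest.raises(ValueError, match="subset"):
            llps_enrichment(["x"], ["y"], ["y"])
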