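"""Nonparametric cross-sample comparison of kinetic parameters.

The five per-gene quantities (mu, kon, CV^2, nu, burst size) are far from
normal, so comparisons across samples use rank statistics: Kruskal-Wallis H
across groups of samples (e.g. CTD-length classes), pairwise two-sided
Wilcoxon rank-sum (Mann-Whitney U) tests between samples, and a pairwise
"tournament": for each unordered sample pair the winner is the sample with
more genes carrying the strictly higher value, and the pair outcomes are
compiled into a ranking by win count (Copeland score). Pairwise p values are
reported unadjusted — each pair yields a single p value over thousands of
strongly dependent genes, so standard multiplicity corrections do not apply;
output metadata carries that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "pairwise_tests",
    "tournament_ordering",
    "PairwiseTest",
    "OrderingResult",
]

KINETIC_PARAMETERS = ("mu", "kon", "cv2", "nu", "burst_size")

P_VALUE_CAVEAT = (
    "pairwise p values are reported without multiplicity adjustment: one p "
    "per sample pair over strongly interdependent genes"
)


@dataclass(frozen=True)
class PairwiseTest:
    parameter: str
    sample_a: str
    sample_b: str
    statistic: float  # Mann-Whitney U for sample_a
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class OrderingResult:
    """Tournament outcome for one parameter."""

    parameter: str
    pair_counts: pd.DataFrame  # sample_a, sample_b, wins_a, wins_b, ties, winner
    wins: pd.Series  # Copeland score per sample
    ranking: list  # samples, descending wins
    skipped_pairs: list  # pairs with no shared genes


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-squared law.

    ``groups`` is a sequence of >= 2 nonempty value arrays. Identical
    values everywhere give H = 0, p = 1 (no separation).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_wilcoxon(values_a, values_b, exact_max: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples are small (<= ``exact_max``) and
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U statistic for the first sample, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (max(a.size, b.size) <= exact_max and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_tests(
    estimates: pd.DataFrame, parameters=KINETIC_PARAMETERS
) -> pd.DataFrame:
    """All pairwise Wilcoxon tests per parameter across samples.

    Excluded estimates are dropped; returns a long-format table
    (parameter, sample_a, sample_b, statistic, p_value, n_a, n_b).
    """
    ok = estimates.loc[~estimates["excluded"].astype(bool)]
    samples = list(pd.unique(ok["sample"]))
    rows = []
    for param in parameters:
        if param not in ok.columns:
            continue
        for i, sa in enumerate(samples):
            va = ok.loc[ok["sample"] == sa, param].dropna().to_numpy()
            for sb in samples[i + 1 :]:
                vb = ok.loc[ok["sample"] == sb, param].dropna().to_numpy()
                stat, p = pairwise_wilcoxon(va, vb)
                rows.append(
                    PairwiseTest(param, sa, sb, stat, p, va.size, vb.size).__dict__
                )
    df = pd.DataFrame(rows)
    df.attrs["caveat"] = P_VALUE_CAVEAT
    return df


def tournament_ordering(
    estimates: pd.DataFrame, parameter: str
) -> OrderingResult:
    """Order samples by pairwise gene-count wins on one parameter.

    For every unordered sample pair, only genes non-excluded in both members
    count; the pair's winner is the sample with more genes carrying the
    strictly higher value (per-gene ties discarded). A drawn pair awards 0.5
    wins to each side. Samples are ranked by total wins, descending, with
    sample name breaking exact win ties deterministically.
    """
    ok = estimates.loc[~estimates["excluded"].astype(bool), ["gene", "sample", parameter]]
    samples = list(pd.unique(estimates["sample"]))
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    wide = ok.pivot(index="gene", columns="sample", values=parameter)
    wins = {s: 0.0 for s in samples}
    rows = []
    skipped = []
    for i, sa in enumerate(samples):
        for sb in samples[i + 1 :]:
            if sa not in wide.columns or sb not in wide.columns:
                shared = wide.iloc[0:0]
            else:
                shared = wide[[sa, sb]].dropna()
            if shared.empty:
                skipped.append((sa, sb))
                continue
            va = shared[sa].to_numpy()
            vb = shared[sb].to_numpy()
            wa = int((va > vb).sum())
            wb = int((vb > va).sum())
            ties = int((va == vb).sum())
            if wa > wb:
                winner = sa
                wins[sa] += 1.0
            elif wb > wa:
                winner = sb
                wins[sb] += 1.0
            else:
                winner = "tie"
                wins[sa] += 0.5
                wins[sb] += 0.5
            rows.append(
                {"sample_a": sa, "sample_b": sb, "wins_a": wa, "wins_b": wb,
                 "ties": ties, "winner": winner}
            )
    wins_s = pd.Series(wins, name="wins")
    ranking = sorted(samples, key=lambda s: (-wins_s[s], s))
    return OrderingResult(
        parameter=parameter,
        pair_counts=pd.DataFrame(rows),
        wins=wins_s,
        ranking=ranking,
        skipped_pairs=skipped,
    )
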