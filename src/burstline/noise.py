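"""Expression-level-corrected transcriptional noise and noise grouping.

Across genes, CV^2 falls with mean expression along the reference curve
``CV^2 = 1/mu + 1/kbar_on`` implied by the negative-binomial bursting law,
where ``kbar_on`` is the burst frequency averaged over the fitted genes of a
sample. The noise distance ``nu`` of a gene is the vertical log-scale
distance of its CV^2 from that curve,

    nu = ln(CV^2) - ln(1/mu + 1/kbar_on),

a dimensionless noise measure with the expression-level trend removed.
Genes are ranked by nu and split into three equal groups (low / medium /
high noise).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mean_burst_frequency",
    "noise_distance",
    "assign_noise_groups",
    "add_noise_stats",
]

NOISE_GROUPS = ("low", "medium", "high")


def mean_burst_frequency(estimates: pd.DataFrame) -> float:
    """Arithmetic mean of kon over non-excluded estimates of one sample."""
    kon = estimates.loc[~estimates["excluded"].astype(bool), "kon"].to_numpy(float)
    if kon.size == 0:
        raise ValueError("no non-excluded estimates to average")
    return float(kon.mean())


def noise_distance(mu, cv2, kbar_on):
    """nu = ln(cv2) - ln(1/mu + 1/kbar_on); vectorized."""
    mu = np.asarray(mu, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    if not kbar_on > 0:
        raise ValueError("kbar_on must be positive")
    if np.any(mu <= 0) or np.any(cv2 <= 0):
        raise ValueError("mu and cv2 must be positive")
    return np.log(cv2) - np.log(1.0 / mu + 1.0 / kbar_on)


def assign_noise_groups(nu, gene_ids=None) -> np.ndarray:
    """Split genes into low/medium/high noise tertiles of equal size (+-1).

    Genes are stably sorted by (nu, gene id); when the count is not a
    multiple of three the extra genes go to the lower groups first, so the
    sizes are e.g. {4, 3, 3} for ten genes. Ties in nu are resolved by the
    stable sort, keeping the split deterministic.
    """
    nu = np.asarray(nu, dtype=float)
    n = nu.size
    if n < 3:
        raise ValueError("need at least 3 genes to form noise tertiles")
    if gene_ids is None:
        order = np.argsort(nu, kind="stable")
    else:
        gene_ids = np.asarray(gene_ids, dtype=object)
        order = np.lexsort((gene_ids, nu))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for size, name in zip(sizes, NOISE_GROUPS):
        labels[order[start : start + size]] = name
        start += size
    return labels


def add_noise_stats(
    estimates: pd.DataFrame, per_sample: bool = True
) -> pd.DataFrame:
    """Join nu, noise_group and the sample's kbar_on onto an estimates table.

    ``per_sample=False`` computes a single global kbar_on across all samples
    instead of one per sample. Excluded estimates get NaN nu and no group.
    """
    df = estimates.copy()
    df["kbar_on"] = np.nan
    df["nu"] = np.nan
    df["noise_group"] = pd.Series([pd.NA] * len(df), dtype=object)
    ok = ~df["excluded"].astype(bool)
    kbar_global = mean_burst_frequency(df) if not per_sample else None
    for sample, idx in df.groupby("sample").groups.items():
        sub = df.loc[idx]
        sel = idx[ok.loc[idx]]
        if len(sel) == 0:
            continue
        kbar = (
            mean_burst_frequency(sub) if per_sample else kbar_global
        )
        nu = noise_distance(
            df.loc[sel, "mu"].to_numpy(float),
            df.loc[sel, "cv2"].to_numpy(float),
            kbar,
        )
        df.loc[sel, "kbar_on"] = kbar
        df.loc[sel, "nu"] = nu
        if len(sel) >= 3:
            df.loc[sel, "noise_group"] = assign_noise_groups(
                nu, df.loc[sel, "gene"].to_numpy()
            )
    return df
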