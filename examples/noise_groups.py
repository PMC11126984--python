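"""Compute the expression-corrected noise statistic nu and noise tertiles.

nu measures how far a gene's CV^2 sits above or below the reference curve
CV^2 = 1/mu + 1/kbar_on (log scale). Grouping genes into noise tertiles
shows the expected physics: high-noise genes burst less frequently and in
larger bursts.
"""

import numpy as np

import burstline as bl
from burstline.inference import fit_genes
from burstline.noise import add_noise_stats

rng = np.random.default_rng(3)
G, C = 100, 800
mu = np.exp(rng.uniform(np.log(0.1), np.log(30.0), G))
kon = np.exp(rng.uniform(np.log(0.1), np.log(5.0), G))
counts = np.vstack([bl.sample_nb_counts(mu[g], kon[g], C, rng) for g in range(G)])

estimates = fit_genes(counts, [f"G{g:03d}" for g in range(G)], n_steps=10_000, seed=4)
annotated = add_noise_stats(estimates)

print(f"kbar_on = {annotated['kbar_on'].iloc[0]:.3f} (mean burst frequency)")
summary = annotated.groupby("noise_group")[["kon", "burst_size", "nu"]].mean()
print(summary.loc[["low", "medium", "high"]].to_string(float_format=lambda v: f"{v:.3f}"))
# Mean k_on falls and mean burst size rises from the low- to the high-noise
# tertile: frequent small bursts give regular expression, rare large bursts
# give noisy expression.
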