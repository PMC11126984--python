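# Methods

## Model

Each gene is modeled by the two-state telegraph process: activation at rate
k_on, inactivation at k_off, transcription at rate α while active,
degradation at rate d per molecule. Time is measured in mean mRNA lifetimes
(d ≡ 1), so only dimensionless rate ratios enter the stationary law. In the
bursting regime (k_off ≫ d) the stationary copy-number distribution is
negative binomial with size r = k_on and burst size b = α/k_off:

    P(X = x) = Γ(x+r) / (Γ(r) x!) · (b/(1+b))^x · (1/(1+b))^r,
    E[X] = μ = r·b,   CV² = 1/μ + 1/k_on,   b = CV²·μ − 1 = μ/k_on.

The package treats this NB law as the generative model for the raw UMI
counts of each gene across the QC-passed cells of one sample. No technical
noise layer (capture efficiency, dropout) is added on top: the fitted model
is the count-level NB, and the default synthetic generator matches it.

## Inference

Per gene, posterior sampling is by random-walk Metropolis on
θ = (log μ, log k_on):

- **Priors.** Independent log-uniform on μ, k_on ∈ [10⁻⁴, 10⁴]. These are
  scale-free and keep the posterior proper on a box wide enough to be
  non-informative at scRNA-seq scales. Genes indistinguishable from Poisson
  (sample CV² ≈ 1/μ) have weakly identified k_on; their posterior mass
  spreads toward the upper prior bound, which correctly lands them in the
  low-noise group downstream.
- **Proposal and adaptation.** Isotropic Gaussian on θ, initial scale 0.5.
  During the first 25% of steps the scale adapts every 100 steps toward
  ~25% acceptance (multiplicative update, clipped to [10⁻³, 5]), then is
  frozen so the final 75% of the chain is a valid Metropolis kernel.
- **Chain length and burn-in.** 100,000 steps by default; the first 25% is
  discarded as burn-in (coinciding with adaptation). Tests and the
  acceptance script use 10,000–20,000 steps, which at 600–2,000 cells per
  gene already recover μ to a few percent and k_on to well within 30%.
- **Initialization.** Method-of-moments: μ₀ = sample mean, k_on,0 =
  1/max(CV²̂ − 1/μ₀, 10⁻³), clipped into the prior box.
- **Estimates.** Posterior means of μ, k_on, and of the *function*
  CV²(θ) = 1/μ + 1/k_on over post-burn-in samples. The reported burst size
  is CV²·μ − 1 of the reported (posterior-mean) values, so the identity
  holds exactly on every emitted row.
- **Exclusions.** All-zero genes are refused (flagged unfit, no estimate).
  Estimates with CV² > 2,000 are flagged excluded — such chains show poor
  mixing — and drop out of every downstream statistic. The threshold is
  strict (CV² = 2,000 is retained). An optional μ ≥ 0.01 reporting filter
  can mark low-expression genes.
- **Determinism and parallelism.** Each gene's chain draws from its own
  child seed (`numpy.random.SeedSequence.spawn`, child index = gene row),
  with random blocks pre-drawn per gene, so batched fitting is bit-identical
  to fitting genes one at a time and independent of scheduling.

The per-step likelihood is evaluated on the compressed count histogram
(unique values × multiplicities) and vectorized across genes, which makes a
200-gene × 2,000-cell × 20,000-step fit run in ~20 s on one CPU.

## Noise statistic and grouping

k̄_on is the arithmetic mean of k_on over non-excluded genes, computed per
sample by default (a global-across-samples switch exists). The noise
distance of a gene is

    ν = ln CV² − ln(1/μ + 1/k̄_on),

the vertical log-scale distance from the NB reference curve; it removes the
1/μ expression-level trend, and rescaling every CV² by a common factor c
shifts every ν by ln c without changing ranks. Genes are stably sorted by
(ν, gene id) and split into three groups of equal size (±1; remainders go to
the lower groups first, so 10 genes split 4/3/3). Natural log is used
throughout; the base only rescales ν and cannot affect grouping or any
monotone comparison.

## Cross-sample comparison

All five per-gene quantities (μ, k_on, CV², ν, burst size) are heavily
non-normal, so comparisons are nonparametric: Kruskal–Wallis H (tie
corrected, chi-squared p) across groups of samples such as CTD-length
classes, and two-sided Mann–Whitney U per sample pair (exact enumeration for
tie-free samples of ≤ 20 values, otherwise normal approximation with tie
correction). Pairwise p values are reported unadjusted: each pair yields a
single p over thousands of mutually dependent genes, so standard
multiplicity corrections are not applicable; the output carries this caveat
in its metadata.

The tournament ordering compares samples pairwise on genes non-excluded in
both: the pair's winner has more genes with the strictly higher value
(per-gene ties are discarded, since "higher" is undefined at equality); a
drawn pair awards 0.5 wins to each side so the ranking stays total
(Copeland score); samples are ranked by total wins with the sample name as a
deterministic tie-break.

## Association analyses

These stages consume the log-normalized layer ln(1 + 10⁴·x/total); raw
counts feed only the kinetic inference.

- **Tag correlation.** Per-gene Pearson r against a tag gene's normalized
  vector; genes with no expression in any analysis cell are removed first,
  and zero-variance genes are dropped with a recorded reason. Two-sided p
  from the t transform with n−2 d.f., Benjamini–Hochberg step-up q,
  significance at q < 0.05. The pipeline pools the tag's own samples by
  default; restriction to tag-positive cells (raw tag count > 0) is a flag.
- **Differential expression.** Two-sided Wilcoxon rank-sum per gene on
  normalized values; p floored at 2.225074×10⁻³⁰⁸ (smallest normal double,
  keeps log-scale plots finite) before Bonferroni adjustment over the genes
  actually tested; log₂ fold change of de-logged group means with a 10⁻⁹
  pseudocount; significance requires both |log2FC| ≥ 0.5 and adjusted
  p < 0.05.
- **Enrichment.** 2×2 Fisher exact test (significant × gene-set membership
  over the tested universe), two-sided; sample odds ratio with a Haldane 0.5
  correction when a cell is zero; Bonferroni across the number of contrasts
  tested. Gene-set membership is a user-supplied list (one symbol per line) —
  LLPS database contents are version-dependent and are deliberately not
  bundled or downloaded.

## Synthetic data

The generator emulates the study design this pipeline targets: several
cell-line samples with shared per-gene kinetics, optional multiplicative
kinetic shifts planted per sample (burst-size shifts scale μ at fixed k_on;
frequency shifts scale k_on at fixed burst size), mitochondrial genes, one
sparsely detected exogenous tag gene per tag type, and a damaged-cell
subpopulation for QC.

Defaults: 6 samples × 3,490 cells (the scale of the emulated experiment),
2,000 genes (a desk-representable fitted-gene count; real datasets carry
~20–30k genes, most unexpressed), μ log-uniform in [0.05, 50] and k_on
log-uniform in [0.1, 5] (the ranges spanned by single-cell bursting fits),
2.5% damaged cells, tag detection rate 7.5% (tags are detected in ~7–8% of
their lines' cells in such experiments), mitochondrial genes 1% of the panel
carrying 8% of a healthy cell's molecules. Mitochondrial transcripts are
high-abundance, low-noise species, so MT- genes get a burst-frequency floor
(k_on ≥ 5); without it, desk-scale panels show spurious mito-fraction
spikes that real data (with thousands of genes buffering the denominator)
does not.

Mechanisms chosen where the emulated study reports only outcomes:

- **Tag genes** are Bernoulli(detection rate) × zero-truncated NB, so the
  nonzero-cell fraction equals the configured rate in expectation. The
  truncation is deliberate: with a plain NB factor the realized detection
  rate would sit below the mask rate by the NB zero mass.
- **Damaged cells** are healthy cells binomially downsampled (retention
  halved iteratively) until their detected-gene count falls at or below the
  configured QC threshold, then their MT- counts are inflated past the
  mito-fraction threshold (target 40%). This is the minimal mechanism that
  triggers both filters. At full scale the planted thresholds are the
  printed 1,250 / 25%; small test panels lower `qc_min_genes` so healthy
  cells clear the detected-genes bar comfortably.
- The generator adds **no cell-cycle structure, doublets, ambient RNA, or
  capture noise**. Passing tests therefore demonstrate correctness of the
  estimators under the fitted model's own assumptions — not robustness to
  technical artifacts absent from that model. Optional binomial thinning is
  not implemented; the fitted model is the count-level NB without an error
  layer, and the generator is its exact twin.

The telegraph simulator is an exact event-driven (Gillespie) implementation
of the four reactions, one independent cell per draw, recorded after a
burn-in of 20/d (≫ both relaxation times at the parameters used). It is the
package's independent oracle: at k_off/d = 50 the empirical stationary law
is within total-variation 0.03–0.04 of the NB limit at 4,000 cells, of which
~0.02 is Monte-Carlo noise and the rest the O(d/k_off) truncation of the
burst limit.

## Numerical and design choices

- NB log-pmf in log space via log-gamma; finite up to counts of 10⁶ and
  normalizes to 1 within 10⁻¹⁰ on truncated support.
- QC boundary semantics are literal: a cell with exactly 1,250 detected
  genes is removed ("1,250 or less"), a cell at exactly 25% mitochondrial is
  retained ("more than 25%" excluded). Zero-total cells are flagged
  degenerate (mito fraction undefined, no division) and always removed
  before normalization.
- Mitochondrial genes are recognized by the case-insensitive "MT-" symbol
  prefix, with an explicit-list override.
- Tertile remainders and ν ties: stable sort by (ν, gene id), extras to the
  lower groups first — deterministic and reproducible.
- The pipeline manifest records a config hash, the seed and per-stage output
  lists; a rerun with the same config skips stages whose outputs exist,
  deleting a stage's outputs recomputes it, and any config change
  invalidates the run. All randomness flows from the config seed.

## Problem sizes used by the test suite and acceptance script

Parameter recovery uses 200 genes × 2,000 cells at 20,000 MCMC steps
(median relative error ≈ 2% for μ and ≈ 3–4% for k_on among genes with
μ ≥ 0.5); the telegraph/NB comparison uses 5 parameter sets × 4,000 cells;
direction-of-effect fits 120 genes × 600 cells at 10,000 steps; the
tournament check runs 20 replicates of a two-sample, 200-gene, 500-cell
study with a 1.5× burst-size shift using method-of-moments estimates (the
screening companion to the MCMC fit); DE recovery plants 25 up- and 25
down-regulated 2-fold genes (μ ∈ [2, 8], k_on ∈ [1, 3], so the rank test is
powered at n = 500 cells/group) among 1,000 nulls; tag-correlation recovery
plants 100 latent-factor genes (loading 0.5) among 400 nulls at 2,000 cells,
keeping the covarying set a minority of the library so size normalization
does not absorb the factor.

## Known limitations

- k_on is reported per mean mRNA lifetime; absolute rates require an
  external estimate of d per gene.
- The NB approximation ignores the finite-k_off correction; genes outside
  the bursting regime fold that bias into k_on.
- Wilcoxon DE on normalized counts inherits the usual compositional
  coupling: large one-sided expression shifts move library sizes and can
  bias fold changes of unchanged genes.
- Genes near the Poisson limit have weakly identified k_on (bounded by the
  prior); their μ and CV² remain well estimated.
- The tag-gene detection model is a phenomenological mask, not a mechanistic
  account of why tag reads are sparse.
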