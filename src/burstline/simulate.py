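"""Synthetic multi-sample UMI studies with known bursting kinetics.

The two-state (telegraph) gene model — activation at rate ``k_on``,
deactivation at ``k_off``, transcription at ``alpha`` while active,
degradation at ``d`` per molecule — has, in the bursting limit
(``k_off >> d``), a negative-binomial stationary copy-number law with size
parameter ``k_on/d``, mean ``mu = (k_on/d) * (alpha/k_off)`` and
``CV^2 = 1/mu + d/k_on``. Time is measured in mean mRNA lifetimes
(``d = 1``) throughout.

Two generators live here:

* :func:`simulate_telegraph` — an exact event-driven (Gillespie) simulator of
  the full telegraph model, used as the independent oracle for the
  negative-binomial limit;
* :func:`sample_nb_counts` / :func:`generate_study` — the generative twin of
  the fitted count model, producing whole multi-sample studies with planted
  kinetic shifts, mitochondrial genes, sparsely detected tag genes and a
  damaged-cell sub-population to exercise QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_qc import CountMatrix, write_count_matrix

__all__ = [
    "TelegraphParams",
    "EffectSpec",
    "StudyConfig",
    "StudyTruth",
    "sample_nb_counts",
    "simulate_telegraph",
    "generate_study",
    "write_truth",
]

KON_CAP = 1e6  # burst frequencies above this are treated as the Poisson limit


@dataclass(frozen=True)
class TelegraphParams:
    """Rates of the two-state gene model, in units of the mRNA lifetime.

    ``k_on``: off->on switching (burst frequency); ``k_off``: on->off
    switching; ``alpha``: transcription rate while on; ``d``: degradation
    rate per molecule (fixes the time unit, default 1).
    """

    k_on: float
    k_off: float
    alpha: float
    d: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "alpha", "d"):
            v = getattr(self, name)
            if not (v >= 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        if self.d <= 0 or self.k_on < 0:
            raise ValueError("d must be strictly positive")

    @property
    def burst_size(self) -> float:
        """Mean mRNAs per burst, alpha / k_off."""
        return self.alpha / self.k_off

    @property
    def mean(self) -> float:
        """Stationary mean alpha/d * k_on/(k_on + k_off)."""
        return self.alpha / self.d * self.k_on / (self.k_on + self.k_off)


def sample_nb_counts(
    mu: float, kon: float, n_cells: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw stationary UMI counts from the negative-binomial bursting law.

    Counts follow NB with size ``r = kon`` and success probability
    ``p = 1/(1+b)`` where ``b = mu/kon`` is the burst size, so that
    ``E[X] = mu`` and ``Var[X] = mu (1 + mu/kon)``. ``kon`` above 1e6 is
    capped, which is numerically the Poisson(mu) limit.
    """
    if not (mu > 0) or not (kon > 0):
        raise ValueError(f"mu and kon must be positive, got mu={mu}, kon={kon}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kon = min(float(kon), KON_CAP)
    b = mu / kon
    p = 1.0 / (1.0 + b)
    return rng.negative_binomial(kon, p, size=n_cells).astype(np.int64)


def simulate_telegraph(
    params: TelegraphParams,
    n_cells: int,
    burn_in_time: float | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One stationary mRNA copy-number draw per cell, by exact simulation.

    Each cell is an independent Gillespie run of the four reactions
    {off->on at k_on, on->off at k_off, birth at alpha while on, death at
    d per molecule}, started off/empty and advanced past ``burn_in_time``
    (default 20 mean lifetimes) before the copy number is recorded.
    """
    if burn_in_time is None:
        burn_in_time = 20.0 / params.d
    if burn_in_time <= 0:
        raise ValueError("burn_in_time must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k_on, k_off, alpha, d = params.k_on, params.k_off, params.alpha, params.d
    out = np.empty(n_cells, dtype=np.int64)
    for c in range(n_cells):
        t = 0.0
        on = False
        m = 0
        while True:
            rate_switch = k_off if on else k_on
            rate_birth = alpha if on else 0.0
            rate_death = d * m
            total = rate_switch + rate_birth + rate_death
            if total <= 0.0:
                # absorbing quiet state (e.g. k_on = 0, no molecules)
                break
            t += rng.exponential(1.0 / total)
            if t >= burn_in_time:
                break
            u = rng.random() * total
            if u < rate_switch:
                on = not on
            elif u < rate_switch + rate_birth:
                m += 1
            else:
                m -= 1
        out[c] = m
    return out


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative kinetic shift planted in one sample.

    ``param`` is ``"burst_size"`` (scales mu, k_on unchanged) or ``"kon"``
    (scales k_on at fixed burst size, so mu scales by the same factor).
    ``genes`` is a sequence of gene indices, or None for all non-tag genes.
    """

    sample: int | str
    param: str
    factor: float
    genes: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.param not in ("burst_size", "kon"):
            raise ValueError(f"unknown effect parameter {self.param!r}")
        if not self.factor > 0:
            raise ValueError("effect factor must be positive")


@dataclass
class StudyConfig:
    """Conditions of a synthetic multi-sample study.

    Defaults mirror the study design this generator emulates: six cell-line
    samples of ~3,490 QC-passed cells each, ~2.5% damaged cells, tag genes
    detected in ~7.5% of their samples' cells, and per-gene kinetics drawn
    log-uniformly over a realistic range of means and burst frequencies.
    """

    n_samples: int = 6
    cells_per_sample: int = 3490
    n_genes: int = 2000
    mu_range: tuple[float, float] = (0.05, 50.0)
    kon_range: tuple[float, float] = (0.1, 5.0)
    frac_mito_genes: float = 0.01
    mito_count_fraction: float = 0.08  # share of a healthy cell's molecules that are MT-
    mito_kon_floor: float = 5.0  # MT- transcripts are abundant and low-noise
    frac_damaged_cells: float = 0.025
    tag_detection_rate: float = 0.075
    tag_names: tuple[str, ...] = ("Dendra2", "HaloTag")
    tag_mu: float = 1.0
    tag_kon: float = 1.0
    effects: tuple[EffectSpec, ...] = ()
    # thresholds the damaged cells are planted to violate (QC defaults at
    # full scale; small studies lower min_genes so healthy cells clear it)
    qc_min_genes: int = 1250
    qc_max_mito: float = 0.25
    damaged_mito_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_mito_genes", "frac_damaged_cells", "tag_detection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("mu_range", "kon_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.n_samples < 1 or self.cells_per_sample < 1 or self.n_genes < 1:
            raise ValueError("study dimensions must be positive")

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class StudyTruth:
    """Ground truth for a generated study.

    ``genes``: per gene x sample rows with mu_true, kon_true and
    burst_size_true = mu_true / kon_true. ``cells``: per-cell table with the
    planted ``damaged`` flag.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame


def _resolve_effects(config: StudyConfig) -> list[tuple[str, str, float, np.ndarray | None]]:
    resolved = []
    names = config.sample_names
    for eff in config.effects:
        if isinstance(eff.sample, int):
            if not 0 <= eff.sample < config.n_samples:
                raise ValueError(f"effect sample index {eff.sample} out of range")
            sample = names[eff.sample]
        else:
            if eff.sample not in names:
                raise ValueError(f"effect sample {eff.sample!r} not in study")
            sample = eff.sample
        genes = None
        if eff.genes is not None:
            genes = np.asarray(eff.genes, dtype=int)
            if genes.size and (genes.min() < 0 or genes.max() >= config.n_genes):
                raise ValueError("effect gene index out of range")
        resolved.append((sample, eff.param, eff.factor, genes))
    return resolved


def generate_study(config: StudyConfig) -> tuple[CountMatrix, StudyTruth]:
    """Generate a multi-sample study with known kinetics.

    Gene layout: ``n_genes`` NB genes named GENE0001.. (a fraction of them
    mitochondrial, renamed MT-1..), plus one tag gene per tag type appended
    at the end. Tag genes are expressed only in their sample group (samples
    are split evenly across tag types, first group first) and are masked to
    the configured detection rate. Damaged cells are healthy cells
    downsampled below the detected-genes threshold with inflated
    mitochondrial counts.
    """
    effects = _resolve_effects(config)
    rng = np.random.default_rng(config.seed)
    names = config.sample_names
    G, C = config.n_genes, config.cells_per_sample

    n_mito = int(round(config.frac_mito_genes * G))
    mito_idx = np.arange(n_mito)  # first genes are mitochondrial
    gene_ids = np.array(
        [f"MT-{i + 1}" if i < n_mito else f"GENE{i + 1:05d}" for i in range(G)],
        dtype=object,
    )

    # base kinetics shared across samples
    mu = np.exp(rng.uniform(np.log(config.mu_range[0]), np.log(config.mu_range[1]), G))
    kon = np.exp(rng.uniform(np.log(config.kon_range[0]), np.log(config.kon_range[1]), G))
    if n_mito and config.mito_count_fraction > 0:
        # rescale mitochondrial means so healthy cells carry a realistic
        # MT- share of molecules
        target = config.mito_count_fraction * mu.sum()
        mu[mito_idx] *= target / mu[mito_idx].sum()
        kon[mito_idx] = np.maximum(kon[mito_idx], config.mito_kon_floor)

    # tag genes: evenly split samples across tag types
    tag_names = tuple(config.tag_names)
    n_tags = len(tag_names)
    tag_group = {}  # sample -> tag index
    if n_tags:
        per = max(1, math.ceil(config.n_samples / n_tags))
        for i, s in enumerate(names):
            tag_group[s] = min(i // per, n_tags - 1)

    all_gene_ids = np.concatenate([gene_ids, np.array(tag_names, dtype=object)])

    truth_rows = []
    cell_rows = []
    blocks = []
    barcodes = []
    sample_labels = []
    n_damaged = int(round(config.frac_damaged_cells * C))

    for s_i, sample in enumerate(names):
        mu_s = mu.copy()
        kon_s = kon.copy()
        for eff_sample, param, factor, genes in effects:
            if eff_sample != sample:
                continue
            sel = slice(None) if genes is None else genes
            if param == "burst_size":
                mu_s[sel] = mu_s[sel] * factor
            else:  # kon at fixed burst size: mu scales too
                kon_s[sel] = kon_s[sel] * factor
                mu_s[sel] = mu_s[sel] * factor

        counts = np.empty((G + n_tags, C), dtype=np.int64)
        for g in range(G):
            counts[g] = sample_nb_counts(mu_s[g], kon_s[g], C, rng)

        # tag genes: zero except in this sample's tag, masked to detection rate
        counts[G:] = 0
        if n_tags:
            t = tag_group[sample]
            detected = rng.random(C) < config.tag_detection_rate
            n_det = int(detected.sum())
            if n_det:
                # zero-truncated NB so every detected cell is nonzero
                draws = np.zeros(n_det, dtype=np.int64)
                todo = np.arange(n_det)
                while todo.size:
                    d = sample_nb_counts(config.tag_mu, config.tag_kon, todo.size, rng)
                    draws[todo] = d
                    todo = todo[d == 0]
                counts[G + t, detected] = draws

        # damaged cells: last n_damaged of the sample
        damaged = np.zeros(C, dtype=bool)
        if n_damaged:
            damaged[-n_damaged:] = True
            for c in np.flatnonzero(damaged):
                col = counts[:, c]
                # binomially downsample until detected genes fall below the
                # planted threshold (always terminates: retention halves)
                keep = 0.5
                for _ in range(60):
                    col = rng.binomial(col, keep)
                    if (col > 0).sum() <= config.qc_min_genes:
                        break
                # inflate MT- counts past the mito-fraction threshold
                non_mito = col.sum() - col[mito_idx].sum()
                f = config.damaged_mito_fraction
                cur = col[mito_idx].sum()
                need = int(math.ceil(f / (1 - f) * non_mito)) + 1
                if n_mito and need > cur:
                    extra = rng.multinomial(need - cur, np.ones(n_mito) / n_mito)
                    col[mito_idx] += extra
                counts[:, c] = col

        blocks.append(counts)
        bcs = [f"{sample}-CELL{i + 1:05d}" for i in range(C)]
        barcodes.extend(bcs)
        sample_labels.extend([sample] * C)
        cell_rows.append(
            pd.DataFrame({"barcode": bcs, "sample": sample, "damaged": damaged})
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene": gene_ids,
                    "sample": sample,
                    "mu_true": mu_s,
                    "kon_true": kon_s,
                    "burst_size_true": mu_s / kon_s,
                }
            )
        )

    matrix = CountMatrix(
        np.concatenate(blocks, axis=1),
        all_gene_ids,
        np.array(barcodes, dtype=object),
        np.array(sample_labels, dtype=object),
        tag_genes=tag_names,
    )
    truth = StudyTruth(
        genes=pd.concat(truth_rows, ignore_index=True),
        cells=pd.concat(cell_rows, ignore_index=True),
    )
    return matrix, truth


def write_truth(truth: StudyTruth, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.genes.to_csv(path / "truth_genes.tsv", sep="\t", index=False)
    truth.cells.to_csv(path / "truth_cells.tsv", sep="\t", index=False)


def write_study(
    matrix: CountMatrix, truth: StudyTruth, path: str | Path, format: str = "mtx-triplet"
) -> None:
    """Write one matrix directory per sample plus the truth tables."""
    path = Path(path)
    for sample in matrix.samples:
        write_count_matrix(matrix.sample_view(sample), path / sample, format=format)
    write_truth(truth, path)
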