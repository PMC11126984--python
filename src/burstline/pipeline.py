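"""Configured, logged, resumable orchestration of the analysis stages.

A run executes simulate -> qc -> fit -> noise -> compare -> assoc from a
single YAML config, writing every stage's outputs plus a ``manifest.json``
recording the config hash, seed and per-stage status. Re-running with the
same config skips stages whose outputs already exist under the same config
hash (deleting a stage's outputs recomputes that stage and its
descendants); changing the config invalidates the whole run. All randomness
flows from the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, compare, inference, io_qc, noise, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger("burstline")

STAGES = ("simulate", "qc", "fit", "noise", "compare", "assoc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see ``load_config`` for the YAML layout."""

    out_dir: Path
    seed: int = 0
    simulate: dict | None = None  # StudyConfig fields; None = read input_dir
    input_dir: Path | None = None
    input_format: str = "mtx-triplet"
    min_genes: int = io_qc.DEFAULT_MIN_GENES
    max_mito: float = io_qc.DEFAULT_MAX_MITO
    n_steps: int = inference.DEFAULT_N_STEPS
    cv2_max: float = inference.CV2_MAX
    mu_min: float | None = None
    per_sample_kbar: bool = True
    classes: dict = field(default_factory=dict)  # sample -> class label (e.g. CTD length)
    tag_genes: tuple[str, ...] = ("Dendra2", "HaloTag")
    contrasts: list = field(default_factory=list)  # {name, group_a: [...], group_b: [...]}
    llps_file: Path | None = None
    tag_positive_only: bool = False

    def validate(self, samples: list[str] | None = None) -> None:
        for contrast in self.contrasts:
            for key in ("name", "group_a", "group_b"):
                if key not in contrast:
                    raise PipelineError("config", f"contrast missing {key!r}: {contrast}")
            if samples is not None:
                for side in ("group_a", "group_b"):
                    for s in contrast[side]:
                        if s not in samples:
                            raise PipelineError(
                                "config",
                                f"contrast {contrast['name']!r} references "
                                f"undefined sample {s!r}",
                            )
        if samples is not None:
            for s in self.classes:
                if s not in samples:
                    raise PipelineError("config", f"class map references undefined sample {s!r}")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file.

    Recognized keys: ``out_dir``, ``seed``, ``simulate`` (StudyConfig
    fields), ``input_dir``, ``input_format``, ``qc: {min_genes, max_mito}``,
    ``fit: {n_steps, cv2_max, mu_min}``, ``noise: {per_sample_kbar}``,
    ``classes`` (sample -> class), ``tags``, ``contrasts``
    (name/group_a/group_b), ``llps_file``, ``assoc: {tag_positive_only}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    qc = raw.get("qc", {})
    fit = raw.get("fit", {})
    nz = raw.get("noise", {})
    assoc = raw.get("assoc", {})
    cfg = PipelineConfig(
        out_dir=Path(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
        input_format=raw.get("input_format", "mtx-triplet"),
        min_genes=int(qc.get("min_genes", io_qc.DEFAULT_MIN_GENES)),
        max_mito=float(qc.get("max_mito", io_qc.DEFAULT_MAX_MITO)),
        n_steps=int(fit.get("n_steps", inference.DEFAULT_N_STEPS)),
        cv2_max=float(fit.get("cv2_max", inference.CV2_MAX)),
        mu_min=fit.get("mu_min"),
        per_sample_kbar=bool(nz.get("per_sample_kbar", True)),
        classes=raw.get("classes", {}) or {},
        tag_genes=tuple(raw.get("tags", ("Dendra2", "HaloTag"))),
        contrasts=raw.get("contrasts", []) or [],
        llps_file=Path(raw["llps_file"]) if raw.get("llps_file") else None,
        tag_positive_only=bool(assoc.get("tag_positive_only", False)),
    )
    cfg.validate()
    return cfg


def _manifest_path(out: Path) -> Path:
    return out / "manifest.json"


def _read_manifest(out: Path) -> dict:
    p = _manifest_path(out)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _write_manifest(out: Path, manifest: dict) -> None:
    _manifest_path(out).write_text(json.dumps(manifest, indent=2, default=str))


def _stage_done(manifest: dict, stage: str, cfg_hash: str, outputs: list[Path]) -> bool:
    info = manifest["stages"].get(stage)
    return (
        info is not None
        and info.get("config_hash") == cfg_hash
        and all(Path(p).exists() for p in info.get("outputs", []))
        and bool(info.get("outputs"))
        and all(o.exists() for o in outputs)
    )


def run_pipeline(config: PipelineConfig, resume: bool = True) -> Path:
    """Run every stage; returns the run directory. See module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest = _read_manifest(out) if resume else {"stages": {}}
    if manifest.get("config_hash") not in (None, cfg_hash):
        manifest = {"stages": {}}  # config changed: start over
    manifest["config_hash"] = cfg_hash
    manifest["seed"] = config.seed
    config.validate()

    def record(stage: str, outputs: list[Path], counts: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "config_hash": cfg_hash,
            "outputs": [str(p) for p in outputs],
            "counts": counts or {},
        }
        _write_manifest(out, manifest)
        logger.info("stage %s done: %s", stage, counts or "")

    # ---- simulate ---------------------------------------------------------
    sim_dir = out / "simulated"
    if config.simulate is not None:
        outputs = [sim_dir / "truth_genes.tsv"]
        if resume and _stage_done(manifest, "simulate", cfg_hash, outputs):
            logger.info("stage simulate: resumed")
        else:
            sim_kwargs = dict(config.simulate)
            effects = [
                simulate.EffectSpec(**e) for e in sim_kwargs.pop("effects", [])
            ]
            study_cfg = simulate.StudyConfig(
                seed=sim_kwargs.pop("seed", config.seed), effects=tuple(effects), **sim_kwargs
            )
            matrix, truth = simulate.generate_study(study_cfg)
            simulate.write_study(matrix, truth, sim_dir)
            record("simulate", outputs, {"n_cells": matrix.n_cells, "n_genes": matrix.n_genes})
        input_dir = sim_dir
    else:
        if config.input_dir is None:
            raise PipelineError("config", "either simulate: or input_dir: is required")
        input_dir = Path(config.input_dir)
        manifest["stages"].setdefault("simulate", {"config_hash": cfg_hash, "outputs": [], "counts": {"skipped": "external input"}})

    # ---- qc ---------------------------------------------------------------
    qc_dir = out / "qc"
    qc_report_path = qc_dir / "qc_report.tsv"
    filtered_dir = qc_dir / "filtered"
    matrix = _read_study(input_dir, config)
    config.validate(matrix.samples)
    if resume and _stage_done(manifest, "qc", cfg_hash, [qc_report_path]):
        filtered = _read_study(filtered_dir, config)
        logger.info("stage qc: resumed")
    else:
        qc = io_qc.compute_cell_qc(matrix)
        filtered, report = io_qc.filter_cells(
            matrix, qc, min_genes=config.min_genes, max_mito=config.max_mito
        )
        qc_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(qc_report_path, sep="\t")
        for sample in filtered.samples:
            io_qc.write_count_matrix(filtered.sample_view(sample), filtered_dir / sample)
        record(
            "qc",
            [qc_report_path],
            {
                "cells_in": matrix.n_cells,
                "cells_removed": int((~report["kept"]).sum()),
                "cells_kept": filtered.n_cells,
            },
        )

    # ---- fit --------------------------------------------------------------
    est_path = out / "estimates.tsv"
    if resume and _stage_done(manifest, "fit", cfg_hash, [est_path]):
        estimates = pd.read_csv(est_path, sep="\t")
        logger.info("stage fit: resumed")
    else:
        ss = np.random.SeedSequence(config.seed)
        sample_seeds = ss.spawn(len(filtered.samples))
        frames = []
        for sample, s_seed in zip(filtered.samples, sample_seeds):
            frames.append(
                inference.fit_sample(
                    filtered, sample, n_steps=config.n_steps,
                    seed=int(s_seed.generate_state(1)[0] % (2**31)),
                    cv2_max=config.cv2_max, mu_min=config.mu_min,
                )
            )
        estimates = pd.concat(frames, ignore_index=True)
        estimates = inference.exclude_poor_fits(estimates, cv2_max=config.cv2_max)
        estimates.to_csv(est_path, sep="\t", index=False)
        record("fit", [est_path], {
            "genes_fit": int(estimates["fit"].sum()),
            "genes_excluded": int(estimates["excluded"].sum()),
        })

    # ---- noise ------------------------------------------------------------
    noise_path = out / "estimates_noise.tsv"
    if resume and _stage_done(manifest, "noise", cfg_hash, [noise_path]):
        annotated = pd.read_csv(noise_path, sep="\t")
        logger.info("stage noise: resumed")
    else:
        annotated = noise.add_noise_stats(estimates, per_sample=config.per_sample_kbar)
        annotated.to_csv(noise_path, sep="\t", index=False)
        record("noise", [noise_path], {
            "samples": len(annotated["sample"].unique()),
        })

    # ---- compare ----------------------------------------------------------
    cmp_dir = out / "compare"
    tests_path = cmp_dir / "pairwise_tests.tsv"
    order_path = cmp_dir / "ordering.tsv"
    if resume and _stage_done(manifest, "compare", cfg_hash, [tests_path, order_path]):
        logger.info("stage compare: resumed")
    else:
        cmp_dir.mkdir(parents=True, exist_ok=True)
        tests = compare.pairwise_tests(annotated)
        tests.to_csv(tests_path, sep="\t", index=False)
        order_rows = []
        for param in compare.KINETIC_PARAMETERS:
            result = compare.tournament_ordering(annotated, param)
            for rank, s in enumerate(result.ranking, start=1):
                order_rows.append(
                    {"parameter": param, "sample": s,
                     "wins": result.wins[s], "rank": rank}
                )
        pd.DataFrame(order_rows).to_csv(order_path, sep="\t", index=False)
        kw_rows = []
        if config.classes:
            ok = annotated.loc[~annotated["excluded"].astype(bool)]
            for param in compare.KINETIC_PARAMETERS:
                groups = [
                    ok.loc[ok["sample"].isin(
                        [s for s, c in config.classes.items() if c == cls]
                    ), param].dropna().to_numpy()
                    for cls in sorted(set(config.classes.values()), key=str)
                ]
                groups = [g for g in groups if g.size]
                if len(groups) >= 2:
                    h, p = compare.kruskal_wallis(groups)
                    kw_rows.append({"parameter": param, "H": h, "p": p})
            pd.DataFrame(kw_rows).to_csv(cmp_dir / "kruskal_wallis.tsv", sep="\t", index=False)
        record("compare", [tests_path, order_path], {"n_tests": len(tests)})

    # ---- assoc ------------------------------------------------------------
    assoc_dir = out / "assoc"
    assoc_outputs: list[Path] = []
    if resume and _stage_done(manifest, "assoc", cfg_hash, [assoc_dir / "done.json"]):
        logger.info("stage assoc: resumed")
    else:
        assoc_dir.mkdir(parents=True, exist_ok=True)
        normalized = io_qc.normalize(filtered)
        counts: dict = {}
        present_tags = [t for t in config.tag_genes if t in set(filtered.gene_ids)]
        for tag in present_tags:
            cells = filtered.sample_labels == filtered.sample_labels  # all cells
            # pool the tag's own samples: cells where the tag is expressed at all
            tag_samples = [
                s for s in filtered.samples
                if np.asarray(
                    filtered.sample_view(s).counts[filtered.gene_index(tag)].todense()
                ).sum() > 0
            ]
            cells = np.isin(filtered.sample_labels, tag_samples)
            if config.tag_positive_only:
                cells &= association.select_tag_positive_cells(filtered, [tag])
            if not cells.any():
                continue
            try:
                corr = association.tag_correlation(normalized, tag, cells=cells)
            except (ValueError, KeyError) as exc:
                logger.warning("tag %s correlation skipped: %s", tag, exc)
                continue
            path = assoc_dir / f"correlation_{tag}.tsv"
            corr.to_csv(path, sep="\t", index=False)
            assoc_outputs.append(path)
            counts[f"corr_significant_{tag}"] = int(corr["significant"].sum())
        llps = None
        if config.llps_file is not None:
            llps = {
                line.strip() for line in Path(config.llps_file).read_text().splitlines()
                if line.strip()
            }
        enr_rows = []
        for contrast in config.contrasts:
            ga = np.isin(filtered.sample_labels, contrast["group_a"])
            gb = np.isin(filtered.sample_labels, contrast["group_b"])
            de = association.differential_expression(normalized, ga, gb)
            path = assoc_dir / f"de_{contrast['name']}.tsv"
            de.to_csv(path, sep="\t", index=False)
            assoc_outputs.append(path)
            counts[f"de_significant_{contrast['name']}"] = int(de["significant"].sum())
            if llps:
                sig = de.loc[de["significant"], "gene"]
                res = association.llps_enrichment(
                    sig, llps, de["gene"], n_contrasts=max(1, len(config.contrasts))
                )
                enr_rows.append(
                    {"contrast": contrast["name"], "odds_ratio": res.odds_ratio,
                     "p": res.p_value, "p_adj": res.p_adjusted,
                     "n_significant": res.n_significant, "n_llps": res.n_llps}
                )
        if enr_rows:
            pd.DataFrame(enr_rows).to_csv(assoc_dir / "enrichment.tsv", sep="\t", index=False)
        done = assoc_dir / "done.json"
        done.write_text(json.dumps(counts, indent=2))
        assoc_outputs.append(done)
        record("assoc", assoc_outputs, counts)

    _write_manifest(out, manifest)
    return out


def _read_study(path: Path, config: PipelineConfig) -> io_qc.CountMatrix:
    """Read per-sample matrix directories under ``path`` into one matrix."""
    sample_dirs = sorted(
        p for p in Path(path).iterdir()
        if p.is_dir() and (
            (p / "matrix.mtx").exists() or (p / "counts.csv").exists()
        )
    )
    if not sample_dirs:
        raise PipelineError("qc", f"no sample matrix directories under {path}")
    parts = []
    for d in sample_dirs:
        fmt = "mtx-triplet" if (d / "matrix.mtx").exists() else "dense-csv"
        parts.append(
            io_qc.read_count_matrix(
                d, format=fmt, tag_genes=config.tag_genes, default_sample=d.name
            )
        )
    first = parts[0]
    for p in parts[1:]:
        if not np.array_equal(p.gene_ids, first.gene_ids):
            raise PipelineError("qc", "sample matrices disagree on gene ids")
    import scipy.sparse as sp

    return io_qc.CountMatrix(
        sp.hstack([p.counts for p in parts]).tocsr(),
        first.gene_ids,
        np.concatenate([p.barcodes for p in parts]),
        np.concatenate([p.sample_labels for p in parts]),
        tag_genes=config.tag_genes,
    )
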