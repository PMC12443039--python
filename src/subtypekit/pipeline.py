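"""End-to-end pipeline: simulate -> normalize -> subtype -> signature ->
lineage -> risk, with a checksummed artifact manifest.

Every randomized stage derives its seed from the global pipeline seed, so
two runs with the same configuration produce bitwise-identical artifacts
and manifests.  Each stage can also be re-run standalone from its
predecessors' files through the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from .containers import ExpressionMatrix
from .lineage import lineage_score
from .nmf import (assign_clusters, basis_specificity, consensus_over_runs,
                  cophenetic_curve, select_rank)
from .normalize import normalize_counts, select_genes
from .signature import build_signature, cross_validate_signature
from .survival import kaplan_meier, run_model_registry, truncate_follow_up
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("subtypekit")

__all__ = ["PipelineConfig", "run_pipeline"]

_SCHEMA: dict[str, dict] = {
    "paths": {"counts": str, "annotation": str, "clinical": str,
              "output_dir": str},
    "simulate": dict,     # SyntheticConfig keyword arguments
    "normalization": {"method": str, "n_top": int, "median_min": float,
                      "log_variance": bool},
    "nmf": {"ranks": list, "n_runs": int, "max_iter": int,
            "conn_stop": int, "conn_interval": int},
    "signature": {"n_per_class": int, "cv_min_n": int, "cv_max_n": int,
                  "cv_repeats": int, "train_fraction": float,
                  "run_cv": bool},
    "survival": {"models": list, "horizon": float, "test_fraction": float},
    "seed": int,
}


@dataclass
class PipelineConfig:
    paths: dict = field(default_factory=dict)
    simulate: dict | None = None
    normalization: dict = field(default_factory=dict)
    nmf: dict = field(default_factory=dict)
    signature: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {sorted(unknown)}")
        for section, schema in _SCHEMA.items():
            if section not in raw or not isinstance(schema, dict):
                continue
            if not isinstance(raw[section], dict):
                raise ValueError(f"configuration section {section!r} "
                                 "must be a mapping")
            if section == "simulate":
                continue          # validated by SyntheticConfig itself
            bad = set(raw[section]) - set(schema)
            if bad:
                raise ValueError(
                    f"unknown key(s) in section {section!r}: {sorted(bad)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        return {"paths": self.paths, "simulate": self.simulate,
                "normalization": self.normalization, "nmf": self.nmf,
                "signature": self.signature, "survival": self.survival,
                "seed": self.seed}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig) -> None:
        self.outdir = outdir
        self.config = config
        self.artifacts: dict[str, str] = {}

    def add(self, path: Path) -> None:
        rel = str(path.relative_to(self.outdir))
        self.artifacts[rel] = _sha256(path)

    def write(self) -> Path:
        payload = {"config": self.config.to_dict(),
                   "artifacts": self.artifacts}
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage=%s wall_time=%.2fs", name,
                        time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, outdir: Path, man: _Manifest):
    sim_kwargs = dict(cfg.simulate or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    ds = generate_dataset(SyntheticConfig(**sim_kwargs))
    skio.write_counts(ds.counts, outdir / "counts.tsv")
    skio.write_annotation(ds.counts.is_mito, outdir / "annotation.tsv",
                          lineage_sets=ds.lineage_sets)
    clinical = ds.survival.copy()
    clinical["true_subtype"] = ds.true_labels
    skio.write_clinical(clinical, outdir / "clinical.tsv")
    skio.write_gene_sets_json(ds.lineage_sets, outdir / "lineage_sets.json")
    truth = {str(k): v for k, v in ds.true_program_genes.items()}
    (outdir / "true_program_genes.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True))
    for f in ("counts.tsv", "annotation.tsv", "clinical.tsv",
              "lineage_sets.json", "true_program_genes.json"):
        man.add(outdir / f)
    return ds


@_stage("normalize")
def _run_normalize(cfg: PipelineConfig, counts, outdir: Path, man: _Manifest):
    ncfg = cfg.normalization
    expr = normalize_counts(counts, method=ncfg.get("method",
                                                    "median_of_ratios"))
    selected = select_genes(expr,
                            n_top=ncfg.get("n_top", 5000),
                            median_min=ncfg.get("median_min", 1.0),
                            log_variance=ncfg.get("log_variance", False))
    skio.write_expression(expr, outdir / "normalized.tsv")
    skio.write_expression(selected, outdir / "selected.tsv")
    man.add(outdir / "normalized.tsv")
    man.add(outdir / "selected.tsv")
    return expr, selected


@_stage("subtype")
def _run_subtype(cfg: PipelineConfig, selected: ExpressionMatrix,
                 outdir: Path, man: _Manifest):
    ncfg = cfg.nmf
    ranks = ncfg.get("ranks", [2, 3, 4, 5, 6])
    n_runs = ncfg.get("n_runs", 30)
    fit_kwargs = {k: ncfg[k] for k in ("max_iter", "conn_stop",
                                       "conn_interval") if k in ncfg}
    results = []
    for rank in ranks:
        res = consensus_over_runs(selected, rank, n_runs=n_runs,
                                  base_seed=cfg.seed + 1000 * rank,
                                  **fit_kwargs)
        cons = pd.DataFrame(res.consensus, index=selected.sample_ids,
                            columns=selected.sample_ids)
        cons.to_csv(outdir / f"consensus_rank{rank}.tsv", sep="\t")
        man.add(outdir / f"consensus_rank{rank}.tsv")
        results.append(res)
    curve = cophenetic_curve(results)
    curve.to_csv(outdir / "rank_curve.tsv", sep="\t")
    man.add(outdir / "rank_curve.tsv")
    rank = select_rank(results)
    best = next(r for r in results if r.rank == rank).best_fit
    pd.DataFrame(best.W, index=selected.gene_ids).to_csv(
        outdir / "nmf_W.tsv", sep="\t")
    pd.DataFrame(best.H, columns=selected.sample_ids).to_csv(
        outdir / "nmf_H.tsv", sep="\t")
    assign = assign_clusters(best)
    assign.labels.to_frame().to_csv(outdir / "assignments.tsv", sep="\t")
    spec = basis_specificity(best)
    spec_out = spec.profile.copy()
    spec_out.insert(0, "specificity", spec.score)
    spec_out.to_csv(outdir / "specificity.tsv", sep="\t")
    for f in ("nmf_W.tsv", "nmf_H.tsv", "assignments.tsv",
              "specificity.tsv"):
        man.add(outdir / f)
    return rank, best, assign


@_stage("signature")
def _run_signature(cfg: PipelineConfig, selected, assign, outdir: Path,
                   man: _Manifest):
    scfg = cfg.signature
    n_per_class = scfg.get("n_per_class", 20)
    if scfg.get("run_cv", True):
        report = cross_validate_signature(
            selected, assign,
            n_range=range(scfg.get("cv_min_n", 1),
                          scfg.get("cv_max_n", 30) + 1),
            repeats=scfg.get("cv_repeats", 100),
            train_fraction=scfg.get("train_fraction", 0.7),
            seed=cfg.seed + 7)
        report.per_N_errors.to_csv(outdir / "cv_report.tsv", sep="\t")
        man.add(outdir / "cv_report.tsv")
    sig = build_signature(selected, assign, n_per_class)
    skio.write_signature_json(sig, outdir / "signature.json",
                              provenance={"seed": cfg.seed})
    man.add(outdir / "signature.json")
    return sig


@_stage("lineage")
def _run_lineage(expr, lineage_sets, outdir: Path, man: _Manifest):
    scores = lineage_score(expr, lineage_sets)
    scores.to_csv(outdir / "lineage_scores.tsv", sep="\t")
    man.add(outdir / "lineage_scores.tsv")
    return scores


@_stage("risk")
def _run_risk(cfg: PipelineConfig, surv: pd.DataFrame, assign, sig,
              expr: ExpressionMatrix, outdir: Path, man: _Manifest):
    vcfg = cfg.survival
    horizon = vcfg.get("horizon")
    if horizon:
        surv = truncate_follow_up(surv, horizon)
    rng = np.random.default_rng(cfg.seed + 13)
    labels = assign.labels
    test_frac = vcfg.get("test_fraction", 0.3)
    test_mask = pd.Series(False, index=surv.index)
    for c in sorted(labels.unique()):     # stratified holdout split
        ids = labels.index[labels == c].to_numpy()
        n_test = max(1, int(round(test_frac * len(ids))))
        test_mask.loc[rng.choice(ids, size=n_test, replace=False)] = True
    tr, te = surv.loc[~test_mask], surv.loc[test_mask]
    expr_tr = ExpressionMatrix(expr.values.loc[:, ~test_mask.to_numpy()],
                               expr.is_mito)
    expr_te = ExpressionMatrix(expr.values.loc[:, test_mask.to_numpy()],
                               expr.is_mito)
    table = run_model_registry(tr, te, sig, expr_tr, expr_te,
                               models=vcfg.get("models"))
    table.to_csv(outdir / "risk_models.tsv", sep="\t")
    man.add(outdir / "risk_models.tsv")
    km = kaplan_meier(surv, labels)
    km.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    man.add(outdir / "km_curves.tsv")
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest as a dict."""
    outdir = Path(config.paths.get("output_dir", "subtypekit_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(outdir, config)

    lineage_sets = None
    if config.simulate is not None:
        ds = _run_simulate(config, outdir, man)
        counts, surv = ds.counts, ds.survival
        lineage_sets = ds.lineage_sets
    else:
        counts = skio.read_counts(config.paths["counts"],
                                  config.paths.get("annotation"))
        surv = skio.read_clinical(config.paths["clinical"])
        if config.paths.get("annotation"):
            ann = skio.read_annotation(config.paths["annotation"])
            if "lineage_set" in ann.columns:
                lineage_sets = skio.lineage_sets_from_annotation(ann)

    expr, selected = _run_normalize(config, counts, outdir, man)
    rank, best, assign = _run_subtype(config, selected, outdir, man)
    sig = _run_signature(config, selected, assign, outdir, man)
    if lineage_sets is not None:
        _run_lineage(expr, lineage_sets, outdir, man)
    _run_risk(config, surv, assign, sig, selected, outdir, man)
    path = man.write()
    logger.info("pipeline complete: %s (%d artifacts)", path,
                len(man.artifacts))
    return json.loads(path.read_text())
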