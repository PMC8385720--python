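"""Config-driven end-to-end run: stratify -> immune scores -> DEG -> per-region
DMG -> DMEG -> ORA -> drug proximity -> prognosis.

Every stage writes deterministic TSV/JSON artifacts into the output directory
and a run manifest records versions, per-stage derived seeds and SHA-256
hashes of every artifact, so a rerun with the same config is bit-identical
and no stage can silently mutate another stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import aggregate_region_beta, call_degs, call_dmgs, moderated_t
from .dmeg import chromosome_distribution, dmeg_gene_set, intersect_dmegs, lda_loocv
from .enrichment import ora
from .immune import compare_score_groups, estimate_scores, pd1_negative_samples
from .io import (
    NORMAL,
    TUMOR,
    read_clinical,
    read_drug_targets,
    read_expression,
    read_gmt,
    read_group_labels,
    read_methylation,
    read_ppi,
)
from .prognosis import (
    cox_univariate,
    dichotomize,
    fit_risk_model,
    km_curve,
    lasso_stability,
    logrank,
    risk_score,
    split_cohort,
    td_roc_auc,
)
from .proximity import drug_proximities, screen_drugs

logger = logging.getLogger(__name__)

STAGES = ("stratify", "immune", "deg", "dmg", "dmeg", "ora", "proximity", "prognosis")


@dataclass
class PipelineConfig:
    """Input paths, thresholds and seeds of an end-to-end run.

    Threshold defaults are the analysis' canonical values: DEG FDR 0.01 and
    |log2FC| 1, DMG FDR 0.05 and |delta beta| 0.3, proximity threshold 0.8,
    PPI confidence cutoff 600, 1000 LASSO repetitions with 10 folds.
    """

    expression: str
    groups: str
    beta: str
    manifest: str
    clinical: str
    signatures: str  # GMT with stromal/immune signatures (also used for ORA)
    ppi: str
    drug_targets: str
    out_dir: str
    checkpoint_gene: str = "PDCD1"
    stromal_set: str = "STROMAL"
    immune_set: str = "IMMUNE"
    expression_log_scale: bool = True
    deg_fdr: float = 0.01
    deg_lfc: float = 1.0
    dmg_fdr: float = 0.05
    dmg_delta: float = 0.3
    regions: tuple[str, ...] = ("TSS200", "TSS1500", "Body")
    ppi_min_score: float = 600.0
    proximity_threshold: float = 0.8
    null_draws: int = 0
    lasso_reps: int = 1000
    lasso_folds: int = 10
    horizons: tuple[float, ...] = (365.0, 1095.0, 1825.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "deg_lfc", "dmg_fdr", "dmg_delta", "proximity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("regions", "horizons"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_inputs(self) -> None:
        for name in ("expression", "groups", "beta", "manifest", "clinical", "signatures", "ppi", "drug_targets"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config input {name!r} does not exist: {p}")


def stage_seed(run_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the run seed (stage-name CRC mix)."""
    return (run_seed ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": [], "artifacts": {}}

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"stage": stage, "path": str(path), "sha256": _sha256(path)}

    def run_stage(stage, fn):
        logger.info("[%s] starting", stage)
        try:
            fn()
        except Exception as exc:  # halt with stage name and cause
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({"name": stage, "seed": stage_seed(config.seed, stage)})
        logger.info("[%s] done", stage)

    expr = read_expression(config.expression, config.expression_log_scale, config.groups)
    meth = read_methylation(config.beta, config.manifest)
    clinical = read_clinical(config.clinical)
    signatures = read_gmt(config.signatures)
    ppi = read_ppi(config.ppi, config.ppi_min_score)
    drugs = read_drug_targets(config.drug_targets)

    state: dict[str, Any] = {}

    def s_stratify():
        negatives = pd1_negative_samples(expr, config.checkpoint_gene)
        state["negatives"] = negatives
        path = out / "pd1_negative_samples.txt"
        path.write_text("\n".join(negatives) + "\n")
        emit("stratify", "pd1_negative_samples", path)

    def s_immune():
        scores = estimate_scores(expr, signatures[config.stromal_set].members, signatures[config.immune_set].members)
        comparison = compare_score_groups(scores, expr.group_labels)
        path = out / "immune_scores.tsv"
        scores.scores.to_csv(path, sep="\t", index_label="sample")
        emit("immune", "immune_scores", path)
        path = out / "immune_score_tests.tsv"
        comparison.to_csv(path, sep="\t", index_label="score")
        emit("immune", "immune_score_tests", path)

    def s_deg():
        normals = expr.samples_in_group(NORMAL)
        cohort = expr.subset_samples(normals + state["negatives"])
        stats = moderated_t(cohort.values, normals, state["negatives"])
        deg = call_degs(stats, config.deg_fdr, config.deg_lfc)
        state["deg"] = deg
        state["analysis_samples"] = normals + state["negatives"]
        path = out / "deg.tsv"
        deg.table.to_csv(path, sep="\t", index_label="feature")
        emit("deg", "deg", path)

    def s_dmg():
        labels = expr.group_labels
        samples = [s for s in state["analysis_samples"] if s in meth.beta.columns]
        dmg_tables = {}
        for region in config.regions:
            rb = aggregate_region_beta(meth, region)[samples]
            table = call_dmgs(rb, labels[samples], region, config.dmg_fdr, config.dmg_delta)
            dmg_tables[region] = table
            path = out / f"dmg_{region}.tsv"
            table.table.to_csv(path, sep="\t", index_label="feature")
            emit("dmg", f"dmg_{region}", path)
        state["dmg_tables"] = dmg_tables

    def s_dmeg():
        records = intersect_dmegs(
            state["deg"], state["dmg_tables"], config.dmg_delta, config.deg_lfc
        )
        state["dmeg_records"] = records
        state["dmeg_genes"] = dmeg_gene_set(records)
        path = out / "dmeg.tsv"
        records.to_csv(path, sep="\t", index=False)
        emit("dmeg", "dmeg", path)
        chrom = chromosome_distribution(records, meth.manifest)
        path = out / "dmeg_chromosomes.tsv"
        chrom.to_csv(path, sep="\t", index_label="chromosome")
        emit("dmeg", "dmeg_chromosomes", path)
        if state["dmeg_genes"]:
            feats = expr.values.loc[state["dmeg_genes"], state["analysis_samples"]].T
            y = expr.group_labels[state["analysis_samples"]].map({NORMAL: 0, TUMOR: 1})
            try:
                report = lda_loocv(feats, y)
                (out / "dmeg_lda_report.json").write_text(
                    json.dumps(
                        {
                            "auc": report.auc,
                            "roc": report.roc_points.to_dict(orient="list"),
                            "scores": {s: float(v) for s, v in report.scores.items()},
                        },
                        indent=2,
                    )
                )
                emit("dmeg", "dmeg_lda_report", out / "dmeg_lda_report.json")
            except ValueError as exc:
                logger.warning("skipping LDA validation: %s", exc)

    def s_ora():
        if not state["dmeg_genes"]:
            logger.warning("no DMEGs; ORA on DEG list instead")
            query = state["deg"].called()
        else:
            query = state["dmeg_genes"]
        table = ora(query, signatures, expr.genes)
        path = out / "ora.tsv"
        table.to_csv(path, sep="\t", index=False)
        emit("ora", "ora", path)

    def s_proximity():
        disease = [g for g in (state["dmeg_genes"] or state["deg"].called()) if g in ppi]
        if not disease:
            logger.warning("no disease gene in the PPI graph; skipping proximity scores")
            (out / "proximity.tsv").write_text("drug\tproximity\tn_targets\n")
            emit("proximity", "proximity", out / "proximity.tsv")
            return
        results = drug_proximities(set(disease), drugs, ppi)
        rows = pd.DataFrame(
            {
                "drug": [r.drug for r in results],
                "proximity": [r.proximity for r in results],
                "n_targets": [len(r.terms) for r in results],
            }
        )
        path = out / "proximity.tsv"
        rows.to_csv(path, sep="\t", index=False)
        emit("proximity", "proximity", path)
        hits = screen_drugs(results, config.proximity_threshold)
        path = out / "proximity_hits.tsv"
        pd.DataFrame({"drug": [r.drug for r in hits], "proximity": [r.proximity for r in hits]}).to_csv(
            path, sep="\t", index=False
        )
        emit("proximity", "proximity_hits", path)

    def s_prognosis():
        seed = stage_seed(config.seed, "prognosis")
        negatives = [s for s in state["negatives"] if s in clinical.data.index]
        train, val = split_cohort(negatives, seed)
        genes = state["dmeg_genes"] or state["deg"].called()[:30]
        feats = expr.values.loc[genes]
        stab = lasso_stability(
            feats[train], clinical.subset(train), config.lasso_reps, config.lasso_folds, seed
        )
        stab.combinations.to_csv(out / "lasso_combinations.tsv", sep="\t", index_label="combination")
        emit("prognosis", "lasso_combinations", out / "lasso_combinations.tsv")
        selected = list(stab.top_combination)
        if not selected:
            selected = list(stab.marginal.sort_values(ascending=False).head(3).index)
            logger.warning("modal combination empty; using top marginal genes %s", selected)
        model = fit_risk_model(selected, feats[train], clinical.subset(train), seed=seed)
        if all(c == 0.0 for c in model.coefficients):
            logger.warning("penalized coefficients all zero; unpenalized refit on %s", selected)
            model = fit_risk_model(selected, feats[train], clinical.subset(train), mode="refit")
        model.to_json(out / "risk_model.json")
        emit("prognosis", "risk_model", out / "risk_model.json")

        cox_rows = [cox_univariate(feats.loc[g, train], clinical.subset(train), gene=g) for g in selected]
        pd.DataFrame([r.__dict__ for r in cox_rows]).to_csv(out / "cox_univariate.tsv", sep="\t", index=False)
        emit("prognosis", "cox_univariate", out / "cox_univariate.tsv")

        evaluation: dict[str, Any] = {"train_n": len(train), "validation_n": len(val), "split_seed": seed}
        for name, subset in (("train", train), ("validation", val)):
            scores = risk_score(model, feats[subset])
            clin = clinical.subset(subset)
            groups = dichotomize(scores, "zscore")
            entry: dict[str, Any] = {
                "n_high": int((groups == "high").sum()),
                "n_low": int((groups == "low").sum()),
            }
            if entry["n_high"] and entry["n_low"]:
                hi, lo = groups[groups == "high"].index, groups[groups == "low"].index
                chi2, p = logrank(
                    clin.data.loc[hi, "time"], clin.data.loc[hi, "event"],
                    clin.data.loc[lo, "time"], clin.data.loc[lo, "event"],
                )
                entry["logrank_chi2"], entry["logrank_p"] = chi2, p
            aucs = {}
            for h in config.horizons:
                try:
                    aucs[str(h)] = td_roc_auc(scores, clin, h)
                except ValueError as exc:
                    aucs[str(h)] = None
                    logger.warning("%s horizon %s: %s", name, h, exc)
            entry["td_auc"] = aucs
            evaluation[name] = entry
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
        emit("prognosis", "evaluation", out / "evaluation.json")

    for stage, fn in zip(
        STAGES, (s_stratify, s_immune, s_deg, s_dmg, s_dmeg, s_ora, s_proximity, s_prognosis)
    ):
        run_stage(stage, fn)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
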