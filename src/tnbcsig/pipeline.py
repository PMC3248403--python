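"""End-to-end orchestration: discovery -> validation -> interpretation.

One declarative config drives the run: load (or simulate) a multi-dataset
cohort, normalize, rank datasets by comparability and partition into
finding/validation cohorts, run the supervised survival discovery on the
finding cohort, build signatures at the configured delta values (plus
bias-filtered stability variants), score and stratify both cohorts,
validate by Kaplan-Meier/log-rank and multivariate Cox, assign signature
probesets to metagenes, and (optionally) evaluate pCR prediction by ROC.

All randomness flows from the single configured seed via named substreams.
Artifacts (TSV/JSON) are written under the output directory; the returned
report is a machine-readable summary of every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cohort_assembly, metagene_analysis, response_prediction, signature_scoring
from . import sam_survival, survival_stats, synthetic_data
from .expression_io import (
    ExpressionMatrix,
    SampleRecord,
    annotations_to_frame,
    read_annotations,
    read_expression_matrix,
    read_metagene_definitions,
    write_signature_file,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    # input: either paths ...
    expression_path: str | None = None
    annotation_path: str | None = None
    expression_dialect: str = "tsv"
    # ... or simulation
    simulate: bool = False
    generator: synthetic_data.GeneratorConfig | None = None

    # normalization
    normalize: bool = False
    already_log: bool = False

    # partition
    partition_top_k: int | None = None
    partition_threshold: float | None = None

    # discovery
    deltas: list[float] = field(default_factory=lambda: [0.3, 0.5])
    sam_B: int = 100
    seed: int | None = None
    s0_override: float | None = None
    bias_cutoffs: list[float] = field(default_factory=lambda: [75.0, 150.0])

    # downstream
    stratification: str = "self"          # "self" | "external"
    metagene_definitions: str | None = None
    metagene_cutoff: float = 0.2
    response_analysis: bool = False
    response_metagene: str = "immune"
    horizon_months: float = 120.0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.simulate == (self.expression_path is not None):
            raise ValueError("provide input paths or simulate=True, not both/neither")
        if not self.simulate and self.annotation_path is None:
            raise ValueError("annotation_path is required with expression_path")
        if not self.deltas:
            raise ValueError("delta list must be non-empty")
        if self.seed is None:
            raise ValueError("a seed is required")
        if (self.partition_top_k is None) == (self.partition_threshold is None):
            raise ValueError("specify exactly one partition rule")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            factors = [
                synthetic_data.FactorSpec(**f) for f in gen.pop("factors", [])
            ]
            cfg.generator = synthetic_data.GeneratorConfig(
                **gen, **({"factors": factors} if factors else {})
            )
        return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    substream = {name: int(s) for name, s in zip(
        ("simulate", "sam"), rng.integers(0, 2**31 - 1, size=2)
    )}
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    def stage(name: str, **info) -> None:
        logger.info("[%s] %s", name, info)
        report["stages"].append({"stage": name, **_jsonable(info)})

    # ------------------------------------------------------------------ load
    truth = None
    if cfg.simulate:
        gen_cfg = cfg.generator or synthetic_data.GeneratorConfig()
        matrix, records, truth = synthetic_data.generate_cohort(
            gen_cfg, seed=substream["simulate"]
        )
        stage("simulate", n_samples=matrix.n_samples, n_probesets=matrix.n_probesets)
    else:
        records = read_annotations(cfg.annotation_path)
        datasets = {r.sample_id: r.dataset_id for r in records}
        matrix = read_expression_matrix(
            cfg.expression_path, dialect=cfg.expression_dialect, datasets=datasets
        )
        stage("load", n_samples=matrix.n_samples, n_probesets=matrix.n_probesets)
    records_by_id = {r.sample_id: r for r in records}

    # ------------------------------------------------------------- normalize
    if cfg.normalize:
        from .expression_io import log2_median_center, unit_scale

        matrix = unit_scale(log2_median_center(matrix, already_log=cfg.already_log))
        stage("normalize", already_log=cfg.already_log)

    # ------------------------------------------------- comparability + split
    comp = cohort_assembly.comparability_metric(matrix)
    finding_ds, validation_ds = cohort_assembly.partition_by_comparability(
        comp, threshold=cfg.partition_threshold, top_k=cfg.partition_top_k
    )
    in_finding = matrix.dataset_labels.isin(finding_ds)
    finding = matrix.subset_samples(matrix.dataset_labels.index[in_finding])
    validation = matrix.subset_samples(matrix.dataset_labels.index[~in_finding])
    if outdir:
        comp.table.to_csv(outdir / "comparability.tsv", sep="\t", index=False)
    stage(
        "partition",
        finding_datasets=finding_ds,
        validation_datasets=validation_ds,
        n_finding=finding.n_samples,
        n_validation=validation.n_samples,
    )

    # -------------------------------------------------------------- endpoints
    def cohort_efs(m: ExpressionMatrix) -> tuple[list, list[str]]:
        recs = [records_by_id[s] for s in m.sample_ids]
        efs = survival_stats.combine_endpoints(recs, horizon=cfg.horizon_months)
        return efs, [r.sample_id for r in efs]

    efs_finding, fu_finding = cohort_efs(finding)
    efs_validation, fu_validation = cohort_efs(validation)
    stage(
        "endpoints",
        n_followup_finding=len(efs_finding),
        n_followup_validation=len(efs_validation),
        n_excluded=matrix.n_samples - len(efs_finding) - len(efs_validation),
    )

    # -------------------------------------------------------------- discovery
    disc = finding.subset_samples(fu_finding)
    surv = sam_survival.SurvivalVector(
        np.array([r.efs_time for r in efs_finding]),
        np.array([r.efs_event for r in efs_finding]),
    )
    sam = sam_survival.run_sam(
        disc, surv, B=cfg.sam_B, seed=substream["sam"], s0_override=cfg.s0_override
    )
    delta_table = sam.delta_table(cfg.deltas)
    if outdir:
        sam.scores_frame().to_csv(outdir / "sam_scores.tsv", sep="\t", index_label="probeset_id")
        delta_table.to_csv(outdir / "delta_table.tsv", sep="\t", index=False)
    stage("sam", s0=sam.s0, pi0=sam.pi0, delta_table=delta_table.to_dict("records"))

    signatures: dict[float, sam_survival.Signature] = {}
    for delta in cfg.deltas:
        try:
            sig = sam_survival.build_signature(sam, delta)
        except ValueError as exc:
            stage("signature", delta=delta, error=str(exc))
            continue
        signatures[delta] = sig
        if outdir:
            write_signature_file(sig.to_frame(), outdir / f"signature_delta{delta}.tsv")
        stage("signature", delta=delta, n_probesets=len(sig), median_FDR=sig.provenance["median_FDR"])
    if not signatures:
        raise RuntimeError("stage 'signature' failed: nothing called at any delta")

    # --------------------------------------------------- bias-filter variants
    bias = cohort_assembly.kruskal_wallis_bias(finding)
    if outdir:
        bias.to_csv(outdir / "kruskal_wallis.tsv", sep="\t", index_label="probeset_id")
    variants: dict[str, sam_survival.Signature] = {}
    for cutoff in cfg.bias_cutoffs:
        retained = cohort_assembly.filter_probesets_by_bias(bias, cutoff)
        for delta, sig in signatures.items():
            keep = [p in retained for p in sig.probeset_ids]
            if not any(keep):
                continue
            variants[f"delta{delta}_kw{cutoff:g}"] = sam_survival.Signature(
                [p for p, k in zip(sig.probeset_ids, keep) if k],
                sig.weights[np.asarray(keep)],
                [d for d, k in zip(sig.directions, keep) if k],
                {**sig.provenance, "bias_cutoff": cutoff},
            )
    stage(
        "bias_filter",
        cutoffs=cfg.bias_cutoffs,
        variant_sizes={k: len(v) for k, v in variants.items()},
    )

    # ------------------------------------------------- scoring + validation
    report["validation"] = {}
    primary_delta = max(signatures)  # most stringent signature is primary
    for delta, sig in signatures.items():
        entry: dict = {"n_probesets": len(sig)}
        for cohort_name, m_c, efs_c, fu_c in (
            ("finding", finding, efs_finding, fu_finding),
            ("validation", validation, efs_validation, fu_validation),
        ):
            if not fu_c:
                continue
            scores = signature_scoring.compound_score(m_c, sig)
            strata = signature_scoring.quartile_stratify(scores.loc[fu_c])
            km = survival_stats.km_logrank(
                efs_c, strata["high_risk"].map({True: "high", False: "low"})
            )
            cov = survival_stats.code_clinical_covariates(
                [records_by_id[s] for s in fu_c]
            )
            cov.insert(0, "high_risk", strata["high_risk"].astype(float))
            try:
                fit = survival_stats.cox_fit(efs_c, cov)
                cox = {
                    "n_used": fit.n_used,
                    "hr_high_risk": fit.hazard_ratio("high_risk"),
                    "ci": [
                        float(fit.table.loc["high_risk", "ci_low"]),
                        float(fit.table.loc["high_risk", "ci_high"]),
                    ],
                    "p": float(fit.table.loc["high_risk", "p"]),
                }
                if outdir:
                    fit.table.to_csv(
                        outdir / f"cox_{cohort_name}_delta{delta}.tsv",
                        sep="\t",
                        index_label="covariate",
                    )
            except (ValueError, survival_stats.CoxSeparationError) as exc:
                cox = {"error": str(exc)}
            entry[cohort_name] = {
                "logrank_chi2": km.chi2,
                "logrank_p": km.p,
                "n": sum(km.n_per_group.values()),
                "cox": cox,
            }
            if outdir:
                strata.to_csv(
                    outdir / f"scores_{cohort_name}_delta{delta}.tsv",
                    sep="\t",
                    index_label="sample_id",
                )
        report["validation"][f"delta{delta}"] = _jsonable(entry)
        stage("validate", delta=delta)

    # ------------------------------------------------------------- metagenes
    mg_defs = None
    if cfg.metagene_definitions:
        mg_defs = read_metagene_definitions(cfg.metagene_definitions)
    elif cfg.simulate:
        gen_cfg = cfg.generator or synthetic_data.GeneratorConfig()
        probe_ids = matrix.probeset_ids
        mg_defs = {
            f.name: [probe_ids[i] for i in f.members] for f in gen_cfg.factors
        }
    if mg_defs:
        mg_scores = metagene_analysis.metagene_score(finding, mg_defs)
        sig = signatures[primary_delta]
        assignment = metagene_analysis.assign_to_metagenes(
            finding, sig.probeset_ids, mg_scores, cutoff=cfg.metagene_cutoff
        )
        sig_score = signature_scoring.compound_score(finding, sig)
        cluster_input = pd.concat(
            [mg_scores, sig_score.to_frame(f"signature_delta{primary_delta}").T]
        )
        names, Z = metagene_analysis.cluster_scores(cluster_input)
        if outdir:
            assignment.to_csv(outdir / "metagene_assignment.tsv", sep="\t", index_label="probeset_id")
            pd.DataFrame(Z, columns=["left", "right", "height", "size"]).to_csv(
                outdir / "linkage.tsv", sep="\t", index=False
            )
        stage(
            "metagenes",
            cutoff=cfg.metagene_cutoff,
            n_assigned=int((assignment["best_metagene"] != "unclassified").sum()),
            n_unclassified=int((assignment["best_metagene"] == "unclassified").sum()),
        )

    # ------------------------------------------------------------ pCR / ROC
    if cfg.response_analysis:
        pcr_ids = [r.sample_id for r in records if r.pcr is not None]
        if pcr_ids and mg_defs and cfg.response_metagene in mg_defs:
            m_pcr = matrix.subset_samples(pcr_ids)
            label = np.array([records_by_id[s].pcr for s in pcr_ids])
            bcell = metagene_analysis.metagene_score(
                m_pcr, {cfg.response_metagene: mg_defs[cfg.response_metagene]}
            ).iloc[0].to_numpy()
            sig_score = signature_scoring.compound_score(
                m_pcr, signatures[primary_delta]
            ).to_numpy()
            combined = response_prediction.combine_predictors(bcell, sig_score)
            rocs = {
                "bcell": response_prediction.roc_auc(bcell, label),
                "signature_no_pcr": response_prediction.roc_auc(-sig_score, label),
                "combined": response_prediction.roc_auc(combined, label),
            }
            report["response"] = {
                k: {"auc": v.auc, "ci": [v.ci_low, v.ci_high], "p": v.p_value}
                for k, v in rocs.items()
            }
            if outdir:
                (outdir / "roc.json").write_text(json.dumps(report["response"], indent=2))
            stage("response", n=len(pcr_ids), pcr_rate=float(label.mean()))
        else:
            stage("response", skipped="no pCR data or immune metagene available")

    # ------------------------------------------------------------- recovery
    if truth is not None:
        top_called = set().union(*(set(s.probeset_ids) for s in signatures.values()))
        kw_removed = set(bias.index) - cohort_assembly.filter_probesets_by_bias(
            bias, max(cfg.bias_cutoffs)
        )
        report["recovery"] = _jsonable(
            synthetic_data.recovery_report(
                truth,
                matrix.probeset_ids,
                sam_called=top_called,
                kw_removed=kw_removed,
            )
        )
        stage("recovery")

    if outdir:
        (outdir / "run_report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
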