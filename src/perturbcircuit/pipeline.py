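"""End-to-end pipeline runner with a content-hashed output manifest.

Stages run in method order (simulate? -> qc -> assign -> de -> fit ->
programs -> score -> interact -> clinical) as configured; every artifact is
recorded in ``manifest.json`` with a sha256 content hash, so reruns with an
unchanged config and master seed reproduce identical hashes. A stage failure
halts the run but still writes the manifest of completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time as _time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import clinical as clin
from . import diffexpr, interaction, io, programs, qc, regmatrix, synthetic
from .config import ConfigurationError, PipelineConfig, stream_seed

log = logging.getLogger("perturbcircuit")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.data: dict = {
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "stages": {},
            "artifacts": {},
        }

    def record_stage(self, name: str, seconds: float, **info) -> None:
        self.data["stages"][name] = {
            "seconds": round(seconds, 3),
            **{k: v for k, v in info.items()},
        }

    def record_artifact(self, path: Path) -> None:
        rel = str(path.relative_to(self.out_dir))
        self.data["artifacts"][rel] = _sha256(path)

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


def demo_config(output_dir: str, master_seed: int = 0) -> PipelineConfig:
    """Small fully-simulated configuration that exercises every stage."""
    from .config import ClinicalParams, SimulationConfig

    return PipelineConfig(
        output_dir=str(output_dir),
        master_seed=master_seed,
        simulate=SimulationConfig(
            n_genes=800, n_targets=8, n_programs=6, cells_per_guide=60,
            n_control_cells=180, doublet_rate=0.2, background_fraction=0.15,
        ),
        clinical=ClinicalParams(n_perm=200),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out_dir = Path(config.output_dir)
    if config.simulate is None:
        needed = [config.counts_mtx, config.barcodes, config.features,
                  config.guides]
        for p in needed:
            if p is None:
                raise ConfigurationError(
                    "without a simulate block, counts/barcodes/features/"
                    "guides paths are required")
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = out_dir / "inputs"
    outputs = out_dir / "outputs"
    outputs.mkdir(exist_ok=True)
    manifest = _Manifest(out_dir, config)
    config.to_yaml(out_dir / "config.yaml")
    manifest.record_artifact(out_dir / "config.yaml")
    seed = config.master_seed

    truth: Optional[synthetic.SyntheticTruth] = None
    planted_signature: Optional[list[str]] = None
    try:
        # ---------------- simulate ----------------
        t0 = _time.perf_counter()
        if config.simulate is not None:
            inputs.mkdir(exist_ok=True)
            sim = config.simulate
            truth = synthetic.generate_truth(sim, seed=stream_seed(seed, "truth"))
            adata, guide_tab = synthetic.simulate_counts(
                truth, seed=stream_seed(seed, "counts"))
            ppi = synthetic.simulate_ppi(truth, seed=stream_seed(seed, "ppi"))
            pathways = synthetic.simulate_pathways(truth)
            # planted clinical signature: top quarter of program 0 by |beta|
            p0 = truth.program_genes(0)
            w = truth.beta_true[p0].abs().mean(axis=0)
            n_sig = max(5, math.ceil(0.25 * len(p0)))
            planted_signature = list(w.sort_values(ascending=False).index[:n_sig])
            cohort = synthetic.simulate_cohort(
                truth, planted_signature, n_samples=500, hr_per_unit=0.5,
                censor_rate=0.3, seed=stream_seed(seed, "cohort"))
            drugs = synthetic.simulate_drug_response(
                truth, planted_signature, r_target=-0.35,
                seed=stream_seed(seed, "drug"), activity=cohort.true_score)

            io.write_counts(adata, inputs / "matrix.mtx",
                            inputs / "barcodes.tsv", inputs / "features.tsv")
            io.write_guides(guide_tab, inputs / "guides.tsv")
            io.write_ppi(ppi, inputs / "ppi.tsv")
            io.write_gmt(pathways, inputs / "pathways.gmt")
            io.write_cohort(cohort, inputs / "cohort_clinical.csv",
                            inputs / "cohort_expression.csv")
            drugs.drop(columns=["score"]).rename_axis("sample_id").to_csv(
                inputs / "drug_auc.csv")
            for f in sorted(inputs.iterdir()):
                manifest.record_artifact(f)
            config = _with_input_paths(config, inputs)
        manifest.record_stage("simulate", _time.perf_counter() - t0,
                              simulated=config.simulate is not None)

        # ---------------- qc ----------------
        t0 = _time.perf_counter()
        adata = io.read_counts(config.counts_mtx, config.barcodes,
                               config.features)
        qc.compute_qc_metrics(adata, mito_prefix=config.qc.mito_prefix)
        filtered, qc_report = qc.filter_cells(
            adata, min_genes=config.qc.min_genes,
            min_counts=config.qc.min_counts, max_mito=config.qc.max_mito)
        (outputs / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        manifest.record_artifact(outputs / "qc_report.json")
        manifest.record_stage("qc", _time.perf_counter() - t0, **qc_report)

        # ---------------- assign ----------------
        t0 = _time.perf_counter()
        guide_tab = io.read_guides(config.guides)
        control = (config.simulate.control_label if config.simulate else "NTC")
        assignments = qc.assign_guides(
            guide_tab, min_umi=config.guide_call.min_umi,
            dominance_ratio=config.guide_call.dominance_ratio,
            control_label=control, cell_ids=list(adata.obs_names))
        assignments = assignments.loc[
            assignments.index.intersection(filtered.obs_names)].sort_index()
        coverage = qc.coverage_summary(assignments)
        assignments.to_csv(outputs / "assignments.csv")
        coverage["per_target"].rename("n_cells").to_csv(outputs / "coverage_per_target.csv")
        manifest.record_artifact(outputs / "assignments.csv")
        manifest.record_artifact(outputs / "coverage_per_target.csv")
        manifest.record_stage("assign", _time.perf_counter() - t0,
                              n_singlet=coverage["n_singlet"],
                              n_doublet=coverage["n_doublet"],
                              n_unassigned=coverage["n_unassigned"])

        # ---------------- de ----------------
        t0 = _time.perf_counter()
        norm = regmatrix.normalize(filtered,
                                   scale_factor=config.fit.scale_factor)
        de = diffexpr.run_de(
            filtered, norm, assignments, control_label=control,
            pseudocount=config.de.pseudocount, fdr_scope=config.de.fdr_scope,
            min_cells=config.de.min_cells)
        de.to_csv(outputs / "de.csv", index=False)
        manifest.record_artifact(outputs / "de.csv")
        manifest.record_stage("de", _time.perf_counter() - t0, n_rows=len(de))

        # ---------------- fit ----------------
        t0 = _time.perf_counter()
        hvgs = regmatrix.select_hvgs(
            norm, min_mean=config.fit.hvg_min_mean,
            max_mean=config.fit.hvg_max_mean,
            min_dispersion=config.fit.hvg_min_dispersion)
        fit = regmatrix.fit_regulatory_matrix(
            norm, assignments, hvgs, control_label=control,
            alpha=config.fit.alpha, split=config.fit.split,
            seed=stream_seed(seed, "fit"), max_iter=config.fit.max_iter,
            tol=config.fit.tol, n_lambdas=config.fit.n_lambdas,
            lambda_min_ratio=config.fit.lambda_min_ratio,
            lambda_selection=config.fit.lambda_selection,
            standardize=config.fit.standardize,
            adaptive_gamma=config.fit.adaptive_gamma,
            debias=config.fit.debias)
        fit.beta.to_csv(outputs / "regulatory_matrix.csv")
        fit.lambda_path.to_csv(outputs / "lambda_path.csv", index=False)
        manifest.record_artifact(outputs / "regulatory_matrix.csv")
        manifest.record_artifact(outputs / "lambda_path.csv")
        manifest.record_stage("fit", _time.perf_counter() - t0,
                              selected_lambda=fit.lambda_,
                              validation_mse=fit.validation_mse,
                              test_mse=fit.test_mse)

        # ---------------- programs + score ----------------
        t0 = _time.perf_counter()
        pp = config.programs
        graph = programs.build_gene_knn(fit, k=pp.k, metric=pp.metric)
        progs = programs.louvain_programs(
            graph, fit, resolution=pp.resolution,
            seed=stream_seed(seed, "louvain"),
            min_program_size=pp.min_program_size,
            top_perturbations=pp.top_perturbations,
            corr_merge=pp.corr_merge)
        labels = programs.program_labels(progs)
        labels.rename_axis("gene").to_csv(outputs / "programs.csv")
        signatures = [programs.program_signature(p, pp.signature_fraction)
                      for p in progs]
        io.write_gmt({s.program_id: s.genes for s in signatures},
                     outputs / "signatures.gmt")
        scores = programs.score_all_programs(
            norm, signatures, n_bins=pp.score_n_bins, n_ctrl=pp.score_n_ctrl,
            seed=stream_seed(seed, "score"), method=pp.score_method)
        scores.rename_axis("barcode").to_csv(outputs / "program_scores.csv")
        enrich = programs.program_enrichment(scores, assignments,
                                             control_label=control)
        enrich.to_csv(outputs / "program_enrichment.csv", index=False)
        for f in ("programs.csv", "signatures.gmt", "program_scores.csv",
                  "program_enrichment.csv"):
            manifest.record_artifact(outputs / f)
        manifest.record_stage("programs", _time.perf_counter() - t0,
                              n_programs=len(progs))

        # ---------------- interact ----------------
        t0 = _time.perf_counter()
        if config.ppi and config.pathways:
            ppi_edges = io.read_ppi(config.ppi)
            pathways = io.read_gmt(config.pathways)
            pairs = interaction.pairwise_interactions(
                de, pathways, ppi_edges, fdr_cut=config.interaction.fdr_cut,
                psd_repair=config.interaction.psd_repair)
            pairs.to_csv(outputs / "interactions.csv", index=False)
            manifest.record_artifact(outputs / "interactions.csv")
            manifest.record_stage("interact", _time.perf_counter() - t0,
                                  n_pairs=len(pairs))
        else:
            manifest.record_stage("interact", 0.0, skipped=True)

        # ---------------- clinical ----------------
        t0 = _time.perf_counter()
        if config.cohort_clinical and config.cohort_expression:
            cohort = io.read_cohort(config.cohort_clinical,
                                    config.cohort_expression)
            sig = _select_clinical_signature(signatures, progs,
                                             planted_signature)
            bulk_scores = clin.score_bulk(cohort.expr, sig)
            cox_adj = clin.cox_association(bulk_scores, cohort,
                                           adjust=config.clinical.adjust)
            cox_unadj = clin.cox_association(bulk_scores, cohort, adjust=False)
            km = clin.km_stratify(bulk_scores, cohort,
                                  cut=config.clinical.cut)
            null_hrs, perm_p, perm_info = clin.permutation_specificity(
                cohort, sig, n_perm=config.clinical.n_perm,
                seed=stream_seed(seed, "perm"))
            summary = {
                "signature_program": sig.program_id,
                "signature_size": len(sig.genes),
                "cox_adjusted": {
                    "hazard_ratio": cox_adj.hazard_ratio,
                    "ci95": list(cox_adj.ci95), "p": cox_adj.p,
                    "n": cox_adj.n},
                "cox_unadjusted": {
                    "hazard_ratio": cox_unadj.hazard_ratio,
                    "ci95": list(cox_unadj.ci95), "p": cox_unadj.p},
                "km_logrank_p": km["p"],
                "permutation": {"empirical_p": perm_p, **perm_info},
            }
            if config.drug_auc:
                auc = pd.read_csv(config.drug_auc, index_col=0)
                drug = clin.drug_correlation(bulk_scores, auc)
                drug.to_csv(outputs / "drug_correlation.csv", index=False)
                manifest.record_artifact(outputs / "drug_correlation.csv")
                top = drug.dropna(subset=["pearson_r"]).sort_values("pearson_r")
                if len(top):
                    summary["top_sensitizing_drug"] = {
                        "drug": str(top.iloc[0]["drug"]),
                        "pearson_r": float(top.iloc[0]["pearson_r"])}
            (outputs / "clinical.json").write_text(
                json.dumps(summary, indent=2))
            manifest.record_artifact(outputs / "clinical.json")
            manifest.record_stage("clinical", _time.perf_counter() - t0,
                                  hazard_ratio=cox_adj.hazard_ratio)
        else:
            manifest.record_stage("clinical", 0.0, skipped=True)
    except Exception as err:
        manifest.data["error"] = f"{type(err).__name__}: {err}"
        manifest.write()
        raise
    manifest.write()
    return manifest.data


def _with_input_paths(config: PipelineConfig, inputs: Path) -> PipelineConfig:
    import dataclasses

    return dataclasses.replace(
        config,
        counts_mtx=str(inputs / "matrix.mtx"),
        barcodes=str(inputs / "barcodes.tsv"),
        features=str(inputs / "features.tsv"),
        guides=str(inputs / "guides.tsv"),
        ppi=str(inputs / "ppi.tsv"),
        pathways=str(inputs / "pathways.gmt"),
        cohort_clinical=str(inputs / "cohort_clinical.csv"),
        cohort_expression=str(inputs / "cohort_expression.csv"),
        drug_auc=str(inputs / "drug_auc.csv"),
    )


def _select_clinical_signature(signatures, progs, planted_signature):
    """Pick the fitted signature for the clinical stage: best Jaccard match
    to the planted signature when simulating, else the largest program."""
    if planted_signature:
        planted = set(planted_signature)
        best, best_j = signatures[0], -1.0
        for s, p in zip(signatures, progs):
            mem = set(p.member_genes)
            j = len(mem & planted) / len(mem | planted)
            if j > best_j:
                best, best_j = s, j
        return best
    return signatures[0]
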