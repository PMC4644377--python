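"""Config-driven orchestration of the discovery and validation pipeline.

``run_discovery`` chains consensus peaks -> fragment counting ->
moderated differential binding (with optional exhaustive label
permutation) -> proximal target genes -> temporal profile partition ->
nested-CV elastic-net Cox signature, writing every intermediate table
plus a provenance record (parameters, seeds, config hash, package
version) so two runs with the same config are file-identical.
``run_validation`` applies a trained signature to an external cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffbind import (
    CountMatrix,
    DiffBindParams,
    DifferentialBindingModel,
    GroupDesign,
    count_fragments_in_regions,
)
from .intervals import (
    AnnotationParams,
    GenomicInterval,
    assign_peaks_to_genes,
    consensus_peaks,
    read_bed,
    read_bed12_genes,
    read_gtf_genes,
    write_bed,
)
from .signature import CoxSignatureModel, SignatureModel, TrainParams, validate_signature
from .survival import CohortData, center_expression, km_curve
from .temporal import ShortTimeSeriesModel, TemporalParams, TimeCourse

logger = logging.getLogger("chromsig")

__all__ = ["PipelineConfig", "run_discovery", "run_validation", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat per-stage parameter namespaces plus input/output paths."""

    output_dir: str = "chromsig_out"
    # inputs
    peaks_bed: dict[str, str] = field(default_factory=dict)  # sample -> BED
    fragments_bed: dict[str, str] = field(default_factory=dict)
    counts_tsv: str | None = None
    gene_models: str | None = None  # BED12 or GTF
    timecourse_tsv: str | None = None
    expression_tsv: str | None = None
    clinical_tsv: str | None = None
    groups: dict[str, str] = field(default_factory=dict)  # sample -> A/B
    # stage toggles
    run_permutation: bool = True
    temporal_class_for_signature: str = "flat"  # up | flat | down
    # parameters
    consensus_min_samples: int = 3
    fdr_threshold: float = 0.10
    upstream_window_bp: int = 20000
    min_change: float = 0.5
    temporal_c: int = 2
    temporal_m: int = 50
    alpha: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    inner_folds: int = 10
    horizon: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.consensus_min_samples < 1:
            raise ValueError("consensus_min_samples must be >= 1")
        if self.upstream_window_bp < 0 or self.min_change < 0:
            raise ValueError("windows and min_change must be >= 0")
        if self.temporal_class_for_signature not in ("up", "flat", "down"):
            raise ValueError("temporal_class_for_signature must be up/flat/down")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig, **extra) -> dict:
    from . import __version__ as version

    return {
        "chromsig_version": version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        **extra,
    }


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_discovery(config: PipelineConfig) -> dict:
    """Execute the discovery pipeline end to end.

    Returns a dict of in-memory artifacts keyed by stage; every table
    is also written under ``config.output_dir``. A failing stage
    raises :class:`StageError` naming the stage, with the outputs of
    completed stages left on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    _write_json(_provenance(config), out / "provenance.json")

    stage = "consensus"
    try:
        peaksets = [
            read_bed(path, sample_id=s) for s, path in config.peaks_bed.items()
        ]
        consensus = consensus_peaks(peaksets, config.consensus_min_samples)
        write_bed(consensus, out / "consensus_peaks.bed")
        artifacts["consensus"] = consensus
        logger.info("consensus: %d regions at k=%d", len(consensus),
                    config.consensus_min_samples)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "count"
    try:
        if config.counts_tsv:
            cm = CountMatrix.from_tsv(config.counts_tsv)
        else:
            fragments = {
                s: list(read_bed(path, sample_id=s))
                for s, path in config.fragments_bed.items()
            }
            cm = count_fragments_in_regions(fragments, list(consensus))
        cm.to_tsv(out / "count_matrix.tsv")
        artifacts["counts"] = cm
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "diffbind"
    try:
        design = GroupDesign(dict(config.groups))
        model = DifferentialBindingModel(cm, design)
        params = DiffBindParams(fdr_threshold=config.fdr_threshold)
        diff = model.fit(params)
        diff.to_tsv(out / "differential_binding.tsv")
        sig = diff.significant()
        artifacts["diffbind"] = diff
        logger.info("diffbind: %d significant regions", len(sig))
        if config.run_permutation:
            report = model.permutation_robustness(params)
            report.table.to_csv(out / "permutation_robustness.tsv", sep="\t",
                                index=False)
            artifacts["permutation"] = report
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "targets"
    try:
        if config.gene_models is None:
            raise ValueError("gene_models path required for target assignment")
        gm_path = str(config.gene_models)
        genes_models = (
            read_gtf_genes(gm_path)
            if gm_path.endswith((".gtf", ".gtf.gz"))
            else read_bed12_genes(gm_path)
        )
        sig_regions = []
        for key in sig.index:
            chrom, span = key.rsplit(":", 1)
            s_, e_ = span.split("-")
            sig_regions.append(GenomicInterval(chrom, int(s_), int(e_)))
        ann = AnnotationParams(upstream_window_bp=config.upstream_window_bp)
        mapping, target_genes = assign_peaks_to_genes(
            sig_regions, genes_models, ann
        )
        pd.Series(
            {k: ";".join(v) for k, v in mapping.items()}, name="genes"
        ).rename_axis("region").to_csv(out / "peak_to_gene.tsv", sep="\t")
        (out / "target_genes.txt").write_text("\n".join(target_genes) + "\n")
        artifacts["target_genes"] = target_genes
        logger.info("targets: %d sites -> %d genes", len(sig_regions),
                    len(target_genes))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "temporal"
    try:
        if config.timecourse_tsv is None:
            raise ValueError("timecourse_tsv required for the temporal stage")
        tc = TimeCourse.from_tsv(config.timecourse_tsv)
        keep = [g for g in tc.genes if g in set(target_genes)]
        idx = [tc.genes.index(g) for g in keep]
        tc_sub = TimeCourse(keep, tc.timepoints, tc.values[idx])
        tmodel = ShortTimeSeriesModel(
            tc_sub,
            TemporalParams(c=config.temporal_c, m=config.temporal_m,
                           min_change=config.min_change),
        )
        tres = tmodel.fit(seed=config.seed)
        tres.assignments.rename_axis("gene").to_csv(
            out / "temporal_assignments.tsv", sep="\t"
        )
        tres.significance.to_csv(out / "temporal_significance.tsv", sep="\t")
        for name, genes_ in (("up", tres.gene_sets.up),
                             ("flat", tres.gene_sets.flat),
                             ("down", tres.gene_sets.down)):
            (out / f"genes_{name}.txt").write_text("\n".join(genes_) + "\n")
        artifacts["temporal"] = tres
        logger.info("temporal: %s", tres.gene_sets.sizes())
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "train"
    try:
        if config.expression_tsv is None or config.clinical_tsv is None:
            raise ValueError("expression_tsv and clinical_tsv required")
        cohort = CohortData.from_files(config.expression_tsv,
                                       config.clinical_tsv)
        cohort.expression = center_expression(cohort.expression)
        gene_set = getattr(tres.gene_sets,
                           config.temporal_class_for_signature)
        smodel = CoxSignatureModel(
            cohort,
            gene_set=gene_set,
            params=TrainParams(
                alpha=config.alpha,
                n_lambdas=config.n_lambdas,
                lambda_min_ratio=config.lambda_min_ratio,
                inner_folds=config.inner_folds,
                horizon=config.horizon,
            ),
        )
        sres = smodel.fit(seed=config.seed)
        sres.model.to_json(out / "signature_model.json")
        pd.DataFrame(
            {
                "prognostic_index": sres.cv_index,
                "risk_group": sres.risk_groups(),
            }
        ).rename_axis("patient").to_csv(out / "cv_prognostic_index.tsv",
                                        sep="\t")
        artifacts["signature"] = sres
        logger.info("train: %s", sres.model.genes)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    return artifacts


def run_validation(
    config: PipelineConfig,
    signature_model: SignatureModel,
    cohort: CohortData,
) -> dict:
    """Apply a trained signature to an external cohort and write a report.

    Computes prognostic indices, risk groups, KM curve points, the
    log-rank split p-value, the horizon AUC, the D'Amico
    cross-tabulation (when clinical data allows) and a PCA projection.
    Missing signature genes raise KeyError listing them.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_signature(
        signature_model, cohort, horizon=config.horizon
    )
    pi_table = report["pi_table"]
    pi_table.rename_axis("patient").to_csv(out / "validation_pi.tsv", sep="\t")
    km_rows = []
    for grp in ("low", "high"):
        mask = (pi_table["risk_group"] == grp).to_numpy()
        if mask.sum():
            km = km_curve(cohort.time[mask], cohort.event[mask])
            km["risk_group"] = grp
            km_rows.append(km)
    if km_rows:
        pd.concat(km_rows).to_csv(out / "validation_km.tsv", sep="\t",
                                  index=False)
    from .survival import pca_projection

    try:
        pca = pca_projection(cohort.expression, signature_model.genes)
        pca.rename_axis("patient").to_csv(out / "validation_pca.tsv", sep="\t")
        report["pca"] = pca
    except ValueError:
        pass
    summary = {
        "logrank_p": report["logrank_p"],
        "logrank_statistic": report["logrank_statistic"],
        "auc": report["auc"],
        "n_low": int((pi_table["risk_group"] == "low").sum()),
        "n_high": int((pi_table["risk_group"] == "high").sum()),
    }
    if "damico_crosstab" in report:
        summary["damico_crosstab"] = report["damico_crosstab"].to_dict()
    _write_json(_provenance(config, report=summary),
                out / "validation_report.json")
    return report
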