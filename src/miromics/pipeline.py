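"""End-to-end pipeline: preprocess -> profiles -> driver screen -> immune
scores -> risk model, with a validated configuration and a machine-readable
run manifest (feature/sample counts per stage)."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .annotation import (
    build_promoters,
    map_cnv_to_mirnas,
    map_probes_to_promoters,
    summarize_promoter_methylation,
)
from .preprocess import correct_type2_bias, filter_by_missingness, knn_impute
from .immune import score_panel
from .risk import RiskModel, RiskScoreModel
from .screen import DriverScreenModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus every tunable parameter of the pipeline, with defaults.

    Unknown keys are rejected; the effective config is echoed into the output
    directory of each run.
    """

    beta: str | None = None
    manifest: str | None = None
    seg: str | None = None
    tss_bed: str | None = None
    loci_gff3: str | None = None
    expression: str | None = None
    gene_expression: str | None = None
    gene_sets: str | None = None
    survival: str | None = None
    out_dir: str = "miromics_out"

    upstream: int = 2000
    downstream: int = 500
    max_missing_fraction: float = 0.30
    knn_k: int = 10
    bmiq_tol: float = 1e-4
    bmiq_max_iter: int = 300
    bmiq_fallback: bool = True
    fdr_threshold: float = 0.05
    min_pairs: int = 10
    ssgsea_alpha: float = 0.25
    normalization: str = "zscore"
    min_group_fraction: float = 0.10
    horizons: list[float] = field(default_factory=lambda: [365.0, 730.0, 1095.0, 1825.0])
    time_unit: str = "days"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage the inputs allow and write all outputs.

    Stage order: missingness filter -> KNN imputation -> type-II bias
    correction -> promoter/CNV mapping -> driver screen -> immune scores ->
    risk model.  The risk stage is skipped with a notice when no survival
    table is configured; any stage error aborts with the stage name and a
    partial-results marker in the manifest.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    manifest: dict = {"stages": {}, "complete": False, "seed": config.seed}
    stage = "setup"

    def _record(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    try:
        # --- methylation preprocessing -----------------------------------
        meth_matrix = None
        if config.beta and config.manifest:
            stage = "preprocess"
            beta = mio.read_matrix(config.beta)
            probes = mio.read_manifest(config.manifest)
            beta = filter_by_missingness(beta, config.max_missing_fraction)
            beta = knn_impute(beta, config.knn_k)
            design = probes.set_index("probe_id")["design_type"]
            beta, corr_info = correct_type2_bias(
                beta,
                design,
                tol=config.bmiq_tol,
                max_iter=config.bmiq_max_iter,
                fallback=config.bmiq_fallback,
            )
            mio.write_matrix(beta, out_dir / "beta_corrected.tsv")
            n_fallback = sum(
                1 for v in corr_info["method_per_sample"].values() if v != "bmiq"
            )
            _record("preprocess", probes=len(beta), samples=beta.shape[1],
                    rank_quantile_fallbacks=n_fallback)

            stage = "methylation_profiles"
            annotation = mio.read_mirna_annotation(config.tss_bed, config.loci_gff3)
            promoters = build_promoters(annotation, config.upstream, config.downstream)
            assignments = map_probes_to_promoters(probes, promoters)
            meth_matrix = summarize_promoter_methylation(beta, assignments)
            mio.write_matrix(meth_matrix, out_dir / "mirna_methylation.tsv")
            _record("methylation_profiles", mirnas=len(meth_matrix),
                    probes_assigned=len({a.probe_id for a in assignments}))

        # --- CNV profiles -------------------------------------------------
        cnv_matrix = None
        if config.seg and config.tss_bed and config.loci_gff3:
            stage = "cnv_profiles"
            annotation = mio.read_mirna_annotation(config.tss_bed, config.loci_gff3)
            promoters = build_promoters(annotation, config.upstream, config.downstream)
            segments = mio.read_seg(config.seg)
            cnv_matrix = map_cnv_to_mirnas(segments, promoters)
            mio.write_matrix(cnv_matrix, out_dir / "mirna_cnv.tsv")
            _record("cnv_profiles", mirnas=len(cnv_matrix), samples=cnv_matrix.shape[1])

        # --- driver screen ------------------------------------------------
        expr = None
        if config.expression:
            expr = mio.read_matrix(config.expression)
        if expr is not None and (cnv_matrix is not None or meth_matrix is not None):
            stage = "driver_screen"
            res = DriverScreenModel(
                expr, cnv=cnv_matrix, meth=meth_matrix, min_pairs=config.min_pairs
            ).fit(config.fdr_threshold)
            res.calls.to_csv(out_dir / "driver_calls.tsv", sep="\t")
            if res.decomposition is not None:
                res.decomposition.to_csv(out_dir / "driver_decomposition.tsv", sep="\t")
            _record(
                "driver_screen",
                mirnas=len(res.calls),
                cnv_mirs=len(res.cnv_mirs),
                dnam_mirs=len(res.dnam_mirs),
            )

        # --- immune scores ------------------------------------------------
        if config.gene_expression:
            stage = "immune_scores"
            gene_expr = mio.read_matrix(config.gene_expression)
            gene_sets = mio.read_gmt(config.gene_sets) if config.gene_sets else None
            allocation = None
            if gene_sets and all(gs.factor_allocation for gs in gene_sets):
                allocation = {gs.name: gs.factor_allocation for gs in gene_sets}
            scores = score_panel(
                gene_expr, gene_sets, allocation, alpha=config.ssgsea_alpha
            )
            mio.write_matrix(scores, out_dir / "immune_scores.tsv")
            _record("immune_scores", scores=len(scores), samples=scores.shape[1])

        # --- risk model ---------------------------------------------------
        if expr is not None and config.survival:
            stage = "risk_model"
            survival = mio.read_survival(config.survival)
            model = RiskScoreModel(
                expr,
                survival,
                RiskModel(normalization=config.normalization),
                time_unit=config.time_unit,
            )
            results = model.fit(config.min_group_fraction, horizons=config.horizons)
            out = pd.DataFrame({"risk_score": results.scores, "risk_group": results.groups})
            out.to_csv(out_dir / "risk_scores.tsv", sep="\t", index_label="sample")
            (out_dir / "risk_summary.txt").write_text(results.summary() + "\n")
            _record(
                "risk_model",
                samples=len(results.scores),
                cutpoint=round(results.cutpoint, 6),
                logrank_p=results.logrank_p,
            )
        elif expr is not None and not config.survival:
            _record("risk_model", skipped="no survival table configured")

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
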