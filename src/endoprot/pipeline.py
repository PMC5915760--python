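"""End-to-end orchestration of the LFQ analysis from one configuration.

Stage order mirrors the study's workflow: load (or simulate) the
protein-group table -> filter -> log2 -> pre-imputation QC on observed
cells -> down-shift imputation -> post-imputation QC -> PCA and
hierarchical clustering -> per-cancer ANOVA enrichment -> progressive
disease-marker calling -> optional signature concordance and
over-representation.  Every output file is recorded in a JSON manifest;
identical (config, seed) pairs reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .differential import VolcanoParams, anova_scan
from .errors import ValidationError
from .io_tables import (
    SampleAnnotation,
    read_gmt,
    read_protein_groups,
    read_sample_annotation,
    read_signature,
    write_protein_groups,
    write_results,
    write_sample_annotation,
)
from .markers import classify_patterns, transition_posteriors
from .multivariate import cut_clusters, hierarchical_cluster, label_agreement, pca
from .preprocess import (
    ExpressionMatrix,
    ImputationParams,
    filter_protein_groups,
    impute_downshift,
    to_log2,
    zscore_rows,
)
from .qc import correlation_matrix, flag_outliers
from .signatures import concordance, ora_hypergeometric
from .simulate import CANCER_COHORTS, SimulationConfig, generate_dataset


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of file inputs or simulation."""

    protein_groups: str | None = None
    annotation: str | None = None
    simulation: SimulationConfig | None = None
    out_dir: str = "results"
    seed: int = 0
    min_unique_peptides: int = 2
    imputation: ImputationParams = field(default_factory=ImputationParams)
    outlier_threshold: float = 0.75
    exclude_outliers: bool = False
    anova_fdr: float = 0.01
    volcano: VolcanoParams = field(default_factory=VolcanoParams)
    tau: float = 0.9
    gamma: float = 0.25
    null: str = "theoretical"
    cancer_cohorts: tuple[str, ...] = CANCER_COHORTS
    signatures: list[dict] = field(default_factory=list)
    gene_sets: str | None = None

    def __post_init__(self) -> None:
        has_files = self.protein_groups is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValidationError(
                "exactly one of (protein_groups + annotation) or simulation "
                "must be configured"
            )
        if has_files and self.annotation is None:
            raise ValidationError("file input requires an annotation path")
        for path in filter(None, [self.protein_groups, self.annotation,
                                  self.gene_sets]):
            if not os.path.exists(path):
                raise ValidationError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "imputation" in raw:
            raw["imputation"] = ImputationParams(**raw["imputation"])
        if "volcano" in raw:
            raw["volcano"] = VolcanoParams(**raw["volcano"])
        if "cancer_cohorts" in raw:
            raw["cancer_cohorts"] = tuple(raw["cancer_cohorts"])
        return cls(**raw)


def _subset(
    m: ExpressionMatrix, keep: Sequence[str]
) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=m.values[list(keep)],
        observed=m.observed[list(keep)],
        gene_names=m.gene_names,
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "files": {},
        "parameters": _echo_params(config),
    }
    tables: dict[str, pd.DataFrame] = {}
    stage = "input"
    try:
        if config.simulation is not None:
            sim = config.simulation
            table, annotations, truth = generate_dataset(sim)
            pg_path = os.path.join(config.out_dir, "protein_groups.tsv")
            ann_path = os.path.join(config.out_dir, "sample_annotation.tsv")
            write_protein_groups(table, pg_path)
            write_sample_annotation(annotations, ann_path)
            tables["simulation_truth"] = pd.DataFrame(
                {"pattern": truth.pattern}
            ).join(truth.true_means.add_prefix("true_mean_"))
            manifest["files"]["protein_groups"] = pg_path
            manifest["files"]["sample_annotation"] = ann_path
        else:
            table = read_protein_groups(config.protein_groups)
            annotations = read_sample_annotation(config.annotation)
        manifest["stages"].append(stage)

        stage = "filter"
        filtered = filter_protein_groups(
            table, min_unique_peptides=config.min_unique_peptides
        )
        manifest["filter_report"] = filtered.filter_report
        manifest["stages"].append(stage)

        stage = "log2"
        matrix = to_log2(filtered)
        manifest["stages"].append(stage)

        stage = "qc_pre_imputation"
        corr_pre = correlation_matrix(matrix, use="observed_pairwise")
        tables["correlation_observed"] = corr_pre
        tables["outliers_observed"] = flag_outliers(
            corr_pre, annotations, threshold=config.outlier_threshold
        )
        manifest["stages"].append(stage)

        stage = "impute"
        params = ImputationParams(
            width=config.imputation.width,
            downshift=config.imputation.downshift,
            seed=config.seed,
        )
        imputed = impute_downshift(matrix, params)
        manifest["stages"].append(stage)

        stage = "qc_post_imputation"
        corr = correlation_matrix(imputed, use="imputed_complete")
        flags = flag_outliers(corr, annotations,
                              threshold=config.outlier_threshold)
        tables["correlation_imputed"] = corr
        tables["outliers_imputed"] = flags
        if config.exclude_outliers and len(flags):
            dropped = set(flags["sample"])
            keep = [s for s in imputed.samples if s not in dropped]
            imputed = _subset(imputed, keep)
            annotations = [a for a in annotations if a.sample not in dropped]
            manifest["excluded_samples"] = sorted(dropped)
        manifest["stages"].append(stage)

        stage = "pca_clustering"
        pca_res = pca(imputed)
        tables["pca_scores"] = pca_res.scores
        tables["pca_explained_variance"] = pd.DataFrame(
            {"explained_variance_ratio": pca_res.explained_variance_ratio},
            index=pca_res.scores.columns,
        )
        ztree = hierarchical_cluster(zscore_rows(imputed), axis="samples")
        clusters2 = cut_clusters(ztree, 2)
        tables["sample_clusters_k2"] = clusters2.to_frame()
        cohorts = {a.sample: a.cohort for a in annotations}
        binary = ["cancer" if cohorts[s] in CANCER_COHORTS else "control"
                  for s in clusters2.index]
        manifest["ari_cancer_vs_control_k2"] = label_agreement(
            clusters2.tolist(), binary
        )
        manifest["stages"].append(stage)

        present = {a.cohort for a in annotations}
        stage = "anova"
        for cancer in config.cancer_cohorts:
            if cancer not in present:
                continue
            res = anova_scan(imputed, annotations, [cancer, "EMT", "END"],
                             fdr=config.anova_fdr)
            tables[f"anova_{cancer}"] = res
            manifest[f"anova_significant_{cancer}"] = int(
                res["significant"].sum()
            )
        manifest["stages"].append(stage)

        stage = "markers"
        for cancer in config.cancer_cohorts:
            if cancer not in present:
                continue
            post = transition_posteriors(
                imputed, annotations, ("END", "EMT", cancer),
                gamma=config.gamma, null=config.null,
            )
            calls = classify_patterns(post.post_first, post.post_second,
                                      tau=config.tau)
            calls["gene_name"] = imputed.gene_names
            tables[f"markers_{cancer}"] = calls
            manifest[f"n_markers_{cancer}"] = int(calls["is_marker"].sum())
            manifest[f"pi0_{cancer}"] = [post.fit_first.pi0,
                                         post.fit_second.pi0]
        manifest["stages"].append(stage)

        stage = "signatures"
        for spec in config.signatures:
            sig = read_signature(spec["path"], name=spec.get("name"))
            cancer = spec.get("cancer", "CC")
            comparator = spec.get("comparator", "EMT")
            if cancer not in present or comparator not in present:
                continue
            sig_table, summary = concordance(
                sig, imputed, annotations, cancer, comparator,
                volcano=config.volcano,
            )
            tables[f"concordance_{sig.name}"] = sig_table
            manifest[f"concordance_{sig.name}"] = summary
        manifest["stages"].append(stage)

        stage = "enrichment"
        if config.gene_sets is not None:
            sets = read_gmt(config.gene_sets)
            background = sorted(
                {g for g in imputed.gene_names if g}
            )
            for cancer in config.cancer_cohorts:
                key = f"markers_{cancer}"
                if key not in tables:
                    continue
                marker_genes = sorted(
                    set(tables[key].loc[tables[key]["is_marker"],
                                        "gene_name"]) & set(background)
                )
                tables[f"enrichment_{cancer}"] = ora_hypergeometric(
                    marker_genes, sets, background
                )
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _finalize(manifest, tables, config)
        raise

    _finalize(manifest, tables, config)
    return manifest


def _echo_params(config: PipelineConfig) -> dict:
    echo = asdict(config)
    echo["volcano"] = asdict(config.volcano)
    echo["imputation"] = asdict(config.imputation)
    if config.simulation is not None:
        echo["simulation"] = asdict(config.simulation)
        echo["simulation"]["cohort_sizes"] = dict(
            config.simulation.cohort_sizes
        )
    echo["cancer_cohorts"] = list(config.cancer_cohorts)
    return echo


def _finalize(manifest: dict, tables: dict, config: PipelineConfig) -> None:
    paths = write_results(tables, config.out_dir)
    manifest["files"].update(paths)
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["files"]["manifest"] = manifest_path
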