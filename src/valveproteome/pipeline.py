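"""End-to-end orchestration from a single config.

Runs identification filtering, log2 transform, valid-value filter,
downshifted imputation, the moderated linear model over all seven
contrasts, effect classification, enrichment with category summaries, a
PCA overview, and optionally the down-sampling analysis — either on files
(protein-groups TSV + metadata + GMT) or on a freshly generated synthetic
cohort.  All outputs are plain TSV/JSON in the output directory and every
run is reproducible from the global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .containers import CONDITIONS, FilterReport, IntensityMatrix, SampleMeta
from .effects import (
    classify_condition_effects,
    classify_sex_effects,
    count_effect_classes,
    effect_calls_table,
)
from .enrichment import (
    GeneSetCollection,
    queries_from_result,
    read_category_map,
    reduce_redundant_terms,
    run_enrichment,
    summarize_categories,
)
from .linear_model import (
    CONTRAST_NAMES,
    build_design,
    estimate_variance_prior,
    fit_linear_model,
    results_table,
    run_contrasts,
)
from .maxquant import apply_identification_filters, read_protein_groups
from .preprocess import ImputationParams, filter_valid_values, impute_downshift, log2_transform
from .robustness import downsample_analysis
from .synth import (
    SynthConfig,
    generate_cohort,
    generate_gene_sets,
    inject_missingness,
    read_metadata_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Exactly one of ``inputs`` (paths to protein groups TSV, metadata TSV and
    optionally a GMT / category map) or ``synth`` (a :class:`SynthConfig`)
    must be given.
    """

    outdir: str = "results"
    seed: int = 0
    inputs: dict | None = None
    synth: SynthConfig | None = None
    min_frac: float = 0.5
    valid_by: str = "condition"
    imputation_width: float = 0.3
    imputation_shift: float = 1.8
    alpha: float = 0.05
    trend: bool = True
    sex_weighting: str = "equal"
    enrichment_fdr: float = 0.05
    enrichment_min_size: int = 3
    enrichment_max_intersection_frac: float = 0.05
    downsample: dict | None = None  # keys: from_group, n_subset, reps, reference_count

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise ValueError(
                "exactly one of 'inputs' and 'synth' must be configured"
            )
        if not 0.0 < self.min_frac <= 1.0:
            raise ValueError("min_frac must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            synth_raw = dict(raw["synth"])
            if "base_mean_range" in synth_raw:
                synth_raw["base_mean_range"] = tuple(synth_raw["base_mean_range"])
            raw["synth"] = SynthConfig(**synth_raw)
        return cls(**raw)


def pca_overview(
    matrix: IntensityMatrix, meta: SampleMeta, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the first two principal components.

    Proteins are centered per row (unit-variance scaling optional); returns
    sample coordinates annotated with condition/sex and the full
    explained-variance-ratio vector.
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    values = matrix.values.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    if scale:
        sd = values.std(axis=1, ddof=1, keepdims=True)
        centered = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    X = centered.T  # samples x proteins
    pca = PCA(n_components=min(X.shape))
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords[:, :2], index=matrix.samples, columns=["PC1", "PC2"]
    )
    out["condition"] = meta.table.loc[out.index, "condition"]
    out["sex"] = meta.table.loc[out.index, "sex"]
    return out, pca.explained_variance_ratio_


def _load_inputs(cfg: PipelineConfig):
    """Returns (raw matrix with missing as NaN, meta, collection, category_map, id_report)."""
    if cfg.synth is not None:
        synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        complete, meta, truth = generate_cohort(synth)
        censored, _ = inject_missingness(complete, synth)
        collection = generate_gene_sets(truth, seed=cfg.seed)
        report = FilterReport(censored.n_proteins)
        return censored, meta, collection, {}, report, truth
    paths = cfg.inputs or {}
    raw = read_protein_groups(paths["protein_groups"])
    meta = read_metadata_tsv(paths["metadata"])
    filtered, report = apply_identification_filters(raw)
    if len(filtered) == 0:
        raise ValueError("identification filters removed every row")
    matrix = log2_transform(filtered)
    collection = (
        GeneSetCollection.read_gmt(paths["gene_sets"])
        if paths.get("gene_sets")
        else None
    )
    category_map = (
        read_category_map(paths["category_map"])
        if paths.get("category_map")
        else {}
    )
    return matrix, meta, collection, category_map, report, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths and summaries."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        matrix, meta, collection, category_map, report, truth = _load_inputs(cfg)

        stage = "valid_value_filter"
        filtered, vv_report = filter_valid_values(
            matrix, meta, min_frac=cfg.min_frac, by=cfg.valid_by
        )
        full_report = report.merged_with(vv_report)
        full_report.as_series().to_csv(
            outdir / "filter_report.tsv", sep="\t", header=["count"]
        )

        stage = "imputation"
        params = ImputationParams(
            width=cfg.imputation_width, shift=cfg.imputation_shift, seed=cfg.seed
        )
        imputed, imputed_mask = impute_downshift(filtered, params)
        filtered.to_tsv(outdir / "log2_intensities_before_imputation.tsv")
        imputed.to_tsv(outdir / "log2_intensities_after_imputation.tsv")

        stage = "linear_model"
        design = build_design(meta, sex_weighting=cfg.sex_weighting)
        fit = fit_linear_model(imputed, design)
        prior = estimate_variance_prior(fit, trend=cfg.trend)
        results = run_contrasts(fit, prior, CONTRAST_NAMES)
        results_table(results).to_csv(
            outdir / "differential_abundance.tsv", sep="\t"
        )

        stage = "effect_calls"
        condition_calls = classify_condition_effects(
            results["AS_vs_CON"],
            results["MR_vs_CON"],
            results["AS_vs_MR"],
            alpha=cfg.alpha,
        )
        sex_calls = {
            "AS": classify_sex_effects(
                results["ASf_vs_CONf"], results["ASm_vs_CONm"], alpha=cfg.alpha
            ),
            "MR": classify_sex_effects(
                results["MRf_vs_CONf"], results["MRm_vs_CONm"], alpha=cfg.alpha
            ),
        }
        calls = effect_calls_table(condition_calls, sex_calls)
        calls.to_csv(outdir / "effect_calls.tsv", sep="\t")
        class_counts = count_effect_classes(condition_calls)
        class_counts.to_csv(outdir / "effect_class_counts.tsv", sep="\t")

        stage = "enrichment"
        proportions = {}
        if collection is not None and len(collection) > 0:
            background = set(imputed.proteins)
            for name in ("AS_vs_CON", "MR_vs_CON", "AS_vs_MR"):
                queries = queries_from_result(results[name], alpha=cfg.alpha)
                table = run_enrichment(
                    queries,
                    background,
                    collection,
                    fdr=cfg.enrichment_fdr,
                    min_size=cfg.enrichment_min_size,
                    max_intersection_frac=cfg.enrichment_max_intersection_frac,
                )
                table = reduce_redundant_terms(table)
                table.to_csv(
                    outdir / f"enrichment_{name}.tsv", sep="\t", index=False
                )
                props = summarize_categories(table, category_map)
                proportions[name] = props.to_dict()
            with open(outdir / "category_proportions.json", "w") as fh:
                json.dump(proportions, fh, indent=2)

        stage = "pca"
        coords, evr = pca_overview(imputed, meta)
        coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t")

        stage = "downsample"
        downsample_summary = None
        if cfg.downsample:
            ds = dict(cfg.downsample)
            result = downsample_analysis(
                imputed,
                meta,
                from_group=ds.get("from_group", "AS"),
                n_subset=int(ds.get("n_subset", 17)),
                reps=int(ds.get("reps", 100)),
                reference_count=ds.get("reference_count"),
                alpha=cfg.alpha,
                trend=cfg.trend,
                seed=cfg.seed,
            )
            result.to_frame().to_csv(
                outdir / "downsample_counts.tsv", sep="\t", index=False
            )
            downsample_summary = result.summary()
            with open(outdir / "downsample_summary.json", "w") as fh:
                json.dump(downsample_summary, fh, indent=2)

        stage = "log"
        run_log = {
            "version": __version__,
            "seed": cfg.seed,
            "n_samples": int(imputed.n_samples),
            "n_proteins_input": int(full_report.n_input),
            "n_proteins_analyzed": int(imputed.n_proteins),
            "parameters": {
                "min_frac": cfg.min_frac,
                "valid_by": cfg.valid_by,
                "imputation_width": cfg.imputation_width,
                "imputation_shift": cfg.imputation_shift,
                "alpha": cfg.alpha,
                "trend": cfg.trend,
                "sex_weighting": cfg.sex_weighting,
                "enrichment_fdr": cfg.enrichment_fdr,
                "enrichment_min_size": cfg.enrichment_min_size,
                "enrichment_max_intersection_frac": cfg.enrichment_max_intersection_frac,
            },
            "prior": {"d0": prior.d0, "s0": prior.s0_scalar, "trend": prior.trend},
            "pca_explained_variance_pc1_pc2": [float(v) for v in evr[:2]],
            "effect_class_counts": {
                k: int(v) for k, v in class_counts.items()
            },
            "downsample": downsample_summary,
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, default=float)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "outdir": str(outdir),
        "run_log": run_log,
        "effect_class_counts": class_counts,
        "category_proportions": proportions,
    }
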