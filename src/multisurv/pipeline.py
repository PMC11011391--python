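"""End-to-end orchestration: simulate -> labels -> featurize -> select -> evaluate.

Each stage reads files written by the previous one, writes its outputs under
the working directory, and records them (with content hashes) in
``manifest.json``.  A rerun with an unchanged config and unchanged inputs
skips stages whose recorded outputs are still valid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from multisurv import cnvfeat, exprfeat, formats, labels as labels_mod, mutfeat, select, simulate
from multisurv.evaluate import NestedCvConfig, nested_cv_evaluate
from multisurv.formats import FeatureMatrix

logger = logging.getLogger(__name__)

STAGES = ("simulate", "labels", "featurize", "select", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    workdir: str = "multisurv_run"
    seed: int = 0
    simulate: bool = True
    cohort: dict[str, Any] = dataclasses.field(default_factory=dict)
    # input paths; filled in automatically when simulate=True
    maf: str | None = None
    seg: str | None = None
    mrna: str | None = None
    mirna: str | None = None
    methylation: str | None = None
    clinical: str | None = None
    reference: str | None = None
    genes_bed: str | None = None
    gene_sets: str | None = None
    signatures: str | None = None
    # labels
    horizon_days: int = 730
    exclude_non_cancer_death: bool = False
    # featurize
    min_reads: int = 10
    frac_overlap: float = 0.9
    protein_altering_only: bool = True
    # select
    correlation_cutoff: float = 0.9
    boruta_max_runs: int = 10_000
    boruta_alpha: float = 0.01
    boruta_n_trees: int = 500
    # evaluate
    outer_folds: int = 10
    tune_grid_size: int = 10
    majority_fraction: float = 0.3
    minority_multiplier: float = 1.0
    repeats: int = 100
    rf_n_trees: int = 500
    rf_inner_trees: int | None = None
    shap_nsim: int = 10
    compute_shap: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)

    def validate_inputs(self) -> None:
        if self.simulate:
            return
        needed = ("maf", "seg", "mrna", "mirna", "methylation", "clinical",
                  "reference", "genes_bed", "gene_sets", "signatures")
        for name in needed:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"config missing required input path: {name}")
            if not Path(value).exists():
                raise ValueError(f"input file does not exist: {name} = {value}")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = json.loads(path.read_text()) if path.exists() else {}

    def stage_current(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if not rec or rec.get("key") != key:
            return False
        for p, digest in rec.get("outputs", {}).items():
            if not Path(p).exists() or _hash_file(Path(p)) != digest:
                return False
        return set(rec.get("outputs", {})) >= {str(p) for p in outputs}

    def record(self, stage: str, key: str, outputs: list[Path]) -> None:
        self.data[stage] = {"key": key,
                            "outputs": {str(p): _hash_file(p) for p in outputs}}
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns the manifest data."""
    config = dataclasses.replace(config)  # stages fill in paths on a copy
    config.validate_inputs()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(workdir / "manifest.json")
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)

    def run_stage(name: str, outputs: list[Path], fn: Callable[[], None]) -> None:
        if name not in stages:
            return
        key = hashlib.sha256((cfg_json + name).encode()).hexdigest()
        if manifest.stage_current(name, key, outputs):
            logger.info("stage %s up to date; skipped", name)
            return
        logger.info("stage %s running", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(name, exc) from exc
        manifest.record(name, key, [p for p in outputs if p.exists()])

    data = workdir / "data"
    feat = workdir / "features"
    res = workdir / "results"

    # ---- simulate -------------------------------------------------------
    def do_simulate():
        spec = simulate.CohortSpec(**{**config.cohort, "seed": config.seed})
        paths, _ = simulate.generate_cohort(spec, data)
        for key in ("maf", "seg", "mrna", "mirna", "methylation", "clinical"):
            setattr(config, key, str(paths[key]))
        config.reference = str(paths["reference"])
        config.genes_bed = str(paths["genes"])
        config.gene_sets = str(paths["gene_sets"])
        config.signatures = str(paths["signatures"])

    if config.simulate:
        sim_outputs = [data / n for n in
                       ("somatic.maf.tsv", "cnv.seg.tsv", "mrna_counts.tsv",
                        "mirna_counts.tsv", "methylation_beta.tsv", "clinical.tsv",
                        "reference.fa", "genes.bed", "gene_sets.gmt",
                        "signatures_sbs96.tsv", "truth.json")]
        run_stage("simulate", sim_outputs, do_simulate)
        for key, fname in (("maf", "somatic.maf.tsv"), ("seg", "cnv.seg.tsv"),
                           ("mrna", "mrna_counts.tsv"), ("mirna", "mirna_counts.tsv"),
                           ("methylation", "methylation_beta.tsv"),
                           ("clinical", "clinical.tsv"), ("reference", "reference.fa"),
                           ("genes_bed", "genes.bed"), ("gene_sets", "gene_sets.gmt"),
                           ("signatures", "signatures_sbs96.tsv")):
            if getattr(config, key) is None:
                setattr(config, key, str(data / fname))

    # ---- labels ---------------------------------------------------------
    labels_path = workdir / "labels.tsv"

    def do_labels():
        clinical = formats.read_clinical(config.clinical)
        ls = labels_mod.dichotomize_survival(clinical, config.horizon_days,
                                             config.exclude_non_cancer_death)
        ls.to_tsv(labels_path)

    run_stage("labels", [labels_path], do_labels)

    # ---- featurize ------------------------------------------------------
    feat.mkdir(parents=True, exist_ok=True)
    combined_path = feat / "combined.tsv"
    combined_sidecar = feat / "combined.provenance.tsv"

    def do_featurize():
        matrix = build_feature_matrix(config)
        matrix.to_tsv(combined_path, combined_sidecar)

    run_stage("featurize", [combined_path, combined_sidecar], do_featurize)

    # ---- select ---------------------------------------------------------
    res.mkdir(parents=True, exist_ok=True)
    decisions_path = res / "boruta_decisions.tsv"
    history_path = res / "boruta_importance_history.tsv"

    def do_select():
        matrix = FeatureMatrix.from_tsv(combined_path, combined_sidecar)
        ls = labels_mod.LabelSet.from_tsv(labels_path, config.horizon_days)
        matrix = select.zero_variance_filter(matrix)
        matrix, removed = select.correlation_filter(matrix, config.correlation_cutoff)
        logger.info("correlation filter removed %d features", len(removed))
        result = select.boruta_rank(matrix, ls, max_runs=config.boruta_max_runs,
                                    alpha=config.boruta_alpha, seed=config.seed,
                                    n_trees=config.boruta_n_trees)
        result.to_tsv(decisions_path)
        result.importance_history.to_csv(history_path, sep="\t", index_label="run")

    run_stage("select", [decisions_path, history_path], do_select)

    # ---- evaluate -------------------------------------------------------
    pred_path = res / "predictions.tsv"
    auc_path = res / "auc_summary.tsv"
    roc_path = res / "roc.tsv"
    shap_path = res / "shap.tsv"

    def do_evaluate():
        matrix = FeatureMatrix.from_tsv(combined_path, combined_sidecar)
        ls = labels_mod.LabelSet.from_tsv(labels_path, config.horizon_days)
        decisions = pd.read_csv(decisions_path, sep="\t", index_col="feature_id")
        chosen = list(decisions.index[decisions["decision"] == select.CONFIRMED])
        if len(chosen) < 2:
            chosen += list(decisions.index[decisions["decision"] == select.TENTATIVE])
        if len(chosen) < 1:
            raise ValueError("no features selected; nothing to evaluate")
        cv_config = NestedCvConfig(
            outer_folds=config.outer_folds, tune_grid_size=config.tune_grid_size,
            minority_multiplier=config.minority_multiplier,
            majority_fraction=config.majority_fraction, repeats=config.repeats,
            shap_nsim=config.shap_nsim, n_trees=config.rf_n_trees,
            inner_n_trees=config.rf_inner_trees,
            compute_shap=config.compute_shap, seed=config.seed)
        result = nested_cv_evaluate(matrix.subset(chosen), ls, cv_config)
        result.predictions.to_csv(pred_path, sep="\t", index=False)
        pd.DataFrame({"auc": result.auc_per_repeat}).agg(["mean", "std"]).to_csv(
            auc_path, sep="\t")
        from multisurv.evaluate import pooled_roc_auc
        roc, _ = pooled_roc_auc(result.predictions["label"],
                                result.predictions["prob_nonsurvivor"])
        roc.to_csv(roc_path, sep="\t", index=False)
        if result.shap is not None:
            result.shap.T.to_csv(shap_path, sep="\t", index_label="feature_id")

    run_stage("evaluate", [pred_path, auc_path, roc_path], do_evaluate)
    return manifest.data


def build_feature_matrix(config: PipelineConfig) -> FeatureMatrix:
    """All per-omics extraction steps, combined into one samples x features matrix.

    Mutation layer: gene-set aggregation (sum of per-gene indicators), SBS/DBS/ID
    catalogue counts and SBS signature exposures.  CNV layer: shared-region
    segment means and gene-set means.  mRNA/miRNA: min-count filter +
    median-of-ratios normalization, raw features.  Methylation: raw betas.
    """
    variants = formats.read_maf(config.maf)
    segments = formats.read_seg(config.seg)
    gene_models = formats.read_bed_genes(config.genes_bed)
    gene_sets = formats.read_gmt(config.gene_sets)
    signatures = formats.read_signatures(config.signatures)
    mrna = formats.read_matrix(config.mrna)
    mirna = formats.read_matrix(config.mirna)
    meth = formats.read_matrix(config.methylation)
    samples = list(mrna.columns)

    catalogues = mutfeat.build_catalogues(variants, config.reference, samples=samples)
    gene_mat = mutfeat.gene_mutation_matrix(variants, gene_models,
                                            config.protein_altering_only, samples=samples)
    set_mat = mutfeat.geneset_aggregate(gene_mat, gene_sets, mode="sum")
    set_mat.values.columns = [f"mut_set:{c}" for c in set_mat.values.columns]
    set_mat.provenance.index = set_mat.values.columns
    exposures = mutfeat.fit_signatures(catalogues["SBS96"], signatures)

    partition = cnvfeat.partition_segments(segments, frac_overlap=config.frac_overlap)
    region_mat = partition.to_feature_matrix()
    region_vals = region_mat.values.reindex(samples, fill_value=0.0)
    region_mat = FeatureMatrix(region_vals, omics="cnv", method="region_overlap")
    cn_gene = cnvfeat.gene_cn_matrix(partition, gene_models, samples=samples)
    cn_set = mutfeat.geneset_aggregate(cn_gene, gene_sets, mode="mean")
    cn_set.values.columns = [f"cnv_set:{c}" for c in cn_set.values.columns]
    cn_set.provenance.index = cn_set.values.columns

    mrna_norm, _ = exprfeat.size_factor_normalize(exprfeat.filter_min_count(
        mrna, config.min_reads))
    mirna_norm, _ = exprfeat.size_factor_normalize(exprfeat.filter_min_count(
        mirna, config.min_reads))
    mrna_fm = FeatureMatrix(mrna_norm.T, omics="mrna", method="raw")
    mirna_fm = FeatureMatrix(mirna_norm.T, omics="mirna", method="raw")
    meth_fm = FeatureMatrix(meth.T, omics="methylation", method="raw")

    return FeatureMatrix.concat([
        set_mat,
        catalogues["SBS96"].to_feature_matrix(),
        catalogues["DBS78"].to_feature_matrix(),
        catalogues["ID83"].to_feature_matrix(),
        exposures.to_feature_matrix(prefix="SBS96"),
        region_mat,
        cn_set,
        mrna_fm,
        mirna_fm,
        meth_fm,
    ])
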