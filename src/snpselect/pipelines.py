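"""End-to-end workflows: FSA selection, FSA + random projection / PCA, FSA vs MDR.

Three composable pipelines over the library modules:

1. :func:`run_algorithm1` — stratified 50/50 split, GCI-SVM feature
   selection, retrain on the top-m SNPs, test accuracy, and validation of the
   selected SNPs against single-SNP association p-values (with the
   random-pick chance baseline).
2. :func:`run_algorithm2` — Algorithm 1's top-m SNPs projected to k
   dimensions (Achlioptas random projection or PCA scores) for a sweep of k,
   normalized and discretized, then re-selected and re-scored with a linear
   FSA pass.
3. :func:`run_algorithm3` — Algorithm 1's FSA against a full MDR search on
   the same data, reporting accuracies and CV consistency side by side.

Every pipeline is deterministic given its config (reports carry the seed and
a config hash), and no stage sees test labels before its final evaluation:
each stage appends to an audit trail recording whether test labels were used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationTable, OverlapReport, overlap_report, single_snp_pvalues
from .data_io import GenotypeMatrix, load_genotype_tsv, load_vcf, stratified_split
from .mdr import MDRResult, mdr_search
from .preprocess import discretize_equal_width, min_max_normalize
from .projection import make_projection, pca_fit, pca_scores, random_project
from .svm_fsa import (
    FeatureRanking,
    KernelSpec,
    evaluate_accuracy,
    gci_select,
    select_top,
    train_svm,
)
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger("snpselect")


@dataclass
class PipelineConfig:
    """Shared configuration for the three pipelines (JSON-serializable)."""

    # input: exactly one of input_tsv / (input_vcf, input_pheno) / simulation
    input_tsv: str | None = None
    input_vcf: str | None = None
    input_pheno: str | None = None
    simulation: SimulationConfig | None = None

    seed: int = 0
    split_fraction: float = 0.5

    kernel: KernelSpec = field(default_factory=KernelSpec)
    C: float = 1.0
    corr_threshold: float = 0.8
    top_m: int = 32
    assoc_method: str = "chisq"
    assoc_top_k: int = 3

    projection_method: str = "rp"  # 'rp' | 'pca'
    k_list: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    distribution: str = "sparse_third"
    normalize_range: tuple[float, float] = (0.0, 1.0)
    n_bins: int = 3
    normalize_discretize: bool = True

    mdr_n_factors: tuple[int, ...] = (1, 2)
    mdr_method: str = "exhaustive"
    mdr_budget: int | None = None
    mdr_folds: int = 10
    mdr_threshold: float = 1.0

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def resolve_input(config: PipelineConfig) -> GenotypeMatrix:
    """Load or simulate the dataset named by the config."""
    if config.input_tsv:
        return load_genotype_tsv(config.input_tsv)
    if config.input_vcf:
        if not config.input_pheno:
            raise ValueError("input_vcf requires input_pheno")
        return load_vcf(config.input_vcf, config.input_pheno)
    if config.simulation is not None:
        return simulate_dataset(config.simulation)
    raise ValueError("config names no input (tsv, vcf, or simulation)")


@dataclass
class StageRecord:
    """One audit-trail entry: stage name, data shapes, test-label use."""

    stage: str
    shape: tuple[int, ...]
    used_test_labels: bool


@dataclass
class Algorithm1Report:
    config_hash: str
    seed: int
    ranking: FeatureRanking
    selected: pd.DataFrame  # selected SNPs in increasing p-value order
    test_accuracy: float
    association: AssociationTable
    overlap: OverlapReport
    audit: list[StageRecord]

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "test_accuracy_pct": self.test_accuracy,
            "n_selected": len(self.selected),
            "overlap_top_k": self.overlap.overlap_count,
            "baseline_pct": 100.0 * self.overlap.baseline_probability,
        }


def run_algorithm1(
    config: PipelineConfig, data: GenotypeMatrix | None = None
) -> Algorithm1Report:
    """FSA selection with p-value validation (the first pipeline)."""
    data = data if data is not None else resolve_input(config)
    audit: list[StageRecord] = []
    split = stratified_split(data, config.split_fraction, config.seed)
    audit.append(StageRecord("split", data.values.shape, False))

    ranking = gci_select(split.train, config.kernel, config.C, config.corr_threshold)
    audit.append(StageRecord("gci_select", split.train.values.shape, False))
    m = min(config.top_m, data.n_snps)
    train_top = select_top(split.train, ranking, m)
    test_top = select_top(split.test, ranking, m)
    audit.append(StageRecord("select_top", train_top.values.shape, False))

    model = train_svm(train_top, config.kernel, config.C)
    audit.append(StageRecord("retrain", train_top.values.shape, False))
    accuracy = evaluate_accuracy(model, test_top)
    audit.append(StageRecord("evaluate", test_top.values.shape, True))

    assoc = single_snp_pvalues(data, config.assoc_method)
    overlap = overlap_report(ranking, assoc, config.assoc_top_k, n_selected=m)
    selected = overlap.selected.sort_values("p_value", kind="stable").reset_index(drop=True)
    logger.info(
        "algorithm1: accuracy=%.3f%% overlap=%d/%d baseline=%.1f%%",
        accuracy, overlap.overlap_count, config.assoc_top_k,
        100 * overlap.baseline_probability,
    )
    return Algorithm1Report(
        config_hash=config.config_hash(),
        seed=config.seed,
        ranking=ranking,
        selected=selected,
        test_accuracy=accuracy,
        association=assoc,
        overlap=overlap,
        audit=audit,
    )


@dataclass
class Algorithm2Report:
    config_hash: str
    seed: int
    base_accuracy: float  # unprojected top-m accuracy (Algorithm 1)
    table: pd.DataFrame  # columns: method, k, accuracy_pct
    audit: list[StageRecord]


def _project_pair(
    train: GenotypeMatrix, test: GenotypeMatrix, method: str, k: int, config: PipelineConfig
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    if method == "rp":
        op = make_projection(train.n_snps, k, config.distribution, seed=config.seed + k)
        return random_project(train, op), random_project(test, op)
    basis = pca_fit(train, k)
    return pca_scores(train, basis), pca_scores(test, basis)


def run_algorithm2(
    config: PipelineConfig, data: GenotypeMatrix | None = None
) -> Algorithm2Report:
    """FSA + random projection (or PCA scores) over a sweep of target dimensions."""
    data = data if data is not None else resolve_input(config)
    audit: list[StageRecord] = []
    split = stratified_split(data, config.split_fraction, config.seed)
    ranking = gci_select(split.train, config.kernel, config.C, config.corr_threshold)
    m = min(config.top_m, data.n_snps)
    train_top = select_top(split.train, ranking, m)
    test_top = select_top(split.test, ranking, m)
    audit.append(StageRecord("first_pass_select", train_top.values.shape, False))

    base_model = train_svm(train_top, config.kernel, config.C)
    base_accuracy = evaluate_accuracy(base_model, test_top)
    audit.append(StageRecord("base_evaluate", test_top.values.shape, True))

    linear = KernelSpec("linear")
    rows = []
    for k in config.k_list:
        if k > m:
            logger.warning("k=%d exceeds top_m=%d; skipped", k, m)
            continue
        tr_p, te_p = _project_pair(train_top, test_top, config.projection_method, k, config)
        audit.append(StageRecord(f"project_k{k}", tr_p.values.shape, False))
        if config.normalize_discretize:
            tr_vals, norm = min_max_normalize(tr_p.values, *config.normalize_range)
            te_vals = norm.transform(te_p.values)
            tr_codes, scheme = discretize_equal_width(tr_vals, config.n_bins)
            te_codes = scheme.transform(te_vals)
            tr_p = tr_p.with_values(tr_codes.astype(float), tr_p.snp_ids)
            te_p = te_p.with_values(te_codes.astype(float), te_p.snp_ids)
            audit.append(StageRecord(f"normalize_discretize_k{k}", tr_p.values.shape, False))
        sub_ranking = gci_select(tr_p, linear, config.C, config.corr_threshold)
        n_sel = max(1, int(sub_ranking.picked.sum()))
        tr_sel = select_top(tr_p, sub_ranking, n_sel)
        te_sel = select_top(te_p, sub_ranking, n_sel)
        model = train_svm(tr_sel, linear, config.C)
        acc = evaluate_accuracy(model, te_sel)
        audit.append(StageRecord(f"evaluate_k{k}", te_sel.values.shape, True))
        rows.append({"method": config.projection_method, "k": k, "accuracy_pct": acc})
    table = pd.DataFrame(rows, columns=["method", "k", "accuracy_pct"])
    return Algorithm2Report(
        config_hash=config.config_hash(),
        seed=config.seed,
        base_accuracy=base_accuracy,
        table=table,
        audit=audit,
    )


@dataclass
class Algorithm3Report:
    config_hash: str
    seed: int
    fsa_accuracy: float
    fsa_selected: list[str]
    mdr_results: list[MDRResult]
    table: pd.DataFrame  # side-by-side: method, model, training/testing acc, cv cons.
    audit: list[StageRecord]


def run_algorithm3(
    config: PipelineConfig, data: GenotypeMatrix | None = None
) -> Algorithm3Report:
    """Compare the FSA pipeline with MDR model search on the same dataset."""
    data = data if data is not None else resolve_input(config)
    a1 = run_algorithm1(config, data)
    audit = list(a1.audit)
    m = min(config.top_m, data.n_snps)

    rows = [
        {
            "method": "FSA",
            "model": " ".join(a1.ranking.snp_ids[: min(4, m)]) + (" ..." if m > 4 else ""),
            "training_acc": np.nan,
            "testing_acc": round(a1.test_accuracy / 100.0, 4),
            "cv_consistency": "",
        }
    ]
    mdr_results = []
    for n in config.mdr_n_factors:
        res = mdr_search(
            data,
            n_factors=n,
            method=config.mdr_method,
            budget=config.mdr_budget,
            forced_loci=None,
            n_folds=config.mdr_folds,
            threshold=config.mdr_threshold,
            seed=config.seed,
        )
        audit.append(StageRecord(f"mdr_{n}_locus", data.values.shape, True))
        mdr_results.append(res)
        rows.append(
            {
                "method": "MDR",
                "model": " ".join(res.best_snp_ids),
                "training_acc": round(res.mean_training_accuracy, 4),
                "testing_acc": round(res.mean_testing_accuracy, 4),
                "cv_consistency": f"{res.cv_consistency}/{res.n_folds}",
            }
        )
    table = pd.DataFrame(rows)
    return Algorithm3Report(
        config_hash=config.config_hash(),
        seed=config.seed,
        fsa_accuracy=a1.test_accuracy,
        fsa_selected=a1.ranking.snp_ids[:m],
        mdr_results=mdr_results,
        table=table,
        audit=audit,
    )


def assert_no_leakage(audit: list[StageRecord]) -> None:
    """Audit hook: test labels may only be used by evaluation/MDR-CV stages."""
    allowed = ("evaluate", "mdr_")
    for rec in audit:
        if rec.used_test_labels and not any(tok in rec.stage for tok in allowed):
            raise AssertionError(f"stage {rec.stage!r} used test labels before evaluation")
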