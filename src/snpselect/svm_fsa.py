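"""SVM training, feature-weight extraction, RFE, and the GCI-SVM selection pass.

The feature selection algorithm (FSA) used throughout this package is the
greedy correlation-incorporated SVM (GCI-SVM): train one soft-margin SVM,
sort features by the norm of their weight-vector component, then walk the
sorted list keeping only features whose absolute Pearson correlation with the
previously kept feature is below a threshold. Kept features move to the front
of the ordering; the rest follow in sorted order. Recursive feature
elimination (RFE) — retrain and drop the smallest-weight feature until two
remain — is provided as the slower classical alternative.

The quadratic program itself is solved by scikit-learn's libsvm-backed
``SVC``; this module owns the kernel parametrization, the weight definition,
and the selection logic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .data_io import GenotypeMatrix

logger = logging.getLogger("snpselect")

KERNEL_KINDS = ("linear", "polynomial", "rbf", "sigmoid")


@dataclass
class KernelSpec:
    """Kernel family and its tunable parameters.

    kind : 'linear' | 'polynomial' | 'rbf' | 'sigmoid'
    p : polynomial degree (polynomial kernel; typically 1..10)
    sigma : RBF width sigma in exp(-||xa-xb||^2 / (2 sigma^2))
    slope, offset : sigmoid kernel tanh(slope * <xa,xb> + offset)
    """

    kind: str = "linear"
    p: int = 2
    sigma: float = 1.0
    slope: float = 0.01
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.p < 1:
            raise ValueError("polynomial degree p must be >= 1")
        if self.kind == "rbf" and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_svc_kwargs(self) -> dict:
        if self.kind == "linear":
            return {"kernel": "linear"}
        if self.kind == "polynomial":
            # (xa . xb + 1)^p  ==  (gamma * xa.xb + coef0)^degree with gamma=1, coef0=1
            return {"kernel": "poly", "degree": self.p, "gamma": 1.0, "coef0": 1.0}
        if self.kind == "rbf":
            return {"kernel": "rbf", "gamma": 1.0 / (2.0 * self.sigma**2)}
        return {"kernel": "sigmoid", "gamma": self.slope, "coef0": self.offset}


@dataclass
class SVMModel:
    """Trained soft-margin SVM in dual form.

    ``dual_coef`` holds alpha_i * y_i for the support vectors, so the decision
    function is ``sum_i dual_coef_i K(x, sv_i) + b``; for the linear kernel the
    primal weight vector ``w = sum_i alpha_i y_i x_i`` is materialized.
    """

    kernel: KernelSpec
    C: float
    dual_coef: np.ndarray
    bias: float
    support_vectors: np.ndarray
    support_labels: np.ndarray
    w: np.ndarray | None
    _svc: SVC = field(repr=False, default=None)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"feature mismatch: model has {self.support_vectors.shape[1]}, data has {X.shape[1]}"
            )
        return self._svc.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) >= 0, 1, -1)


@dataclass
class FeatureRanking:
    """GCI-adjusted feature ordering.

    ``snp_ids`` is the adjusted order (picked features first); ``weights``
    are the per-SNP weight norms in that same order; ``picked`` flags which
    entries survived the correlation filter.
    """

    snp_ids: list[str]
    weights: np.ndarray
    picked: np.ndarray
    corr_threshold: float


def kernel_value(kernel: KernelSpec, xa: np.ndarray, xb: np.ndarray) -> float:
    """Evaluate the kernel function on a single pair of vectors."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError("vectors must have equal length")
    if kernel.kind == "linear":
        return float(xa @ xb)
    if kernel.kind == "polynomial":
        return float((xa @ xb + 1.0) ** kernel.p)
    if kernel.kind == "rbf":
        return float(np.exp(-np.sum((xa - xb) ** 2) / (2.0 * kernel.sigma**2)))
    return float(np.tanh(kernel.slope * (xa @ xb) + kernel.offset))


def train_svm(train: GenotypeMatrix, kernel: KernelSpec | None = None, C: float = 1.0) -> SVMModel:
    """Fit a soft-margin SVM to the training matrix.

    The margin objective minimizes ||w||^2/2 plus C times the slack; C
    defaults to 1.0 (the hard-margin limit C -> inf fails on overlapping
    classes, which genotype data always is).
    """
    kernel = kernel or KernelSpec()
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    if not np.isfinite(train.values).all():
        raise ValueError("training values must be finite")
    svc = SVC(C=C, **kernel.to_svc_kwargs())
    svc.fit(train.values, train.labels)
    w = svc.coef_.ravel().copy() if kernel.kind == "linear" else None
    return SVMModel(
        kernel=kernel,
        C=C,
        dual_coef=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        support_vectors=svc.support_vectors_.copy(),
        support_labels=train.labels[svc.support_].copy(),
        w=w,
        _svc=svc,
    )


def feature_weights(model: SVMModel) -> np.ndarray:
    """Per-feature weight norm used for ranking.

    Linear kernel: |w_j|. Non-linear kernels have no explicit w, so the
    linearized pre-image weight |sum_i alpha_i y_i x_ij| over the support
    vectors is used instead.
    """
    if model.w is not None:
        return np.abs(model.w)
    return np.abs(model.dual_coef @ model.support_vectors)


def pearson_correlation(data: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation matrix.

    Constant columns correlate 0 with everything (by convention, with a
    warning) instead of producing NaNs.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sd = data.std(axis=0)
    const = sd == 0
    if const.any():
        logger.warning("%d constant column(s): correlation set to 0", int(const.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _weight_order(weights: np.ndarray) -> np.ndarray:
    """Indices sorted by weight descending; stable, original order breaks ties."""
    return np.argsort(-weights, kind="stable")


def greedy_correlation_filter(
    weights: np.ndarray,
    corr: np.ndarray,
    threshold: float,
    compare_all_picked: bool = False,
) -> tuple[list[int], np.ndarray]:
    """Steps 3-5 of the GCI pass on explicit weights and correlations.

    Returns the adjusted index order (picked first, then unpicked in sorted
    order) and a boolean picked flag aligned with it.
    """
    order = _weight_order(np.asarray(weights, dtype=float))
    picked: list[int] = [int(order[0])]
    unpicked: list[int] = []
    for j in order[1:]:
        j = int(j)
        ref = picked if compare_all_picked else picked[-1:]
        if all(abs(corr[j, r]) < threshold for r in ref):
            picked.append(j)
        else:
            unpicked.append(j)
    adjusted = picked + unpicked
    flags = np.array([True] * len(picked) + [False] * len(unpicked))
    return adjusted, flags


def gci_select(
    train: GenotypeMatrix,
    kernel: KernelSpec | None = None,
    C: float = 1.0,
    corr_threshold: float = 0.8,
    compare_all_picked: bool = False,
    model: SVMModel | None = None,
) -> FeatureRanking:
    """One-shot GCI-SVM feature selection.

    1. Compute the pairwise Pearson correlations of the features.
    2. Train the SVM once on the training data (or reuse ``model``).
    3. Sort features by weight norm, descending.
    4. Greedy scan: pick the top feature, then repeatedly advance through
       the sorted list picking the next feature whose |correlation| with the
       most recently picked feature is below ``corr_threshold`` (or, with
       ``compare_all_picked``, with every picked feature).
    5. Move the picked features in order to the front; unpicked features
       follow in their sorted order.
    """
    if not 0.0 < corr_threshold <= 1.0:
        raise ValueError("corr_threshold must be in (0, 1]")
    corr = pearson_correlation(train.values)
    model = model or train_svm(train, kernel, C)
    weights = feature_weights(model)
    adjusted, flags = greedy_correlation_filter(weights, corr, corr_threshold, compare_all_picked)
    return FeatureRanking(
        snp_ids=[train.snp_ids[j] for j in adjusted],
        weights=weights[adjusted],
        picked=flags,
        corr_threshold=corr_threshold,
    )


def rfe_rank(train: GenotypeMatrix, kernel: KernelSpec | None = None, C: float = 1.0) -> list[str]:
    """Recursive feature elimination ranking (best first).

    Retrains after each removal of the smallest-weight feature until two
    features remain; the two survivors rank highest, then eliminated features
    in reverse elimination order.
    """
    if train.n_snps < 3:
        raise ValueError("RFE requires at least 3 features")
    remaining = list(range(train.n_snps))
    eliminated: list[int] = []
    while len(remaining) > 2:
        sub = train.subset_snps(remaining)
        weights = feature_weights(train_svm(sub, kernel, C))
        drop_pos = int(np.argmin(weights))  # argmin: first smallest on ties
        eliminated.append(remaining.pop(drop_pos))
    ranking = remaining + eliminated[::-1]
    return [train.snp_ids[j] for j in ranking]


def select_top(data: GenotypeMatrix, ranking: FeatureRanking, m: int) -> GenotypeMatrix:
    """Keep the first ``m`` SNPs of the adjusted order (subjects unchanged)."""
    if not 1 <= m <= data.n_snps:
        raise ValueError(f"m must be in [1, {data.n_snps}]")
    pos = {sid: j for j, sid in enumerate(data.snp_ids)}
    idx = [pos[sid] for sid in ranking.snp_ids[:m]]
    return data.subset_snps(idx)


def evaluate_accuracy(model: SVMModel, test: GenotypeMatrix) -> float:
    """Percent of test subjects whose label sign is predicted correctly."""
    if test.n_subjects == 0:
        raise ValueError("empty test set")
    preds = model.predict(test.values)
    return 100.0 * float(np.mean(preds == test.labels))
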