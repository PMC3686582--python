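"""Multifactor Dimensionality Reduction (MDR), implemented from scratch.

MDR collapses an n-locus genotype table into a single binary attribute: for
each observed combination of genotype codes at the chosen loci (a "cell"),
the training case:control ratio is computed; cells at or above a threshold
(default 1.0) are labeled high-risk, the rest low-risk. Subjects in high-risk
cells are predicted cases. Model search runs under stratified k-fold
cross-validation: within each fold the candidate locus combination with the
fewest misclassified training subjects wins, and the cross-validation
consistency (CV consistency) is the number of folds that agree on the overall
winner.

Search modes: exhaustive (all C(d, n) combinations), forced (one given
combination), and random (a seeded budget of distinct combinations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .data_io import GenotypeMatrix

logger = logging.getLogger("snpselect")

EXHAUSTIVE_CAP = 10**6


@dataclass
class MDRModel:
    """High/low-risk labeling of the genotype cells at a locus combination."""

    loci: tuple[int, ...]
    cell_labels: dict[tuple[int, ...], str]  # "high_risk" | "low_risk"
    ratio_threshold: float
    training_accuracy: float
    testing_accuracy: float | None = None


@dataclass
class MDRResult:
    """Cross-validated search outcome for one factor count."""

    n_factors: int
    best_loci: tuple[int, ...]
    best_snp_ids: tuple[str, ...]
    mean_training_accuracy: float
    mean_testing_accuracy: float
    mean_testing_accuracy_all_folds: float
    cv_consistency: int
    n_folds: int
    fold_choices: list[tuple[int, ...]]


def mdr_fit_cells(train: GenotypeMatrix, loci: tuple[int, ...], threshold: float = 1.0) -> MDRModel:
    """Label each observed genotype cell high/low risk from its case:control ratio.

    A cell with cases but no controls has infinite ratio and is high-risk.
    Training accuracy is the fraction of training subjects whose label matches
    their cell's risk class (high-risk -> case).
    """
    if train.n_subjects == 0:
        raise ValueError("empty training set")
    geno = train.values[:, list(loci)].astype(int)
    is_case = train.labels == 1
    keys = [tuple(row) for row in geno]
    cases: dict[tuple[int, ...], int] = {}
    controls: dict[tuple[int, ...], int] = {}
    for key, c in zip(keys, is_case):
        if c:
            cases[key] = cases.get(key, 0) + 1
            controls.setdefault(key, 0)
        else:
            controls[key] = controls.get(key, 0) + 1
            cases.setdefault(key, 0)
    cell_labels: dict[tuple[int, ...], str] = {}
    correct = 0
    for key in cases:
        n_case, n_ctrl = cases[key], controls[key]
        if n_ctrl == 0:
            high = n_case > 0
        else:
            high = (n_case / n_ctrl) >= threshold
        cell_labels[key] = "high_risk" if high else "low_risk"
        correct += n_case if high else n_ctrl
    return MDRModel(
        loci=tuple(loci),
        cell_labels=cell_labels,
        ratio_threshold=threshold,
        training_accuracy=correct / train.n_subjects,
    )


def mdr_predict(model: MDRModel, data: GenotypeMatrix) -> np.ndarray:
    """Predict +1 for subjects in high-risk cells, -1 otherwise.

    Combinations unseen in training predict control (-1): deterministic and
    conservative.
    """
    geno = data.values[:, list(model.loci)].astype(int)
    preds = np.array(
        [1 if model.cell_labels.get(tuple(row)) == "high_risk" else -1 for row in geno]
    )
    return preds


# -- vectorized candidate scoring -------------------------------------------
# Candidate search inside cross-validation dominates the runtime; scoring a
# candidate reduces to two bincounts over flattened cell indices.

def _cell_index(geno: np.ndarray, loci: tuple[int, ...], n_codes: int) -> np.ndarray:
    idx = np.zeros(geno.shape[0], dtype=np.int64)
    for j in loci:
        idx = idx * n_codes + geno[:, j]
    return idx


def _score_candidate(
    geno: np.ndarray, is_case: np.ndarray, loci: tuple[int, ...], n_codes: int, threshold: float
) -> int:
    """Number of correctly classified training subjects for one candidate."""
    idx = _cell_index(geno, loci, n_codes)
    size = n_codes ** len(loci)
    case_counts = np.bincount(idx[is_case], minlength=size)
    ctrl_counts = np.bincount(idx[~is_case], minlength=size)
    with np.errstate(divide="ignore", invalid="ignore"):
        high = np.where(
            ctrl_counts > 0, case_counts >= threshold * ctrl_counts, case_counts > 0
        )
    return int(np.where(high, case_counts, ctrl_counts).sum())


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per subject: stratified, each class split within 1."""
    assign = np.empty(labels.shape[0], dtype=int)
    for cls in (-1, 1):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        assign[perm] = np.arange(perm.size) % n_folds
    return assign


def mdr_cross_validate(
    data: GenotypeMatrix,
    n_factors: int,
    candidates: list[tuple[int, ...]],
    n_folds: int = 10,
    threshold: float = 1.0,
    seed: int = 0,
) -> MDRResult:
    """Stratified k-fold CV over a candidate set of locus combinations.

    Within each fold the candidate with the fewest misclassified training
    subjects is selected (ties broken by lexicographic loci order) and
    evaluated on the held-out part. The overall best model is the candidate
    chosen most often; CV consistency is the number of folds choosing it.
    Reported accuracies are means over the folds where it was chosen.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not candidates:
        raise ValueError("candidate list must not be empty")
    candidates = sorted(tuple(c) for c in candidates)
    geno = data.values.astype(int)
    if geno.min() < 0:
        raise ValueError("genotype codes must be non-negative integers")
    n_codes = int(geno.max()) + 1
    is_case = data.labels == 1

    rng = np.random.default_rng(seed)
    for attempt in range(2):
        assign = _stratified_folds(data.labels, n_folds, rng)
        ok = all(
            len(np.unique(data.labels[assign != f])) == 2 for f in range(n_folds)
        )
        if ok:
            break
        if attempt == 1:
            raise ValueError("could not build folds with both classes in every training part")

    fold_choices: list[tuple[int, ...]] = []
    fold_train_acc: list[float] = []
    fold_test_acc: list[float] = []
    for f in range(n_folds):
        tr = assign != f
        te = ~tr
        g_tr, c_tr = geno[tr], is_case[tr]
        best: tuple[int, ...] | None = None
        best_correct = -1
        for loci in candidates:
            correct = _score_candidate(g_tr, c_tr, loci, n_codes, threshold)
            if correct > best_correct:
                best_correct = correct
                best = loci
        train_part = data.subset_subjects(np.flatnonzero(tr))
        test_part = data.subset_subjects(np.flatnonzero(te))
        model = mdr_fit_cells(train_part, best, threshold)
        preds = mdr_predict(model, test_part)
        fold_choices.append(best)
        fold_train_acc.append(model.training_accuracy)
        fold_test_acc.append(float(np.mean(preds == test_part.labels)))

    # winner = most frequently chosen; ties -> higher mean testing accuracy
    tallies: dict[tuple[int, ...], list[int]] = {}
    for i, c in enumerate(fold_choices):
        tallies.setdefault(c, []).append(i)
    best_loci = max(
        tallies,
        key=lambda c: (len(tallies[c]), float(np.mean([fold_test_acc[i] for i in tallies[c]]))),
    )
    chosen = tallies[best_loci]
    return MDRResult(
        n_factors=n_factors,
        best_loci=best_loci,
        best_snp_ids=tuple(data.snp_ids[j] for j in best_loci),
        mean_training_accuracy=float(np.mean([fold_train_acc[i] for i in chosen])),
        mean_testing_accuracy=float(np.mean([fold_test_acc[i] for i in chosen])),
        mean_testing_accuracy_all_folds=float(np.mean(fold_test_acc)),
        cv_consistency=len(chosen),
        n_folds=n_folds,
        fold_choices=fold_choices,
    )


def mdr_search(
    data: GenotypeMatrix,
    n_factors: int,
    method: str = "exhaustive",
    budget: int | None = None,
    forced_loci: tuple[int, ...] | None = None,
    n_folds: int = 10,
    threshold: float = 1.0,
    seed: int = 0,
) -> MDRResult:
    """Search locus combinations by the exhaustive, forced, or random method.

    * exhaustive — every C(d, n_factors) combination (refused above a cap;
      use the random method instead);
    * forced — exactly the one combination in ``forced_loci``;
    * random — ``budget`` distinct combinations drawn uniformly (seeded).
    """
    d = data.n_snps
    if method == "exhaustive":
        n_cand = comb(d, n_factors)
        if n_cand > EXHAUSTIVE_CAP:
            raise ValueError(
                f"exhaustive search over {n_cand} combinations exceeds the cap "
                f"({EXHAUSTIVE_CAP}); use method='random' with a budget"
            )
        candidates = list(combinations(range(d), n_factors))
    elif method == "forced":
        if forced_loci is None:
            raise ValueError("forced method requires forced_loci")
        candidates = [tuple(forced_loci)]
    elif method == "random":
        if budget is None or budget < 1:
            raise ValueError("random method requires budget >= 1")
        rng = np.random.default_rng(seed)
        total = comb(d, n_factors)
        if budget >= total:
            candidates = list(combinations(range(d), n_factors))
        else:
            seen: set[tuple[int, ...]] = set()
            while len(seen) < budget:
                seen.add(tuple(sorted(rng.choice(d, size=n_factors, replace=False).tolist())))
            candidates = sorted(seen)
    else:
        raise ValueError(f"unknown search method {method!r}")
    return mdr_cross_validate(data, n_factors, candidates, n_folds, threshold, seed)
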