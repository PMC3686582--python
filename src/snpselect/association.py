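"""Single-SNP association p-values and the random-pick baseline.

Each SNP is tested for association with case/control status either by a
Pearson chi-square test on the 2 x g label-by-genotype contingency table
(df = g - 1) or by a likelihood-ratio test of a one-covariate logistic
regression against the intercept-only model (df = 1); for a single SNP the
two are asymptotically equivalent. The random-pick probability quantifies
how often a random selection of SNPs would hit the top-ranked ones by
chance, the baseline a feature-selection result must beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import GenotypeMatrix
from .svm_fsa import FeatureRanking

logger = logging.getLogger("snpselect")


@dataclass
class AssociationTable:
    """Per-SNP p-values, ascending; ``table`` has columns rank/snp_id/p_value."""

    table: pd.DataFrame

    def top(self, k: int) -> list[str]:
        return self.table["snp_id"].head(k).tolist()

    def p_value(self, snp_id: str) -> float:
        row = self.table.loc[self.table["snp_id"] == snp_id, "p_value"]
        return float(row.iloc[0])

    def rank(self, snp_id: str) -> int:
        row = self.table.loc[self.table["snp_id"] == snp_id, "rank"]
        return int(row.iloc[0])


def _chisq_pvalue(col: np.ndarray, is_case: np.ndarray, merge_small: bool) -> float:
    codes, inv = np.unique(col, return_inverse=True)
    g = codes.size
    if g < 2:
        return 1.0
    case_counts = np.bincount(inv[is_case], minlength=g).astype(float)
    ctrl_counts = np.bincount(inv[~is_case], minlength=g).astype(float)
    table = np.vstack([case_counts, ctrl_counts])
    if merge_small:
        # merge any genotype class with expected count < 1 into its neighbour
        while table.shape[1] > 2:
            total = table.sum()
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
            small = np.flatnonzero(expected.min(axis=0) < 1.0)
            if small.size == 0:
                break
            j = small[0]
            nbr = j - 1 if j > 0 else j + 1
            table[:, nbr] += table[:, j]
            table = np.delete(table, j, axis=1)
    if table.shape[1] < 2:
        return 1.0
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(p)


def _logistic_pvalue(col: np.ndarray, y01: np.ndarray) -> float:
    # genotype enters as categorical dummies over the observed classes, so the
    # likelihood-ratio test has df = g - 1 and matches the Pearson chi-square
    # on the same 2 x g table asymptotically
    import statsmodels.api as sm

    codes = np.unique(col)
    if codes.size < 2:
        return 1.0
    dummies = np.column_stack([(col == c).astype(float) for c in codes[1:]])
    X = sm.add_constant(dummies)
    try:
        fit = sm.Logit(y01, X).fit(disp=0, maxiter=200)
        return float(fit.llr_pvalue)
    except Exception:  # perfect separation etc.
        logger.warning("logistic fit failed for a SNP; recording p=1")
        return 1.0


def single_snp_pvalues(
    data: GenotypeMatrix, method: str = "chisq", merge_small: bool = True
) -> AssociationTable:
    """Per-SNP association p-values, sorted ascending.

    ``method='chisq'`` builds the 2 x g contingency table of label against
    genotype class (classes with expected count < 1 merged into a neighbour
    unless ``merge_small=False``); ``method='logistic'`` runs a df=1
    likelihood-ratio test of the single-covariate logistic model. SNPs with
    one observed genotype class record p = 1 with a warning.
    """
    if method not in ("chisq", "logistic"):
        raise ValueError(f"unknown method {method!r}")
    is_case = data.labels == 1
    y01 = is_case.astype(float)
    pvals = np.empty(data.n_snps)
    n_degenerate = 0
    for j in range(data.n_snps):
        col = data.values[:, j]
        if np.unique(col).size < 2:
            pvals[j] = 1.0
            n_degenerate += 1
            continue
        if method == "chisq":
            pvals[j] = _chisq_pvalue(col, is_case, merge_small)
        else:
            pvals[j] = _logistic_pvalue(col, y01)
    if n_degenerate:
        logger.warning("%d SNP(s) with a single genotype class: p=1 recorded", n_degenerate)
    df = pd.DataFrame({"snp_id": data.snp_ids, "p_value": pvals})
    df = df.sort_values(["p_value", "snp_id"], kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["bonferroni"] = np.minimum(df["p_value"] * data.n_snps, 1.0)
    return AssociationTable(df)


def random_pick_probability(
    n_total: int, n_picked: int, n_targets: int, exact: bool = False
) -> float:
    """Probability that a random pick of ``n_picked`` SNPs hits >= 1 of the
    ``n_targets`` top SNPs.

    Default is the independent-draws approximation
    ``1 - (1 - n_targets/n_total)^n_picked``; ``exact=True`` uses the
    hypergeometric ``1 - C(N - t, m) / C(N, m)``.
    """
    if n_total <= 0 or n_targets < 0 or not 0 < n_picked <= n_total:
        raise ValueError("require 0 < n_picked <= n_total and n_targets >= 0")
    if n_targets == 0:
        return 0.0
    if n_targets > n_total:
        raise ValueError("n_targets cannot exceed n_total")
    if exact:
        if n_picked > n_total - n_targets:
            return 1.0
        return 1.0 - comb(n_total - n_targets, n_picked) / comb(n_total, n_picked)
    return 1.0 - (1.0 - n_targets / n_total) ** n_picked


@dataclass
class OverlapReport:
    """FSA selections annotated with association ranks, plus the chance baseline."""

    selected: pd.DataFrame  # snp_id, p_value, assoc_rank, in_top_k
    top_k: int
    overlap_count: int
    baseline_probability: float


def overlap_report(
    ranking: FeatureRanking, assoc: AssociationTable, top_k: int, n_selected: int | None = None
) -> OverlapReport:
    """How many FSA-selected SNPs fall in the association top-k, vs chance.

    ``n_selected`` defaults to the number of picked features in the ranking.
    """
    if n_selected is None:
        n_selected = int(ranking.picked.sum())
    selected_ids = ranking.snp_ids[:n_selected]
    top_ids = set(assoc.top(top_k))
    rows = [
        {
            "snp_id": sid,
            "p_value": assoc.p_value(sid),
            "assoc_rank": assoc.rank(sid),
            "in_top_k": sid in top_ids,
        }
        for sid in selected_ids
    ]
    df = pd.DataFrame(rows)
    n_total = len(assoc.table)
    return OverlapReport(
        selected=df,
        top_k=top_k,
        overlap_count=int(df["in_top_k"].sum()) if len(df) else 0,
        baseline_probability=random_pick_probability(n_total, len(selected_ids), top_k),
    )
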