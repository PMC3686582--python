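"""Genotype matrix container, text/VCF readers, and the stratified case/control split.

The central container is :class:`GenotypeMatrix`: an ``n_subjects x n_snps``
numeric matrix (additive 0/1/2 alternate-allele coding; columns may hold
continuous values after projection or normalization) together with SNP ids,
subject ids, and a binary phenotype label per subject coded +1 (case) / -1
(control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("snpselect")

#: Strings treated as a missing genotype in TSV input.
MISSING_TOKENS = {".", "NA", "na", ""}


class ParseError(ValueError):
    """A malformed input file (bad row length, unreadable field)."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs matrix with ids and binary labels.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_snps)
        Genotype codes 0/1/2, or continuous values after projection or
        normalization.
    snp_ids : list of str
        Unique column identifiers.
    subject_ids : list of str
        Row identifiers.
    labels : ndarray of {+1, -1}
        +1 = case, -1 = control.
    """

    values: np.ndarray
    snp_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.values.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels length must match row count")
        if len(self.snp_ids) != d:
            raise ValueError("snp_ids length must match column count")
        if len(set(self.snp_ids)) != d:
            raise ValueError("snp_ids must be unique")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +/-1, found {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_subjects(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[idx],
            list(self.snp_ids),
            [self.subject_ids[i] for i in idx],
            self.labels[idx],
        )

    def subset_snps(self, idx: list[int] | np.ndarray) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            [self.snp_ids[i] for i in idx],
            list(self.subject_ids),
            self.labels.copy(),
        )

    def with_values(self, values: np.ndarray, snp_ids: list[str]) -> "GenotypeMatrix":
        """New matrix with the same subjects/labels but replaced columns."""
        return GenotypeMatrix(values, snp_ids, list(self.subject_ids), self.labels.copy())


@dataclass
class SplitPair:
    """Disjoint train/test partition of a :class:`GenotypeMatrix`."""

    train: GenotypeMatrix
    test: GenotypeMatrix


def _map_labels(raw: np.ndarray) -> np.ndarray:
    """Map {0,1} or {-1,+1} file labels onto {-1,+1}."""
    vals = set(np.unique(raw).tolist())
    if vals <= {-1.0, 1.0}:
        return raw.astype(int)
    if vals <= {0.0, 1.0}:
        return np.where(raw > 0, 1, -1)
    raise ValueError(f"labels must be binary (0/1 or -1/+1), found {sorted(vals)}")


def _impute_column(col: np.ndarray, snp_id: str, method: str) -> np.ndarray:
    """Fill NaNs with the per-SNP mean (for SVM/projection) or mode (for MDR)."""
    mask = np.isnan(col)
    if not mask.any():
        return col
    observed = col[~mask]
    if observed.size == 0:
        raise ValueError(f"SNP {snp_id!r}: all genotypes missing, cannot impute")
    if method == "mean":
        fill = observed.mean()
    elif method == "mode":
        codes, counts = np.unique(observed, return_counts=True)
        fill = codes[np.argmax(counts)]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out = col.copy()
    out[mask] = fill
    return out


def load_genotype_tsv(path: str, label_column: str = "label", impute: str = "mean") -> GenotypeMatrix:
    """Read a tab-separated genotype file.

    Expected layout: header ``subject_id <snp1> ... <snpM> <label_column>``,
    one row per subject. Missing genotypes (".", "NA", empty) are imputed
    per SNP with the column mean (default) or mode.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if label_column not in header:
            raise ParseError(f"label column {label_column!r} not in header")
        n_fields = len(header)
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
                )
            rows.append(fields)
    label_idx = header.index(label_column)
    snp_cols = [i for i in range(1, n_fields) if i != label_idx]
    snp_ids = [header[i] for i in snp_cols]
    subject_ids = [r[0] for r in rows]

    def parse_geno(tok: str, lineno: int) -> float:
        if tok in MISSING_TOKENS:
            return np.nan
        try:
            return float(tok)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: bad genotype value {tok!r}") from None

    values = np.array(
        [[parse_geno(r[i], ln) for i in snp_cols] for ln, r in enumerate(rows, start=2)],
        dtype=float,
    ).reshape(len(rows), len(snp_cols))
    try:
        raw_labels = np.array([float(r[label_idx]) for r in rows])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric label: {exc}") from None
    labels = _map_labels(raw_labels)
    for j, sid in enumerate(snp_ids):
        values[:, j] = _impute_column(values[:, j], sid, impute)
    return GenotypeMatrix(values, snp_ids, subject_ids, labels)


def write_genotype_tsv(data: GenotypeMatrix, path: str, label_column: str = "label") -> None:
    """Write the TSV format read by :func:`load_genotype_tsv` (round-trip safe)."""
    df = pd.DataFrame(data.values, columns=data.snp_ids)
    df.insert(0, "subject_id", data.subject_ids)
    df[label_column] = data.labels
    df.to_csv(path, sep="\t", index=False)


def load_vcf(path: str, phenotype_path: str, impute: str = "mean") -> GenotypeMatrix:
    """Read a VCF and a two-column ``sample_id<TAB>label`` phenotype file.

    Biallelic sites are encoded additively (ALT-allele count 0/1/2);
    multi-allelic sites are skipped with a warning. Sample order follows the
    VCF header. Missing calls ("./.") are imputed to the per-site mean (or
    mode) of the observed codes.
    """
    from cyvcf2 import VCF

    pheno = pd.read_csv(
        phenotype_path, sep="\t", header=None, names=["sample_id", "label"], dtype={"sample_id": str}
    )
    pheno_map = dict(zip(pheno["sample_id"], pheno["label"]))

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pheno_map]
    if missing:
        raise ValueError(f"samples missing from phenotype file: {missing}")

    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%s (ALT=%s)", var.CHROM, var.POS, var.ALT)
            continue
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 3, 2.0, gt)
        col[gt == 2] = np.nan
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(sid)
        columns.append(col)
    values = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    for j, sid in enumerate(snp_ids):
        values[:, j] = _impute_column(values[:, j], sid, impute)
    labels = _map_labels(np.array([float(pheno_map[s]) for s in samples]))
    return GenotypeMatrix(values, snp_ids, samples, labels)


def stratified_split(data: GenotypeMatrix, fraction: float = 0.5, seed: int = 0) -> SplitPair:
    """Random split preserving class proportions.

    Within each class, ``floor(fraction * class_count)`` subjects are drawn
    uniformly at random into the training set; the rest form the test set.
    Deterministic for a given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (-1, 1):
        members = np.flatnonzero(data.labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls:+d} has fewer than 2 subjects")
        perm = rng.permutation(members)
        n_train = int(np.floor(fraction * members.size))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    train_idx_a = np.sort(np.array(train_idx))
    test_idx_a = np.sort(np.array(test_idx))
    return SplitPair(data.subset_subjects(train_idx_a), data.subset_subjects(test_idx_a))
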