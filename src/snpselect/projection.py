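"""Achlioptas random projection and the PCA-score alternative.

A data matrix A (n points in R^d) is mapped to E = (1/sqrt(k)) A R where R is
a d x k matrix of i.i.d. entries from one of the two database-friendly laws:

* dense:  +1 / -1 each with probability 1/2
* sparse: sqrt(3) * {+1 with prob 1/6, 0 with prob 2/3, -1 with prob 1/6}

Both have zero mean and unit variance, so squared pairwise distances are
preserved in expectation; the Johnson-Lindenstrauss bound
``k0 = (4 + 2 beta) ln n / (eps^2/2 - eps^3/3)`` gives the target dimension
at which all pairwise distances stay within (1 +/- eps) of the originals with
probability at least 1 - n^(-beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .data_io import GenotypeMatrix

DISTRIBUTIONS = ("dense_pm1", "sparse_third")


@dataclass
class ProjectionOperator:
    """A d x k random matrix R with its 1/sqrt(k) scale."""

    R: np.ndarray
    k: int
    distribution: str
    seed: int

    @property
    def scale(self) -> float:
        return 1.0 / np.sqrt(self.k)


@dataclass
class PCABasis:
    """Fitted principal-component basis: loadings, column means, variances."""

    loadings: np.ndarray  # d x k, orthonormal columns
    means: np.ndarray
    explained_variance: np.ndarray


def jl_min_dimension(n: int, epsilon: float, beta: float = 1.0) -> int:
    """Smallest integer k strictly above the Johnson-Lindenstrauss bound k0."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    if beta <= 0:
        raise ValueError("beta must be positive")
    k0 = (4.0 + 2.0 * beta) * np.log(n) / (epsilon**2 / 2.0 - epsilon**3 / 3.0)
    return int(np.floor(k0)) + 1


def make_projection(d: int, k: int, distribution: str = "sparse_third", seed: int = 0) -> ProjectionOperator:
    """Draw a d x k random projection matrix from one of the two Achlioptas laws."""
    if k < 1 or d < 1:
        raise ValueError("d and k must be >= 1")
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}; use one of {DISTRIBUTIONS}")
    rng = np.random.default_rng(seed)
    if distribution == "dense_pm1":
        R = rng.choice([-1.0, 1.0], size=(d, k))
    else:
        R = np.sqrt(3.0) * rng.choice(
            [1.0, 0.0, -1.0], size=(d, k), p=[1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0]
        )
    return ProjectionOperator(R=R, k=k, distribution=distribution, seed=seed)


def project_values(values: np.ndarray, op: ProjectionOperator) -> np.ndarray:
    """Apply E = (1/sqrt(k)) A R to a raw matrix."""
    values = np.asarray(values, dtype=float)
    if values.shape[1] != op.R.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {values.shape[1]} columns, R has {op.R.shape[0]} rows"
        )
    return op.scale * (values @ op.R)


def random_project(data: GenotypeMatrix, op: ProjectionOperator) -> GenotypeMatrix:
    """Project a genotype matrix to k dimensions named dim_1..dim_k."""
    projected = project_values(data.values, op)
    dim_ids = [f"dim_{j + 1}" for j in range(op.k)]
    return data.with_values(projected, dim_ids)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude entry positive (reproducibility)."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_fit(data: GenotypeMatrix, k: int) -> PCABasis:
    """Fit the top-k principal components of the column-centered matrix."""
    n, d = data.values.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k must be in [1, {min(n - 1, d)}]")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(data.values)
    return PCABasis(
        loadings=_fix_signs(pca.components_.T),
        means=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )


def pca_scores(data: GenotypeMatrix, basis: PCABasis) -> GenotypeMatrix:
    """Project onto the fitted basis: scores = (X - means) . loadings."""
    if data.values.shape[1] != basis.loadings.shape[0]:
        raise ValueError("column count does not match the fitted basis")
    scores = (data.values - basis.means) @ basis.loadings
    dim_ids = [f"pc_{j + 1}" for j in range(basis.loadings.shape[1])]
    return data.with_values(scores, dim_ids)
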