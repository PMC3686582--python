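"""Min-max normalization and equal-width discretization.

Both transforms are fit column-wise on training data and can be re-applied
to held-out data with the training statistics, so no test-set information
leaks into the fitted parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("snpselect")


@dataclass
class NormalizationParams:
    """Per-column observed range plus the target range.

    Maps v to ``(v - min_a) / (max_a - min_a) * (new_max - new_min) + new_min``.
    """

    min_a: np.ndarray
    max_a: np.ndarray
    new_min: float
    new_max: float

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        span = self.max_a - self.min_a
        out = np.empty_like(data)
        const = span == 0
        safe_span = np.where(const, 1.0, span)
        out = (data - self.min_a) / safe_span * (self.new_max - self.new_min) + self.new_min
        out[:, const] = self.new_min
        return out


@dataclass
class DiscretizationScheme:
    """Equal-width bin edges per column with integer codes 0..n_bins-1.

    Intervals are half-open ``[lo, hi)``; the final interval is closed so the
    column maximum maps to code ``n_bins - 1``.
    """

    n_bins: int
    edges: np.ndarray  # (n_bins + 1) x n_columns

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        codes = np.empty(data.shape, dtype=int)
        for j in range(data.shape[1]):
            if self.edges[0, j] == self.edges[-1, j]:  # constant column
                codes[:, j] = 0
                continue
            # searchsorted on interior edges: ties at an edge go to the upper bin
            codes[:, j] = np.searchsorted(self.edges[1:-1, j], data[:, j], side="right")
        return np.clip(codes, 0, self.n_bins - 1)


def min_max_normalize(
    data: np.ndarray, new_min: float = 0.0, new_max: float = 1.0
) -> tuple[np.ndarray, NormalizationParams]:
    """Affine rescale of each column from its observed range to [new_min, new_max].

    A constant column maps entirely to ``new_min`` (with a warning) rather
    than dividing by zero.
    """
    if not new_max > new_min:
        raise ValueError("new_max must exceed new_min")
    data = np.asarray(data, dtype=float)
    params = NormalizationParams(data.min(axis=0), data.max(axis=0), new_min, new_max)
    n_const = int(np.sum(params.max_a == params.min_a))
    if n_const:
        logger.warning("%d constant column(s) mapped to new_min during normalization", n_const)
    return params.transform(data), params


def discretize_equal_width(
    data: np.ndarray, n_bins: int = 3
) -> tuple[np.ndarray, DiscretizationScheme]:
    """Bin each column into ``n_bins`` equal-width intervals, codes 0..n_bins-1."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("data must be finite")
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    if np.any(lo == hi):
        logger.warning("constant column(s) map entirely to bin 0 during discretization")
    edges = lo[None, :] + np.arange(n_bins + 1)[:, None] * ((hi - lo)[None, :] / n_bins)
    scheme = DiscretizationScheme(n_bins, edges)
    return scheme.transform(data), scheme
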