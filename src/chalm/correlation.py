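"""Balanced subsetting, Spearman correlation and the permutation test
comparing two correlation coefficients.

Most promoter CGIs are unmethylated, so methylation-vs-outcome scatter is
dominated by the zero bin; :func:`balanced_subset` resamples regions evenly
across the methylation range before any correlation analysis.  Two
correlations computed on equal-sized samples are compared with a
permutation test: pool the (x, y) pairs, split at random into two halves B
times, and report the one-sided exceedance fraction of the permuted
correlation differences — no add-one smoothing, so p may be exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "CorrComparison",
    "balanced_subset",
    "spearman",
    "permutation_corr_test",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired (methylation, outcome) observations for one correlation."""

    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have the same length")
        if len(self.x) < 3:
            raise ValueError("need >= 3 pairs for a correlation")
        if any(not math.isfinite(v) for v in (*self.x, *self.y)):
            raise ValueError("pairs must be finite (no NA)")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[float, float]]
    ) -> "PairedSample":
        xs, ys = zip(*pairs)
        return cls(tuple(float(v) for v in xs), tuple(float(v) for v in ys))


@dataclass(frozen=True)
class CorrComparison:
    """Result of the correlation-difference permutation test."""

    r1: float
    r2: float
    r_d: float  # r2 - r1
    B: int
    p_value: float


def balanced_subset(
    items: Sequence[tuple[str, float]],
    n_bins: int = 200,
    per_bin: int = 60,
    seed: int | None = None,
) -> list[str]:
    """Down-sample ids to a flat methylation distribution.

    Items are assigned to ``n_bins`` equal-width bins over [0, 1] by their
    (traditional) methylation value; up to ``per_bin`` ids are drawn per
    bin without replacement.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    bins: dict[int, list[str]] = {}
    for item_id, value in items:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"methylation value {value} outside [0, 1]")
        b = min(int(value * n_bins), n_bins - 1)
        bins.setdefault(b, []).append(item_id)
    chosen: list[str] = []
    for b in sorted(bins):
        members = bins[b]
        if len(members) <= per_bin:
            chosen.extend(members)
        else:
            idx = rng.choice(len(members), size=per_bin, replace=False)
            chosen.extend(members[i] for i in sorted(idx))
    return chosen


def spearman(sample: PairedSample) -> float:
    """Spearman rank correlation (average ranks on ties); NaN when either
    variable is constant."""
    if len(set(sample.x)) == 1 or len(set(sample.y)) == 1:
        return math.nan
    r, _ = stats.spearmanr(sample.x, sample.y)
    return float(r)


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two (B, n) arrays."""
    rx = stats.rankdata(x, axis=-1)
    ry = stats.rankdata(y, axis=-1)
    rx = rx - rx.mean(axis=-1, keepdims=True)
    ry = ry - ry.mean(axis=-1, keepdims=True)
    num = (rx * ry).sum(axis=-1)
    den = np.sqrt((rx**2).sum(axis=-1) * (ry**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def permutation_corr_test(
    sample1: PairedSample,
    sample2: PairedSample,
    B: int = 10_000,
    seed: int | None = None,
) -> CorrComparison:
    """Permutation test of r2 - r1 between two equal-sized paired samples.

    All (x, y) pairs are pooled (pairs travel together — splitting the
    tuples would destroy the very correlations under test); each of the B
    runs splits the pool uniformly at random into two halves and records
    the difference of the halves' Spearman coefficients.  The one-sided
    p-value is the plain exceedance fraction
    ``(1/B) * sum_b I(r_d^(b) >= r_d)``.
    """
    if len(sample1) != len(sample2):
        raise ValueError("samples must have the same size")
    if B < 1:
        raise ValueError("B must be >= 1")
    r1 = spearman(sample1)
    r2 = spearman(sample2)
    r_d = r2 - r1
    n = len(sample1)
    pool_x = np.array(sample1.x + sample2.x)
    pool_y = np.array(sample1.y + sample2.y)
    rng = np.random.default_rng(seed)
    # one permutation per row; ranks recomputed within each half
    perms = np.array([rng.permutation(2 * n) for _ in range(B)])
    x1, x2 = pool_x[perms[:, :n]], pool_x[perms[:, n:]]
    y1, y2 = pool_y[perms[:, :n]], pool_y[perms[:, n:]]
    r_d_perm = _spearman_rows(x2, y2) - _spearman_rows(x1, y1)
    p = float(np.mean(r_d_perm >= r_d))
    return CorrComparison(r1=r1, r2=r2, r_d=r_d, B=B, p_value=p)
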