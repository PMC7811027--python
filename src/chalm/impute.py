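"""Low-rank SVD/EM completion of read matrices and read extension.

Bisulfite reads (~100 bp) cover only a slice of a promoter CpG island, so
the reads-by-CpGs matrix of a region is mostly missing.  Uncovered cells
are completed with a rank-k SVD approximation estimated by EM: missing
cells are initialized with column means, then the matrix is repeatedly
replaced on the missing cells only by its rank-k reconstruction until the
imputed values stabilise.  Completed values, binarized at a threshold, are
used to extend each read toward a target effective length, which improves
clonal (CHALM) quantification of short-read data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .reads import MethRead, RegionReadMatrix, build_matrix
from .regions import GenomicInterval

__all__ = [
    "ImputationConfig",
    "IneligibleRegionError",
    "eligible",
    "impute_matrix",
    "impute_values",
    "extend_reads",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Imputation and extension parameters.

    Eligibility mirrors the selection used for promoter CGIs: regions
    longer than ``min_region_len`` bases with more than ``min_reads``
    mapped reads.  ``target_length`` is the effective read length to extend
    to (clonal quantification plateaus around 300 bp).
    """

    rank: int = 4
    max_iter: int = 100
    tol: float = 1e-4
    binarize_threshold: float = 0.5
    min_region_len: int = 500
    min_reads: int = 300
    target_length: int = 300

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must be in (0, 1)")


class IneligibleRegionError(ValueError):
    """Region does not meet the length/read-count eligibility thresholds."""


def eligible(
    region: GenomicInterval, n_reads: int, cfg: ImputationConfig
) -> bool:
    """True iff the region is strictly longer than ``min_region_len`` bases
    and has strictly more than ``min_reads`` mapped reads."""
    return len(region) > cfg.min_region_len and n_reads > cfg.min_reads


def impute_values(
    data: np.ndarray, rank: int = 4, max_iter: int = 100, tol: float = 1e-4
) -> np.ndarray:
    """EM completion of a matrix with NaN cells by rank-k SVD.

    Observed cells are returned bit-identical; NaN cells receive the
    rank-``rank`` reconstruction, clipped to [0, 1] at the end.  All-NaN
    columns are not allowed (drop them first).  Deterministic.
    """
    data = np.asarray(data, dtype=float)
    missing = np.isnan(data)
    if missing.all():
        raise ValueError("matrix has no observed entries")
    if np.any(missing.all(axis=0)):
        raise ValueError("matrix has all-NaN columns; drop them first")
    rank = min(rank, min(data.shape))
    if not missing.any():
        return data.copy()
    col_means = np.nanmean(data, axis=0)
    x = np.where(missing, col_means[np.newaxis, :], data)
    prev = x[missing]
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        approx = (u[:, :rank] * s[:rank]) @ vt[:rank]
        x = np.where(missing, approx, data)
        cur = x[missing]
        denom = np.linalg.norm(prev)
        change = np.linalg.norm(cur - prev) / (denom if denom > 0 else 1.0)
        prev = cur
        if change < tol:
            break
    out = data.copy()
    out[missing] = np.clip(x[missing], 0.0, 1.0)
    return out


def impute_matrix(
    matrix: RegionReadMatrix, cfg: ImputationConfig = ImputationConfig()
) -> RegionReadMatrix:
    """Complete a region read-matrix; all-NaN columns are dropped with a
    warning (there is nothing to learn them from)."""
    data = matrix.data
    keep = ~np.isnan(data).all(axis=0)
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} CpG column(s) with no observation dropped",
            stacklevel=2,
        )
        data = data[:, keep]
    completed = impute_values(data, cfg.rank, cfg.max_iter, cfg.tol)
    return RegionReadMatrix(
        matrix.region,
        matrix.cpg_positions[keep],
        completed,
        list(matrix.read_ids),
    )


def extend_reads(
    reads: Iterable[MethRead],
    region: GenomicInterval,
    cfg: ImputationConfig = ImputationConfig(),
) -> list[MethRead]:
    """Extend reads with imputed calls toward the target effective length.

    The full region matrix is imputed once; each read then gains binarized
    imputed calls (value >= ``binarize_threshold`` -> M, else U) at region
    CpGs lying within ``target_length / 2`` of the read midpoint that the
    read does not already cover.  Original calls are never overwritten.
    Raises :class:`IneligibleRegionError` when the region fails the
    eligibility thresholds — callers treat that as an explicit skip.
    """
    reads = list(reads)
    if not eligible(region, len(reads), cfg):
        raise IneligibleRegionError(
            f"{region}: needs > {cfg.min_region_len} bp and "
            f"> {cfg.min_reads} reads ({len(region)} bp, {len(reads)} reads)"
        )
    matrix = impute_matrix(build_matrix(reads, region), cfg)
    pos = matrix.cpg_positions
    by_id = {rid: i for i, rid in enumerate(matrix.read_ids)}
    half = cfg.target_length / 2.0
    out: list[MethRead] = []
    for r in reads:
        row = by_id.get(r.read_id)
        if row is None:  # read had no informative call in the region
            out.append(r)
            continue
        mid = r.midpoint
        covered = {p for p, _ in r.calls}
        new_calls = dict(r.calls)
        in_window = (pos >= mid - half) & (pos < mid + half)
        for j in np.nonzero(in_window)[0]:
            p = int(pos[j])
            if p in covered:
                continue
            value = matrix.data[row, j]
            new_calls[p] = (
                "M" if value >= cfg.binarize_threshold else "U"
            )
        if not new_calls:
            out.append(r)
            continue
        start = min(r.frag_start, min(new_calls))
        end = max(r.frag_end, max(new_calls) + 1)
        out.append(
            MethRead(
                r.read_id,
                r.chrom,
                start,
                end,
                r.strand,
                tuple(sorted(new_calls.items())),
            )
        )
    return out
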