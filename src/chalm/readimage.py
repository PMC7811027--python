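"""Image-like encoding of region reads and the mCpG-shuffle control.

A region's reads are summarized into a fixed 200 x 10 x 2 array: 200
pseudo-read rows sorted by per-read methylation fraction, 10 CpG-bin
columns, and two channels — methylation status and (signed, scaled)
distance of the read midpoint to the TSS.  Regions with fewer than 200
reads are bootstrapped up; regions with more are block-averaged down after
sorting by methylation fraction.  :func:`shuffle_mcpgs` is the clonal-
disruption control: it re-assigns the mCpGs uniformly at random across all
covered read positions while conserving their total number exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .reads import MethRead, build_matrix
from .regions import GenomicInterval

__all__ = [
    "EncoderConfig",
    "ReadImage",
    "RegionSkipped",
    "read_fraction",
    "normalize_cols",
    "normalize_rows",
    "encode_region",
    "shuffle_mcpgs",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Encoding geometry and eligibility.

    ``min_reads`` mirrors the selection of promoter CGIs with more than 50
    mapped reads; ``distance_scale`` (bases) normalizes the TSS-distance
    channel.
    """

    n_rows: int = 200
    n_cols: int = 10
    min_reads: int = 50
    distance_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")


@dataclass(frozen=True)
class ReadImage:
    """The encoded region: (n_rows, n_cols, 2) array.

    Channel 0 is methylation (values in [0, 1]); channel 1 is the scaled
    signed distance of each row's read midpoint to the TSS.
    """

    array: np.ndarray
    region_id: str

    def __post_init__(self) -> None:
        if self.array.ndim != 3 or self.array.shape[2] != 2:
            raise ValueError("array must have shape (n_rows, n_cols, 2)")


class RegionSkipped(ValueError):
    """Region does not have enough mapped reads to encode."""


def read_fraction(read: MethRead) -> float:
    """Per-read methylation fraction f_m = N_m / (N_m + N_u); NaN if the
    read has no informative call."""
    n_m, n_u = read.n_meth, read.n_unmeth
    if n_m + n_u == 0:
        return math.nan
    return n_m / (n_m + n_u)


def normalize_cols(calls: Sequence[float], n_cols: int = 10) -> np.ndarray:
    """Map one read's calls over the region CpGs onto ``n_cols`` columns.

    ``calls`` holds 1.0/0.0/NaN per region CpG.  With >= ``n_cols`` CpGs,
    adjacent sites are merged: column c averages the non-NaN calls in the
    contiguous bin [floor(c*k/n), floor((c+1)*k/n)).  With fewer CpGs each
    column replicates the call at CpG floor(c*k/n) (pseudo-CpG expansion).
    Columns left NaN (uncovered) inherit the nearest non-NaN column.
    """
    vals = np.asarray(calls, dtype=float)
    k = len(vals)
    if k == 0 or np.isnan(vals).all():
        raise ValueError("need >= 1 non-NA call")
    out = np.full(n_cols, np.nan)
    if k >= n_cols:
        edges = [(c * k) // n_cols for c in range(n_cols + 1)]
        for c in range(n_cols):
            seg = vals[edges[c] : edges[c + 1]]
            if not np.isnan(seg).all():
                out[c] = np.nanmean(seg)
    else:
        for c in range(n_cols):
            out[c] = vals[(c * k) // n_cols]
    # NA-only columns inherit the nearest filled column (ties -> left)
    filled = np.nonzero(~np.isnan(out))[0]
    for c in np.nonzero(np.isnan(out))[0]:
        out[c] = out[filled[np.argmin(np.abs(filled - c))]]
    return out


def _block_size(n_reads: int, n_rows: int) -> int:
    """Largest F with n_rows * F < n_reads (so n_reads - n_rows < n_rows*F)."""
    return (n_reads - 1) // n_rows


def normalize_rows(
    reads: Sequence[MethRead],
    region: GenomicInterval,
    cfg: EncoderConfig = EncoderConfig(),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a region's reads to ``cfg.n_rows`` pseudo-read rows.

    Returns ``(rows, distances)`` where ``rows`` is (n_rows, n_cols)
    methylation and ``distances`` the raw (unscaled) midpoint-to-TSS-proxy
    values, here the read midpoints (the caller subtracts the TSS).  Rows
    are sorted by methylation fraction ascending.  With fewer than
    ``n_rows`` reads, rows are bootstrapped with replacement; with more,
    ``n_rows * F`` randomly chosen reads are sorted by f_m and averaged in
    consecutive blocks of ``F``.
    """
    n_r = len(reads)
    if n_r <= cfg.min_reads:
        raise RegionSkipped(
            f"{region}: {n_r} reads <= min_reads ({cfg.min_reads})"
        )
    rng = np.random.default_rng(seed)
    matrix = build_matrix(reads, region)
    by_id = {rid: i for i, rid in enumerate(matrix.read_ids)}
    usable = [r for r in reads if r.read_id in by_id]
    cols = np.stack(
        [
            normalize_cols(matrix.data[by_id[r.read_id]], cfg.n_cols)
            for r in usable
        ]
    )
    fm = np.array([read_fraction(r) for r in usable])
    mids = np.array([r.midpoint for r in usable])
    n = len(usable)
    if n < cfg.n_rows:
        pick = rng.integers(0, n, size=cfg.n_rows)
        rows, dists, fsort = cols[pick], mids[pick], fm[pick]
    elif n == cfg.n_rows:
        rows, dists, fsort = cols, mids, fm
    else:
        f_size = _block_size(n, cfg.n_rows)
        pick = rng.choice(n, size=cfg.n_rows * f_size, replace=False)
        order = pick[np.argsort(fm[pick], kind="stable")]
        rows = cols[order].reshape(cfg.n_rows, f_size, cfg.n_cols).mean(axis=1)
        dists = mids[order].reshape(cfg.n_rows, f_size).mean(axis=1)
        fsort = fm[order].reshape(cfg.n_rows, f_size).mean(axis=1)
    final = np.argsort(fsort, kind="stable")
    return rows[final], dists[final]


def encode_region(
    reads: Sequence[MethRead],
    region: GenomicInterval,
    tss: int,
    cfg: EncoderConfig = EncoderConfig(),
    seed: int | None = None,
    region_id: str | None = None,
) -> ReadImage:
    """Encode a region's reads into the (n_rows, n_cols, 2) image."""
    rows, mids = normalize_rows(reads, region, cfg, seed)
    arr = np.empty((cfg.n_rows, cfg.n_cols, 2))
    arr[:, :, 0] = rows
    arr[:, :, 1] = ((mids - tss) / cfg.distance_scale)[:, np.newaxis]
    return ReadImage(arr, region_id if region_id is not None else str(region))


def shuffle_mcpgs(
    reads: Sequence[MethRead], seed: int | None = None
) -> list[MethRead]:
    """Disrupt clonal structure by re-assigning mCpGs across reads.

    All covered (non-NA) read-position slots are pooled; the observed total
    number of M calls is placed uniformly at random over the slots (at most
    one per slot) and every other slot becomes U.  The total mCpG count is
    conserved exactly (asserted); per-read coverage patterns are unchanged.
    """
    slots: list[tuple[int, int]] = []  # (read index, call index)
    total_m = 0
    for i, r in enumerate(reads):
        for j, (_, state) in enumerate(r.calls):
            if state != "NA":
                slots.append((i, j))
                if state == "M":
                    total_m += 1
    if total_m > len(slots):
        raise ValueError("more mCpGs than covered slots")  # impossible on valid input
    rng = np.random.default_rng(seed)
    meth_slots = set()
    if total_m:
        chosen = rng.choice(len(slots), size=total_m, replace=False)
        meth_slots = {slots[i] for i in chosen}
    out: list[MethRead] = []
    for i, r in enumerate(reads):
        calls = tuple(
            (pos, state if state == "NA" else ("M" if (i, j) in meth_slots else "U"))
            for j, (pos, state) in enumerate(r.calls)
        )
        out.append(
            MethRead(r.read_id, r.chrom, r.frag_start, r.frag_end, r.strand, calls)
        )
    assert sum(r.n_meth for r in out) == total_m
    return out
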