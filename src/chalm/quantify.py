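"""Region methylation quantification: mean, weighted and clonal (CHALM).

Three summaries of a region's bisulfite evidence:

* *mean methylation* — the average over CpG sites of per-site methylated
  fractions, ``(1/n) * sum_i C_i / (C_i + T_i)``;
* *weighted methylation* — total methylated calls over total calls,
  ``sum_i C_i / sum_i (C_i + T_i)``;
* *CHALM* — the fraction of reads carrying at least ``min_mcpg`` (default 1)
  methylated CpGs, ``n_m / (n_m + n_u)``, treating each read as one cell.

Undefined quantities (no coverage) are returned as NaN, never 0 — zero is a
meaningful methylation level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .reads import CpGCounts, MethRead, pileup
from .regions import GenomicInterval

__all__ = [
    "MethylationSummary",
    "mean_methylation",
    "weighted_methylation",
    "chalm",
    "per_cpg_chalm_transform",
]


@dataclass(frozen=True)
class MethylationSummary:
    """All three quantifications for one region."""

    region_id: str
    n_reads: int
    n_meth_reads: int
    n_unmeth_reads: int
    chalm: float
    mean_meth: float
    weighted_meth: float
    n_cpgs: int
    mean_depth: float


def mean_methylation(counts: Sequence[CpGCounts]) -> float:
    """Average of per-CpG methylated fractions; NaN on empty input."""
    ratios = [c.ratio for c in counts if c.depth > 0]
    if not ratios:
        return math.nan
    return sum(ratios) / len(ratios)


def weighted_methylation(counts: Sequence[CpGCounts]) -> float:
    """Total methylated calls over total calls; NaN on zero depth."""
    total = sum(c.depth for c in counts)
    if total == 0:
        return math.nan
    return sum(c.c_meth for c in counts) / total


def chalm(
    reads: Iterable[MethRead],
    region: GenomicInterval | None = None,
    min_mcpg: int = 1,
    region_id: str | None = None,
    min_depth: int = 4,
) -> MethylationSummary:
    """Clonal methylation summary of the reads mapped to a region.

    A read is *mapped to* the region iff it has >= 1 non-NA CpG call inside
    it (coordinate overlap alone carries no methylation evidence); it is
    *methylated* iff it carries >= ``min_mcpg`` M calls there.  The CHALM
    level is the methylated-read fraction.  ``mean_meth``/``weighted_meth``
    are computed from the per-CpG pileup of the same reads with the
    >= ``min_depth`` coverage filter; read-level counting itself is never
    depth-filtered.
    """
    if min_mcpg < 1:
        raise ValueError("min_mcpg must be >= 1")
    reads = list(reads)
    n_m = n_u = 0
    covered: list[MethRead] = []
    for r in reads:
        calls = r.calls if region is None else r.calls_in(region)
        informative = [s for _, s in calls if s != "NA"]
        if not informative:
            continue
        covered.append(r)
        if sum(1 for s in informative if s == "M") >= min_mcpg:
            n_m += 1
        else:
            n_u += 1
    counts = pileup(covered, region, min_depth=min_depth)
    n_total = n_m + n_u
    if region_id is None:
        region_id = str(region) if region is not None else "."
    return MethylationSummary(
        region_id=region_id,
        n_reads=n_total,
        n_meth_reads=n_m,
        n_unmeth_reads=n_u,
        chalm=n_m / n_total if n_total else math.nan,
        mean_meth=mean_methylation(counts),
        weighted_meth=weighted_methylation(counts),
        n_cpgs=len(counts),
        mean_depth=(
            sum(c.depth for c in counts) / len(counts) if counts else math.nan
        ),
    )


def per_cpg_chalm_transform(
    reads: Iterable[MethRead], min_depth: int = 4
) -> tuple[list[MethRead], list[CpGCounts]]:
    """Propagate clonal methylation along reads, then re-pileup.

    Every read carrying >= 1 mCpG has all its non-NA calls set to M (the
    read represents one methylated cell, so each of its CpGs is methylated
    at the cell level); NA stays NA and the covered-position pattern is
    unchanged.  The returned per-CpG ratios are the pileup of the
    transformed reads under the >= ``min_depth`` filter — a CHALM level per
    CpG site, ready for de novo DMR segmentation tools.
    """
    transformed: list[MethRead] = []
    for r in reads:
        if any(s == "M" for _, s in r.calls):
            calls = tuple(
                (p, "M" if s != "NA" else "NA") for p, s in r.calls
            )
            r = MethRead(
                r.read_id, r.chrom, r.frag_start, r.frag_end, r.strand, calls
            )
        transformed.append(r)
    return transformed, pileup(transformed, min_depth=min_depth)
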