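"""Beta-binomial empirical-Bayes differential clonal methylation.

For region *i* the methylated-read count is modelled as
``n_mi ~ Binomial(n_mi + n_ui, p_i)`` with ``p_i ~ Beta(alpha, beta)``;
the Beta prior is fitted across regions by an empirical-Bayes method of
moments, per condition.  The differential statistic is the posterior
distribution of ``d = p2 - p1`` (posteriors are conjugate Betas), computed
by numerical convolution on a uniform grid; the reported p-value is the
two-sided posterior tail ``2 * min(P(d <= 0), P(d >= 0))``.  Significance
combines an effect-size gate with Benjamini-Hochberg FDR control
(|delta| >= 0.1 and q < 0.05 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaBinomPrior",
    "RegionDiffInput",
    "DiffResult",
    "fit_prior",
    "diff_region",
    "adjust_and_call",
    "export_metilene",
    "read_metilene",
]


@dataclass(frozen=True)
class BetaBinomPrior:
    """Beta(alpha, beta) prior on a region's methylated-read probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.alpha)
            and math.isfinite(self.beta)
            and self.alpha > 0
            and self.beta > 0
        ):
            raise ValueError("alpha and beta must be finite and positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


#: Flat fallback prior used when the moment estimate is degenerate.
UNIFORM_PRIOR = BetaBinomPrior(1.0, 1.0)


@dataclass(frozen=True)
class RegionDiffInput:
    """Methylated/unmethylated read counts for one region, two conditions."""

    region_id: str
    cond1: tuple[int, int]  # (n_meth_reads, n_unmeth_reads)
    cond2: tuple[int, int]

    def __post_init__(self) -> None:
        for n_m, n_u in (self.cond1, self.cond2):
            if n_m < 0 or n_u < 0:
                raise ValueError("read counts must be >= 0")


@dataclass(frozen=True)
class DiffResult:
    region_id: str
    chalm1: float
    chalm2: float
    delta: float  # posterior-mean difference, condition2 - condition1
    p_value: float
    q_value: float = math.nan
    significant: bool = False


def fit_prior(
    counts: Sequence[tuple[int, int]], min_regions: int = 10
) -> BetaBinomPrior:
    """Empirical-Bayes method-of-moments fit of the Beta prior.

    ``counts`` are per-region ``(n_meth_reads, n_unmeth_reads)`` pairs for
    one condition.  The across-region variance of observed ratios is
    decomposed into binomial sampling noise plus prior variance; if the
    observed variance does not exceed the binomial floor the flat
    Beta(1, 1) prior is returned.
    """
    arr = np.asarray(counts, dtype=float)
    totals = arr.sum(axis=1)
    usable = totals > 0
    if int(usable.sum()) < min_regions:
        raise ValueError(
            f"need >= {min_regions} regions with nonzero counts to fit a "
            "prior; supply an explicit BetaBinomPrior instead"
        )
    n = totals[usable]
    r = arr[usable, 0] / n
    # depth-weighted moments of the ratio distribution
    w = n / n.sum()
    m = float((w * r).sum())
    v = float((w * (r - m) ** 2).sum())
    if m <= 0.0 or m >= 1.0:
        return UNIFORM_PRIOR
    # Var(r_i) = m(1-m) [ rho + (1 - rho)/n_i ], rho = 1/(alpha+beta+1)
    inv_n = float((w / n).sum())
    denom = m * (1.0 - m) * (1.0 - inv_n)
    if denom <= 0:
        return UNIFORM_PRIOR
    rho = (v - m * (1.0 - m) * inv_n) / denom
    if not (0.0 < rho < 1.0):
        return UNIFORM_PRIOR
    s = 1.0 / rho - 1.0  # alpha + beta
    return BetaBinomPrior(m * s, (1.0 - m) * s)


def _posterior_pmf(
    n_m: int, n_u: int, prior: BetaBinomPrior, grid: np.ndarray
) -> np.ndarray:
    """Discretized Beta(alpha + n_m, beta + n_u) posterior on grid midpoints."""
    pdf = stats.beta.pdf(grid, prior.alpha + n_m, prior.beta + n_u)
    total = pdf.sum()
    if not np.isfinite(total) or total <= 0:
        # extremely peaked posterior: put mass at the nearest grid point
        mode = (prior.alpha + n_m - 1) / max(
            prior.alpha + n_m + prior.beta + n_u - 2, 1e-12
        )
        pdf = np.zeros_like(grid)
        pdf[int(np.clip(np.searchsorted(grid, mode), 0, len(grid) - 1))] = 1.0
        return pdf
    return pdf / total


def diff_region(
    inp: RegionDiffInput,
    prior1: BetaBinomPrior = UNIFORM_PRIOR,
    prior2: BetaBinomPrior = UNIFORM_PRIOR,
    grid_size: int = 512,
) -> DiffResult:
    """Posterior-difference test for one region (q-value left unset).

    The posterior of each condition's methylated-read probability is the
    conjugate Beta; the distribution of ``d = p2 - p1`` is obtained by
    convolving the two discretized posteriors.  ``p_value`` is the
    two-sided tail at 0, clipped to ``[1/grid_size**2, 1]`` so downstream
    BH adjustment is well defined.
    """
    (m1, u1), (m2, u2) = inp.cond1, inp.cond2
    if m1 + u1 == 0 or m2 + u2 == 0:
        raise ValueError(
            f"region {inp.region_id}: both conditions need > 0 reads"
        )
    grid = (np.arange(grid_size) + 0.5) / grid_size
    w1 = _posterior_pmf(m1, u1, prior1, grid)
    w2 = _posterior_pmf(m2, u2, prior2, grid)
    # pmf of d = p2 - p1 on the lattice k/grid_size, k = -(G-1)..(G-1)
    diff_pmf = np.convolve(w2, w1[::-1])
    center = grid_size - 1  # index of d == 0
    p_low = diff_pmf[:center].sum() + 0.5 * diff_pmf[center]
    p_high = diff_pmf[center + 1 :].sum() + 0.5 * diff_pmf[center]
    p = 2.0 * min(p_low, p_high)
    p = float(np.clip(p, 1.0 / grid_size**2, 1.0))
    mean1 = (prior1.alpha + m1) / (prior1.alpha + prior1.beta + m1 + u1)
    mean2 = (prior2.alpha + m2) / (prior2.alpha + prior2.beta + m2 + u2)
    return DiffResult(
        region_id=inp.region_id,
        chalm1=m1 / (m1 + u1),
        chalm2=m2 / (m2 + u2),
        delta=mean2 - mean1,
        p_value=p,
    )


def adjust_and_call(
    results: Iterable[DiffResult],
    delta_min: float = 0.1,
    q_max: float = 0.05,
) -> list[DiffResult]:
    """Benjamini-Hochberg adjustment and significance flags.

    A region is significant iff |delta| >= ``delta_min`` and its BH
    q-value is < ``q_max``.
    """
    results = list(results)
    if not results:
        return []
    p = np.array([r.p_value for r in results])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [
        replace(
            r,
            q_value=float(qv),
            significant=bool(abs(r.delta) >= delta_min and qv < q_max),
        )
        for r, qv in zip(results, q)
    ]


# ---------------------------------------------------------------------------
# Metilene export (de novo DMR mode feeds an external segmentation tool)
# ---------------------------------------------------------------------------

def export_metilene(
    path: str | Path,
    chrom: str,
    group1: Sequence[Mapping[int, float]],
    group2: Sequence[Mapping[int, float]],
    group_names: tuple[str, str] = ("g1", "g2"),
) -> None:
    """Write per-CpG ratios of two replicate groups in Metilene's dialect.

    Each group is a sequence of replicate mappings ``{cpg_pos: ratio}``
    (typically CHALM-transformed, depth-filtered ratios).  Output columns:
    ``chrom  pos  <g1_1..>  <g2_1..>`` with missing values as ``"."``;
    positions are the sorted union over all replicates.
    """
    positions = sorted(
        {p for rep in (*group1, *group2) for p in rep}
    )
    header = ["chrom", "pos"]
    header += [f"{group_names[0]}_{i + 1}" for i in range(len(group1))]
    header += [f"{group_names[1]}_{i + 1}" for i in range(len(group2))]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for pos in positions:
            row = [chrom, str(pos)]
            for rep in (*group1, *group2):
                v = rep.get(pos)
                row.append("." if v is None else f"{v:.6g}")
            fh.write("\t".join(row) + "\n")


def read_metilene(
    path: str | Path,
) -> tuple[str, list[dict[int, float]], list[str]]:
    """Parse a Metilene-dialect table back into per-replicate mappings.

    Returns ``(chrom, replicate_columns, column_names)``; raises on
    unsorted positions.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[2:]
        reps: list[dict[int, float]] = [{} for _ in names]
        chrom = ""
        prev = None
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom = fields[0]
            pos = int(fields[1])
            if prev is not None and pos <= prev:
                raise ValueError(f"{path}: positions not sorted at {pos}")
            prev = pos
            for rep, val in zip(reps, fields[2:]):
                if val != ".":
                    rep[pos] = float(val)
    return chrom, reps, names
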