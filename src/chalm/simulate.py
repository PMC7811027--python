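"""Synthetic bulk bisulfite reads with explicit clonal (epiallele) structure.

Each simulated region is a mixture of *clones* — per-cell methylation
programs defined by per-CpG Bernoulli probabilities.  A read is one cell's
fragment: its clone is drawn by mixture weight, its start uniformly over
the region, and each covered CpG is called M with the clone's probability
at that site.  This expresses both textbook idealizations (a fraction of
fully methylated cells among fully unmethylated ones; every cell carrying
a single dispersed mCpG) and noisier, more realistic mixtures.  Ground
truth (clone labels, the methylated-clone fraction, per-CpG marginals)
travels alongside the reads so recovery can be tested exactly.

The number of reads per region is Poisson with mean
``depth * region_length / read_length`` so that ``depth`` is the expected
per-CpG coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reads import MethRead
from .regions import GenomicInterval

__all__ = [
    "CloneSpec",
    "EpialleleModel",
    "SimTruth",
    "simulate_reads",
    "simulate_pair",
    "simulate_expression",
    "simulate_clonal_cohort",
    "ClonalCohort",
]


@dataclass(frozen=True)
class CloneSpec:
    """One epiallele: mixture weight and per-CpG methylation probabilities.

    ``is_methylated`` marks the clone as a "methylated cell" for ground-
    truth purposes; by default a clone is methylated iff all its per-CpG
    probabilities are 1 (a fully, deterministically methylated program).
    """

    weight: float
    probs: tuple[float, ...]
    is_methylated: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.probs):
            raise ValueError("probabilities must be in [0, 1]")

    @property
    def methylated(self) -> bool:
        if self.is_methylated is not None:
            return self.is_methylated
        return bool(self.probs) and all(p == 1.0 for p in self.probs)


@dataclass(frozen=True)
class EpialleleModel:
    """A region's clonal mixture and sequencing parameters.

    ``depth`` is the mean read coverage per CpG; the realized read count is
    Poisson.  ``read_length`` fragments start uniformly over the region.
    """

    region: GenomicInterval
    cpg_positions: tuple[int, ...]
    clones: tuple[CloneSpec, ...]
    read_length: int
    depth: float

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone weights must sum to 1 (got {total})")
        if any(len(c.probs) != len(self.cpg_positions) for c in self.clones):
            raise ValueError("each clone needs one probability per CpG")
        if self.read_length > len(self.region):
            raise ValueError("read_length exceeds region length")
        for p in self.cpg_positions:
            if not self.region.contains(p):
                raise ValueError(f"CpG {p} outside region {self.region}")

    @property
    def methylated_clone_fraction(self) -> float:
        """Total weight of clones marked as methylated cells."""
        return sum(c.weight for c in self.clones if c.methylated)

    @property
    def per_cpg_marginal(self) -> np.ndarray:
        """Clone-weighted expected methylation per CpG."""
        w = np.array([c.weight for c in self.clones])
        p = np.array([c.probs for c in self.clones])
        return w @ p

    def p_any_mcpg_full_span(self) -> float:
        """P(a full-span read carries >= 1 mCpG) — the closed-form clonal
        methylation level when reads cover every CpG."""
        w = np.array([c.weight for c in self.clones])
        p = np.array([c.probs for c in self.clones])
        return float(np.sum(w * (1.0 - np.prod(1.0 - p, axis=1))))


@dataclass
class SimTruth:
    """Exact generating quantities for one simulated region."""

    clone_labels: np.ndarray
    methylated_clone_fraction: float
    per_cpg_marginal: np.ndarray
    clone_weights: tuple[float, ...] = field(default_factory=tuple)


def simulate_reads(
    model: EpialleleModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_reads: int | None = None,
) -> tuple[list[MethRead], SimTruth]:
    """Draw one region's reads (and ground truth) from the clonal mixture."""
    if rng is None:
        rng = np.random.default_rng(seed)
    region = model.region
    if n_reads is None:
        lam = model.depth * len(region) / model.read_length
        n_reads = int(rng.poisson(lam))
    weights = np.array([c.weight for c in model.clones])
    labels = rng.choice(len(model.clones), size=n_reads, p=weights)
    cpgs = np.asarray(model.cpg_positions)
    reads: list[MethRead] = []
    for i in range(n_reads):
        start = int(
            rng.integers(region.start, region.end - model.read_length + 1)
        )
        end = start + model.read_length
        covered = cpgs[(cpgs >= start) & (cpgs < end)]
        probs = np.asarray(model.clones[labels[i]].probs)[
            np.isin(cpgs, covered)
        ]
        meth = rng.random(len(covered)) < probs
        reads.append(
            MethRead(
                f"sim{i}",
                region.chrom,
                start,
                end,
                "+",
                tuple(
                    (int(p), "M" if m else "U") for p, m in zip(covered, meth)
                ),
            )
        )
    truth = SimTruth(
        clone_labels=labels,
        methylated_clone_fraction=model.methylated_clone_fraction,
        per_cpg_marginal=model.per_cpg_marginal,
        clone_weights=tuple(c.weight for c in model.clones),
    )
    return reads, truth


def simulate_pair(
    model1: EpialleleModel,
    model2: EpialleleModel,
    n_regions: int,
    seed: int | None = None,
) -> tuple[list[list[MethRead]], list[list[MethRead]], list[float]]:
    """Independent two-condition read sets over replicate regions.

    Returns ``(reads_cond1, reads_cond2, truth_deltas)`` where the truth
    delta is the difference of methylated-clone fractions (condition 2
    minus condition 1) — zero for every region when the models coincide.
    """
    rng = np.random.default_rng(seed)
    reads1, reads2, deltas = [], [], []
    for _ in range(n_regions):
        r1, t1 = simulate_reads(model1, rng=rng)
        r2, t2 = simulate_reads(model2, rng=rng)
        reads1.append(r1)
        reads2.append(r2)
        deltas.append(
            t2.methylated_clone_fraction - t1.methylated_clone_fraction
        )
    return reads1, reads2, deltas


def simulate_expression(
    truths: Sequence[SimTruth],
    slope: float = 1.0,
    noise_sd: float = 0.1,
    intercept: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Expression driven by the unmethylated-cell fraction plus noise:
    ``y = intercept + slope * (1 - methylated_clone_fraction) + N(0, sd)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    frac = np.array([t.methylated_clone_fraction for t in truths])
    return intercept + slope * (1.0 - frac) + rng.normal(0.0, noise_sd, len(frac))


# ---------------------------------------------------------------------------
# study-condition cohort: clustered epialleles at matched mean methylation
# ---------------------------------------------------------------------------

@dataclass
class ClonalCohort:
    """A battery of simulated regions with clustered epialleles."""

    regions: list[GenomicInterval]
    tss: list[int]
    reads: list[list[MethRead]]
    truths: list[SimTruth]
    expression: np.ndarray


def simulate_clonal_cohort(
    n_regions: int = 500,
    n_cpgs: int = 10,
    depth: float = 80.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> ClonalCohort:
    """Regions where clonal structure, not mean methylation, drives expression.

    Each region mixes a fully methylated clone (weight theta ~ U(0.05, 0.5),
    the repressed-cell fraction) with a background clone carrying dispersed
    mCpGs at a per-CpG rate chosen so every region's expected mean
    methylation sits near 0.55 (jittered U(0.5, 0.6)).  Mean-level
    quantification therefore barely separates regions, while the fraction
    of fully methylated reads tracks theta — the mixture the clonal
    quantification and the read-image model are designed to resolve.
    Reads span the whole region; expression is
    ``y = 1 - theta + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(seed)
    spacing = 20
    region_len = n_cpgs * spacing
    cohort = ClonalCohort([], [], [], [], np.empty(0))
    for i in range(n_regions):
        start = 10_000 + i * (region_len + 1000)
        region = GenomicInterval("chrSim", start, start + region_len)
        cpgs = tuple(start + spacing // 2 + spacing * j for j in range(n_cpgs))
        theta = float(rng.uniform(0.05, 0.5))
        target_mean = float(rng.uniform(0.5, 0.6))
        background = (target_mean - theta) / (1.0 - theta)
        model = EpialleleModel(
            region=region,
            cpg_positions=cpgs,
            clones=(
                CloneSpec(theta, (1.0,) * n_cpgs),
                CloneSpec(
                    1.0 - theta, (background,) * n_cpgs, is_methylated=False
                ),
            ),
            read_length=region_len,
            depth=depth,
        )
        reads, truth = simulate_reads(model, rng=rng)
        cohort.regions.append(region)
        cohort.tss.append(start + int(rng.integers(-400, 400)))
        cohort.reads.append(reads)
        cohort.truths.append(truth)
    cohort.expression = simulate_expression(
        cohort.truths,
        slope=1.0,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    return cohort
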