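"""Per-read CpG methylation calls: parsing, mate merging, pileup, matrices.

A :class:`MethRead` is one sequenced fragment's ordered CpG calls and is the
unit of clonal evidence: each read stands in for a single cell of the
sequenced bulk.  Calls are ``'M'`` (methylated), ``'U'`` (unmethylated) or
``'NA'`` (covered but uninformative, e.g. a mate-pair disagreement).

Two input routes are supported: SAM/BAM with Bismark-style ``XM`` call
strings (via pysam), and a canonical tab-separated text dialect

    read_id  chrom  frag_start  frag_end  strand  pos:state[,pos:state...]

that makes every test and small experiment self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .regions import GenomicInterval

__all__ = [
    "MethRead",
    "CpGCounts",
    "RegionReadMatrix",
    "ReadFormatError",
    "parse_reads_tsv",
    "parse_reads_sam",
    "write_reads_tsv",
    "merge_mates",
    "pileup",
    "build_matrix",
    "write_bedgraph",
    "read_bedgraph",
]

VALID_STATES = ("M", "U", "NA")


class ReadFormatError(ValueError):
    """Input reads are malformed or missing required methylation calls."""


@dataclass(frozen=True)
class MethRead:
    """One fragment's ordered CpG methylation calls.

    ``calls`` is a tuple of ``(cpg_pos, state)`` with strictly increasing
    positions inside ``[frag_start, frag_end)``.
    """

    read_id: str
    chrom: str
    frag_start: int
    frag_end: int
    strand: str = "."
    calls: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.frag_start >= self.frag_end:
            raise ValueError("frag_start must be < frag_end")
        prev = None
        for pos, state in self.calls:
            if state not in VALID_STATES:
                raise ValueError(f"invalid call state {state!r}")
            if prev is not None and pos <= prev:
                raise ValueError(
                    f"CpG positions must be strictly increasing (read "
                    f"{self.read_id}: {pos} after {prev})"
                )
            if not self.frag_start <= pos < self.frag_end:
                raise ValueError(
                    f"call position {pos} outside fragment "
                    f"[{self.frag_start},{self.frag_end}) of {self.read_id}"
                )
            prev = pos

    @property
    def n_meth(self) -> int:
        """Number of methylated CpG calls (N_m)."""
        return sum(1 for _, s in self.calls if s == "M")

    @property
    def n_unmeth(self) -> int:
        """Number of unmethylated CpG calls (N_u)."""
        return sum(1 for _, s in self.calls if s == "U")

    @property
    def midpoint(self) -> float:
        return (self.frag_start + self.frag_end) / 2.0

    def calls_in(self, region: GenomicInterval) -> tuple[tuple[int, str], ...]:
        """Calls whose positions fall inside ``region`` (half-open)."""
        if region.chrom != self.chrom:
            return ()
        return tuple(
            (p, s) for p, s in self.calls if region.start <= p < region.end
        )


@dataclass(frozen=True)
class CpGCounts:
    """Methylated / unmethylated read counts at one CpG (C_i, T_i)."""

    cpg_pos: int
    c_meth: int
    c_unmeth: int

    def __post_init__(self) -> None:
        if self.c_meth < 0 or self.c_unmeth < 0:
            raise ValueError("counts must be >= 0")

    @property
    def depth(self) -> int:
        return self.c_meth + self.c_unmeth

    @property
    def ratio(self) -> float:
        return self.c_meth / self.depth if self.depth else float("nan")


@dataclass
class RegionReadMatrix:
    """Reads x CpGs methylation matrix for one region.

    ``data`` holds 1.0 (M), 0.0 (U) or NaN (read does not cover / NA call);
    columns follow genomic CpG order.
    """

    region: GenomicInterval
    cpg_positions: np.ndarray  # shape (n_cpgs,), int
    data: np.ndarray  # shape (n_reads, n_cpgs), float with NaN
    read_ids: list[str]

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.read_ids), len(self.cpg_positions)):
            raise ValueError("matrix shape inconsistent with labels")

    @property
    def n_reads(self) -> int:
        return self.data.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# canonical TSV dialect
# ---------------------------------------------------------------------------

def _parse_call_field(text: str, read_id: str) -> tuple[tuple[int, str], ...]:
    if not text or text == ".":
        return ()
    calls = []
    for item in text.split(","):
        pos_s, _, state = item.partition(":")
        calls.append((int(pos_s), state))
    for (p1, _), (p2, _) in zip(calls, calls[1:]):
        if p2 <= p1:
            raise ReadFormatError(
                f"read {read_id}: call positions not strictly increasing"
            )
    return tuple(calls)


def parse_reads_tsv(path: str | Path) -> Iterator[MethRead]:
    """Stream reads from the canonical TSV dialect."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ReadFormatError(f"{path}:{lineno}: expected 6 columns")
            read_id, chrom, start_s, end_s, strand, call_s = fields[:6]
            try:
                yield MethRead(
                    read_id,
                    chrom,
                    int(start_s),
                    int(end_s),
                    strand,
                    _parse_call_field(call_s, read_id),
                )
            except ValueError as exc:
                raise ReadFormatError(f"{path}:{lineno}: {exc}") from exc


def write_reads_tsv(reads: Iterable[MethRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            call_s = ",".join(f"{p}:{s}" for p, s in r.calls) or "."
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.frag_start}\t{r.frag_end}\t"
                f"{r.strand}\t{call_s}\n"
            )


# ---------------------------------------------------------------------------
# SAM/BAM route (Bismark-style XM tag)
# ---------------------------------------------------------------------------

def parse_reads_sam(
    path: str | Path,
    cpg_reference: Mapping[str, Sequence[int]] | None = None,
) -> Iterator[MethRead]:
    """Stream reads from SAM/BAM carrying per-base methylation calls.

    The alignment must carry a Bismark-style ``XM`` tag ('Z' = methylated
    CpG, 'z' = unmethylated CpG at the read base).  Calls from reads aligned
    to the G strand (``XG == 'GA'``) are collapsed onto the C-strand CpG
    coordinate (position - 1) so both strands report the same CpG unit.
    With ``cpg_reference`` (sorted CpG positions per chromosome), calls at
    positions absent from the reference are kept as NA with a warning.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.has_tag("XM"):
                raise ReadFormatError(
                    f"alignment {aln.query_name} lacks an XM methylation tag"
                )
            xm = aln.get_tag("XM")
            g_strand = aln.has_tag("XG") and aln.get_tag("XG") == "GA"
            calls: dict[int, str] = {}
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                code = xm[qpos]
                if code not in "zZ":
                    continue
                cpg = rpos - 1 if g_strand else rpos
                state = "M" if code == "Z" else "U"
                if cpg_reference is not None:
                    ref = cpg_reference.get(aln.reference_name, ())
                    i = int(np.searchsorted(ref, cpg))
                    if i >= len(ref) or ref[i] != cpg:
                        warnings.warn(
                            f"CpG {aln.reference_name}:{cpg} not in reference; "
                            "recorded as NA",
                            stacklevel=2,
                        )
                        state = "NA"
                calls[cpg] = state
            start = aln.reference_start
            end = max(aln.reference_end, max(calls, default=0) + 1)
            yield MethRead(
                aln.query_name,
                aln.reference_name,
                start,
                end,
                "-" if aln.is_reverse else "+",
                tuple(sorted(calls.items())),
            )


# ---------------------------------------------------------------------------
# fragment merging and pileup
# ---------------------------------------------------------------------------

def merge_mates(reads: Iterable[MethRead]) -> list[MethRead]:
    """Merge paired alignments sharing a read_id into single fragments.

    Overlapping CpGs with agreeing calls are kept once; disagreements become
    NA (conservative, symmetric).  Singletons pass through unchanged.
    """
    groups: dict[str, list[MethRead]] = {}
    order: list[str] = []
    for r in reads:
        if r.read_id not in groups:
            order.append(r.read_id)
        groups.setdefault(r.read_id, []).append(r)
    out: list[MethRead] = []
    for rid in order:
        mates = groups[rid]
        if len(mates) == 1:
            out.append(mates[0])
            continue
        if len(mates) > 2:
            raise ReadFormatError(
                f"read {rid}: {len(mates)} alignments; expected <= 2"
            )
        a, b = mates
        if a.chrom != b.chrom:
            raise ReadFormatError(f"read {rid}: mates on different chromosomes")
        merged: dict[int, str] = dict(a.calls)
        for pos, state in b.calls:
            if pos in merged and merged[pos] != state:
                merged[pos] = "NA"
            else:
                merged.setdefault(pos, state)
        out.append(
            MethRead(
                rid,
                a.chrom,
                min(a.frag_start, b.frag_start),
                max(a.frag_end, b.frag_end),
                a.strand,
                tuple(sorted(merged.items())),
            )
        )
    return out


def pileup(
    reads: Iterable[MethRead],
    region: GenomicInterval | None = None,
    min_depth: int = 4,
) -> list[CpGCounts]:
    """Per-CpG methylated/unmethylated counts, depth-filtered.

    Only CpGs with total depth >= ``min_depth`` are returned (the standard
    >= 4-read coverage filter by default).  NA calls count toward neither
    methylated nor unmethylated depth.
    """
    meth: dict[int, int] = {}
    unmeth: dict[int, int] = {}
    for r in reads:
        calls = r.calls if region is None else r.calls_in(region)
        for pos, state in calls:
            if state == "M":
                meth[pos] = meth.get(pos, 0) + 1
                unmeth.setdefault(pos, 0)
            elif state == "U":
                unmeth[pos] = unmeth.get(pos, 0) + 1
                meth.setdefault(pos, 0)
    out = [
        CpGCounts(pos, meth[pos], unmeth[pos])
        for pos in sorted(meth)
        if meth[pos] + unmeth[pos] >= min_depth
    ]
    return out


def build_matrix(
    reads: Iterable[MethRead], region: GenomicInterval
) -> RegionReadMatrix:
    """Reads x CpGs matrix over the region's observed CpG positions.

    Reads contributing no non-NA call inside the region are excluded;
    raises :class:`ReadFormatError` if no read qualifies.
    """
    kept: list[MethRead] = []
    positions: set[int] = set()
    for r in reads:
        calls = r.calls_in(region)
        if any(s != "NA" for _, s in calls):
            kept.append(r)
            positions.update(p for p, _ in calls)
    if not kept:
        raise ReadFormatError(f"no reads with CpG calls overlap {region}")
    cpg_positions = np.array(sorted(positions), dtype=np.int64)
    index = {int(p): j for j, p in enumerate(cpg_positions)}
    data = np.full((len(kept), len(cpg_positions)), np.nan)
    for i, r in enumerate(kept):
        for pos, state in r.calls_in(region):
            if state == "M":
                data[i, index[pos]] = 1.0
            elif state == "U":
                data[i, index[pos]] = 0.0
    return RegionReadMatrix(region, cpg_positions, data, [r.read_id for r in kept])


# ---------------------------------------------------------------------------
# bedGraph-like per-CpG ratio table
# ---------------------------------------------------------------------------

def write_bedgraph(
    counts: Iterable[CpGCounts], chrom: str, path: str | Path
) -> None:
    """Write per-CpG ratios as ``chrom start end ratio c_meth c_total``."""
    with open(path, "w") as fh:
        for c in counts:
            fh.write(
                f"{chrom}\t{c.cpg_pos}\t{c.cpg_pos + 1}\t{c.ratio:.6g}\t"
                f"{c.c_meth}\t{c.depth}\n"
            )


def read_bedgraph(path: str | Path) -> dict[str, list[CpGCounts]]:
    """Inverse of :func:`write_bedgraph`, grouped by chromosome."""
    out: dict[str, list[CpGCounts]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, _end, _ratio, c_meth, c_total = line.split("\t")[:6]
            c_m = int(c_meth)
            out.setdefault(chrom, []).append(
                CpGCounts(int(start), c_m, int(c_total) - c_m)
            )
    return out
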