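"""Genomic interval model, annotation parsing and promoter-CGI derivation.

All coordinates are 0-based half-open (BED convention) internally.  GTF
records (1-based, closed) are converted on read.  A *promoter CGI* is a CpG
island that overlaps a 2-kb window centered on a transcription start site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PromoterCGI",
    "BedParseError",
    "AnnotationFormatError",
    "load_intervals",
    "write_intervals",
    "load_genes",
    "derive_promoter_cgis",
    "nearest_gene",
]


class BedParseError(ValueError):
    """A BED line could not be parsed or failed validation."""


class AnnotationFormatError(ValueError):
    """A gene-annotation file is in an unrecognized or inconsistent dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A transcript-level gene model reduced to its TSS.

    For minus-strand transcripts the TSS is the annotated transcript end
    minus one (last covered base in 0-based coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class PromoterCGI:
    """A CpG island overlapping >= 1 promoter window, with its genes."""

    interval: GenomicInterval
    gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("a PromoterCGI must be associated with >= 1 gene")


def load_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals sorted by (chrom, start).

    Column 6, if present, is taken as the strand.  Raises
    :class:`BedParseError` naming the offending line on malformed input.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED (BED4 when ``names`` is given)."""
    names_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names_list is not None:
                cols.append(names_list[i])
            fh.write("\t".join(cols) + "\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(attr))


def _load_genes_gtf(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: GTF requires 9 columns"
                )
            feature = fields[2]
            if feature not in {"transcript", "mRNA"}:
                continue
            strand = fields[6]
            if strand not in {"+", "-"}:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: transcript record missing strand"
                )
            start1, end1 = int(fields[3]), int(fields[4])  # 1-based closed
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id") or attrs.get("transcript_id")
            if gene_id is None:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: no gene_id/transcript_id attribute"
                )
            tss = start1 - 1 if strand == "+" else end1 - 1
            genes.append(GeneModel(gene_id, fields[0], strand, tss))
    return genes


def _load_genes_refflat(path: str | Path) -> list[GeneModel]:
    # refFlat: geneName  name  chrom  strand  txStart  txEnd  ...
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: refFlat requires >= 6 columns"
                )
            gene_id, _name, chrom, strand = fields[:4]
            if strand not in {"+", "-"}:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: record missing strand"
                )
            tx_start, tx_end = int(fields[4]), int(fields[5])  # already 0-based
            tss = tx_start if strand == "+" else tx_end - 1
            genes.append(GeneModel(gene_id, chrom, strand, tss))
    return genes


def load_genes(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Load transcript TSSs from a GTF or refFlat-style TSV.

    ``dialect`` is ``'gtf'`` or ``'refflat'``; by default it is inferred
    from the file extension (``.gtf``/``.gff`` -> GTF, otherwise refFlat).
    """
    if dialect is None:
        suffix = Path(path).suffix.lower()
        dialect = "gtf" if suffix in {".gtf", ".gff", ".gff3"} else "refflat"
    if dialect == "gtf":
        return _load_genes_gtf(path)
    if dialect == "refflat":
        return _load_genes_refflat(path)
    raise AnnotationFormatError(f"unknown annotation dialect {dialect!r}")


def derive_promoter_cgis(
    genes: Sequence[GeneModel],
    cgis: Sequence[GenomicInterval],
    window_half: int = 1000,
) -> list[PromoterCGI]:
    """CpG islands overlapping a promoter window around any TSS.

    A CGI is kept iff it shares >= 1 base with ``[tss - window_half,
    tss + window_half)`` for at least one gene; the result lists every such
    gene per CGI.  Output order follows (chrom, start) of the CGIs; it does
    not depend on input ordering.
    """
    out: list[PromoterCGI] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for cgi in sorted(set(cgis), key=lambda iv: (iv.chrom, iv.start, iv.end)):
        hits = {
            g.gene_id
            for g in by_chrom.get(cgi.chrom, ())
            if cgi.start < g.tss + window_half and g.tss - window_half < cgi.end
        }
        if hits:
            out.append(PromoterCGI(cgi, frozenset(hits)))
    return out


def nearest_gene(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> GeneModel | None:
    """The gene with TSS nearest to the interval midpoint (same chromosome).

    A convenience join for annotating DMRs; no statistics attached.
    """
    mid = (interval.start + interval.end) // 2
    candidates = [g for g in genes if g.chrom == interval.chrom]
    if not candidates:
        return None
    return min(candidates, key=lambda g: (abs(g.tss - mid), g.gene_id))
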