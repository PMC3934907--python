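"""Gene-annotation I/O and positional indexes.

All coordinates are 0-based half-open internally.  GFF3/GTF use 1-based
inclusive spans, so conversion happens exactly once, at the parsing
boundary; BED input is already 0-based half-open and is passed through.

A gene's transcription start site (TSS) is the 5' end of its span:
``start`` on the plus strand, ``end - 1`` (the last covered base) on the
minus strand.  Gene extent is the annotated gene-feature span including
UTRs and introns; isoform-level TSSs are not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-"})

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "TSSIndex",
    "AnnotationError",
    "AnnotationParseError",
    "read_gene_annotation",
    "write_gene_annotation",
    "tss_of",
    "build_tss_index",
]


class AnnotationError(ValueError):
    """Invalid annotation content (duplicate ids, bad coordinates, ...)."""


class AnnotationParseError(AnnotationError):
    """A line of an annotation file could not be parsed."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class GeneRecord:
    """A gene span with strand; the reference frame for peak assignment."""

    gene_id: str
    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self):
        if self.start < 0:
            raise AnnotationError(f"gene {self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def tss_of(gene: GeneRecord) -> int:
    """TSS position of a gene: ``start`` for +, ``end - 1`` for -."""
    return gene.start if gene.strand == "+" else gene.end - 1


@dataclass
class GenomeAnnotation:
    """A collection of genes with unique ids, optionally with chromosome sizes."""

    genes: list[GeneRecord]
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        if self.chrom_sizes is not None:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is not None and g.end > size:
                    raise AnnotationError(
                        f"gene {g.gene_id} extends past end of {g.chrom} "
                        f"({g.end} > {size})"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _attr_first(attrs, *keys) -> str | None:
    for key in keys:
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return None


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return "gff3"
    if suffix == ".gtf":
        return "gtf"
    if suffix == ".bed":
        return "bed"
    raise AnnotationError(
        f"cannot infer annotation format from {path.name!r}; pass format= explicitly"
    )


def read_gene_annotation(path, format: str | None = None) -> GenomeAnnotation:
    """Read gene spans from GFF3, GTF, or BED6.

    Only ``gene`` features are used from GFF3/GTF; their 1-based inclusive
    coordinates are converted to 0-based half-open.  ``##sequence-region``
    directives populate ``chrom_sizes``.  Duplicate gene ids and unknown
    strand symbols are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in {"gff3", "gtf"}:
        genes, sizes = _read_gff_like(path, fmt)
    elif fmt == "bed":
        genes, sizes = _read_bed(path), None
    else:
        raise AnnotationError(f"unknown annotation format {fmt!r}")
    if not genes:
        raise AnnotationError(f"{path}: no gene records found")
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def _read_gff_like(path: Path, fmt: str):
    genes: list[GeneRecord] = []
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    path, lineno, f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationParseError(path, lineno, str(exc)) from exc
            if feature.featuretype != "gene":
                continue
            if feature.strand not in VALID_STRANDS:
                raise AnnotationParseError(
                    path, lineno, f"unknown strand symbol {feature.strand!r}"
                )
            attrs = feature.attributes
            gene_id = _attr_first(attrs, "ID", "gene_id")
            if gene_id is None:
                raise AnnotationParseError(
                    path, lineno, "gene feature lacks ID/gene_id attribute"
                )
            name = _attr_first(attrs, "Name", "gene_name", "name") or gene_id
            try:
                record = GeneRecord(
                    gene_id=gene_id,
                    name=name,
                    chrom=feature.seqid,
                    start=feature.start - 1,  # 1-based inclusive -> 0-based
                    end=feature.end,
                    strand=feature.strand,
                )
            except AnnotationError as exc:
                raise AnnotationParseError(path, lineno, str(exc)) from exc
            genes.append(record)
    return genes, (sizes or None)


def _read_bed(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    path, lineno, f"BED6 needs >= 6 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationParseError(
                    path, lineno, f"non-integer coordinate: {exc}"
                ) from exc
            try:
                record = GeneRecord(
                    gene_id=fields[3],
                    name=fields[3],
                    chrom=fields[0],
                    start=start,
                    end=end,
                    strand=fields[5],
                )
            except AnnotationError as exc:
                raise AnnotationParseError(path, lineno, str(exc)) from exc
            genes.append(record)
    return genes


def write_gene_annotation(annotation: GenomeAnnotation, path, format: str = "bed") -> None:
    """Write gene spans to BED6 or GFF3 (inverse of :func:`read_gene_annotation`)."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "bed":
            for g in annotation.genes:
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
                )
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            if annotation.chrom_sizes:
                for chrom in sorted(annotation.chrom_sizes):
                    fh.write(
                        f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n"
                    )
            for g in annotation.genes:
                fh.write(
                    f"{g.chrom}\tchiptarget\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};Name={g.name}\n"
                )
        else:
            raise AnnotationError(f"unknown output format {format!r}")


@dataclass
class TSSIndex:
    """Per-chromosome sorted TSS positions supporting nearest queries.

    Exactly one entry per gene.  Ties (equidistant TSSs) are returned in
    full, ordered by gene_id, making nearest-neighbour results
    deterministic.
    """

    positions: dict[str, np.ndarray]
    gene_ids: dict[str, list[str]]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.gene_ids.values())

    def chroms(self) -> set[str]:
        return set(self.positions)

    def nearest(self, chrom: str, pos: int) -> tuple[list[str], int]:
        """Nearest TSS(s) to a point; returns (gene_ids, unsigned distance)."""
        return self.nearest_to_interval(chrom, pos, pos + 1)

    def nearest_to_interval(self, chrom: str, start: int, end: int) -> tuple[list[str], int]:
        """Nearest TSS(s) to a half-open interval.

        Distance is 0 when a TSS lies inside [start, end); otherwise the
        distance from the nearest interval edge (``start`` or ``end - 1``,
        inclusive-base convention) to the TSS.
        """
        if chrom not in self.positions:
            raise KeyError(chrom)
        pos = self.positions[chrom]
        ids = self.gene_ids[chrom]
        lo = int(np.searchsorted(pos, start, "left"))
        hi = int(np.searchsorted(pos, end, "left"))
        if hi > lo:  # at least one TSS inside the interval
            return sorted(ids[lo:hi]), 0
        candidates: list[tuple[int, int]] = []  # (distance, position)
        if lo > 0:
            candidates.append((start - int(pos[lo - 1]), int(pos[lo - 1])))
        if hi < len(pos):
            candidates.append((int(pos[hi]) - (end - 1), int(pos[hi])))
        best = min(d for d, _ in candidates)
        winners: list[str] = []
        for d, p in candidates:
            if d == best:
                a = int(np.searchsorted(pos, p, "left"))
                b = int(np.searchsorted(pos, p, "right"))
                winners.extend(ids[a:b])
        return sorted(set(winners)), best


def build_tss_index(annotation: GenomeAnnotation) -> TSSIndex:
    """Index one TSS per gene for nearest-position queries."""
    if len(annotation) == 0:
        raise AnnotationError("cannot build a TSS index from an empty annotation")
    positions: dict[str, np.ndarray] = {}
    gene_ids: dict[str, list[str]] = {}
    for chrom, genes in annotation.by_chrom().items():
        entries = sorted((tss_of(g), g.gene_id) for g in genes)
        positions[chrom] = np.array([p for p, _ in entries], dtype=np.int64)
        gene_ids[chrom] = [gid for _, gid in entries]
    return TSSIndex(positions=positions, gene_ids=gene_ids)
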